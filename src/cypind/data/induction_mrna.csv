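compound,enzyme,donor,ec50_uM,emax_fold,nc
apalutamide,CYP3A4,donor1,0.690,6.12,False
apalutamide,CYP3A4,donor2,1.61,20.8,False
apalutamide,CYP3A4,donor3,1.08,7.45,False
carbamazepine,CYP3A4,donor1,23.6,4.09,False
carbamazepine,CYP3A4,donor2,61.2,9.93,False
carbamazepine,CYP3A4,donor3,28.5,3.53,False
efavirenz,CYP3A4,donor1,2.61,5.32,False
efavirenz,CYP3A4,donor2,4.38,11.3,False
efavirenz,CYP3A4,donor3,3.04,5.31,False
rifampicin,CYP3A4,donor1,0.0655,5.60,False
rifampicin,CYP3A4,donor2,0.128,13.4,False
rifampicin,CYP3A4,donor3,0.0602,4.87,False
apalutamide,CYP2C8,donor1,1.68,8.36,False
apalutamide,CYP2C8,donor2,1.22,4.55,False
apalutamide,CYP2C8,donor3,1.26,7.20,False
carbamazepine,CYP2C8,donor1,35.6,3.21,False
carbamazepine,CYP2C8,donor2,20.0,2.26,False
carbamazepine,CYP2C8,donor3,40.2,5.07,False
efavirenz,CYP2C8,donor1,4.48,5.22,False
efavirenz,CYP2C8,donor2,1.97,2.85,False
efavirenz,CYP2C8,donor3,2.95,5.11,False
rifampicin,CYP2C8,donor1,0.504,6.89,False
rifampicin,CYP2C8,donor2,0.260,4.51,False
rifampicin,CYP2C8,donor3,0.307,7.36,False
apalutamide,CYP2C9,donor1,0.794,3.50,False
apalutamide,CYP2C9,donor2,0.419,3.63,False
apalutamide,CYP2C9,donor3,0.474,2.73,False
carbamazepine,CYP2C9,donor1,9.86,2.44,False
carbamazepine,CYP2C9,donor2,,,True
carbamazepine,CYP2C9,donor3,,,True
efavirenz,CYP2C9,donor1,0.455,2.46,False
efavirenz,CYP2C9,donor2,,,True
efavirenz,CYP2C9,donor3,,,True
rifampicin,CYP2C9,donor1,0.0876,3.23,False
rifampicin,CYP2C9,donor2,0.0784,2.87,False
rifampicin,CYP2C9,donor3,0.149,2.57,False
apalutamide,CYP2C19,donor1,4.01,8.42,False
apalutamide,CYP2C19,donor2,5.22,7.70,False
apalutamide,CYP2C19,donor3,6.04,14.6,False
carbamazepine,CYP2C19,donor1,124,5.11,False
carbamazepine,CYP2C19,donor2,186,4.48,False
carbamazepine,CYP2C19,donor3,182,7.22,False
efavirenz,CYP2C19,donor1,8.30,4.79,False
efavirenz,CYP2C19,donor2,,,True
efavirenz,CYP2C19,donor3,2.91,3.56,False
rifampicin,CYP2C19,donor1,1.64,19.9,False
rifampicin,CYP2C19,donor2,0.803,8.45,False
rifampicin,CYP2C19,donor3,1.47,17.9,False
apalutamide,CYP2B6,donor1,4.44,10.2,False
apalutamide,CYP2B6,donor2,2.98,6.71,False
apalutamide,CYP2B6,donor3,2.96,9.06,False
carbamazepine,CYP2B6,donor1,46.9,5.74,False
carbamazepine,CYP2B6,donor2,41.9,4.84,False
carbamazepine,CYP2B6,donor3,59.0,6.93,False
efavirenz,CYP2B6,donor1,2.76,6.46,False
efavirenz,CYP2B6,donor2,3.67,6.61,False
efavirenz,CYP2B6,donor3,4.01,9.44,False
rifampicin,CYP2B6,donor1,0.415,6.71,False
rifampicin,CYP2B6,donor2,0.53,5.91,False
rifampicin,CYP2B6,donor3,0.399,8.44,False
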