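compound,enzyme,donor,ec50_uM,emax_fold,nc
apalutamide,CYP3A4,donor1,0.686,2.96,False
apalutamide,CYP3A4,donor2,0.709,3.03,False
apalutamide,CYP3A4,donor3,1.50,10.6,False
carbamazepine,CYP3A4,donor1,6.40,2.31,False
carbamazepine,CYP3A4,donor2,2.70,3.38,False
carbamazepine,CYP3A4,donor3,17.8,4.44,False
efavirenz,CYP3A4,donor1,1.43,5.07,False
efavirenz,CYP3A4,donor2,0.259,2.79,False
efavirenz,CYP3A4,donor3,4.54,16.3,False
rifampicin,CYP3A4,donor1,0.0509,2.84,False
rifampicin,CYP3A4,donor2,0.0652,3.45,False
rifampicin,CYP3A4,donor3,0.0897,7.74,False
apalutamide,CYP2C9,donor1,13.1,2.79,False
apalutamide,CYP2C9,donor2,,,True
apalutamide,CYP2C9,donor3,23.7,3.25,False
carbamazepine,CYP2C9,donor1,41.4,2.52,False
carbamazepine,CYP2C9,donor2,,,True
carbamazepine,CYP2C9,donor3,,,True
efavirenz,CYP2C9,donor1,4.29,2.40,False
efavirenz,CYP2C9,donor2,,,True
efavirenz,CYP2C9,donor3,,,True
rifampicin,CYP2C9,donor1,0.469,2.44,False
rifampicin,CYP2C9,donor2,,,True
rifampicin,CYP2C9,donor3,,,True
apalutamide,CYP2C19,donor1,0.455,3.38,False
apalutamide,CYP2C19,donor2,1.03,3.62,False
apalutamide,CYP2C19,donor3,0.865,9.66,False
carbamazepine,CYP2C19,donor1,8.14,2.48,False
carbamazepine,CYP2C19,donor2,2.05,3.63,False
carbamazepine,CYP2C19,donor3,18,4.54,False
efavirenz,CYP2C19,donor1,0.946,3.04,False
efavirenz,CYP2C19,donor2,0.297,3.52,False
efavirenz,CYP2C19,donor3,2.48,6.87,False
rifampicin,CYP2C19,donor1,0.0438,3.48,False
rifampicin,CYP2C19,donor2,0.0816,4.09,False
rifampicin,CYP2C19,donor3,0.105,9.32,False
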