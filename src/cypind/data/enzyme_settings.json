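{
  "_comment": "Editable turnover/physiology defaults. kdeg: first-order enzyme degradation rate constants (1/h), literature consensus values (hepatic CYP3A4 t1/2 ~36 h, enterocyte CYP3A4 ~23 h, CYP2C9 ~104 h; Yang et al., Curr Drug Metab 2008; Obach et al., Clin Pharmacol Ther 2007).",
  "kdeg_per_h": {
    "CYP3A4": 0.0193,
    "CYP2C8": 0.03,
    "CYP2C9": 0.0067,
    "CYP2C19": 0.026,
    "CYP2B6": 0.022
  },
  "kdeg_gut_cyp3a4_per_h": 0.03,
  "q_hepatic_L_h": 97.0,
  "q_gut_L_h": 18.0,
  "driver": "inlet"
}
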