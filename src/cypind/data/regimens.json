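{
  "_comment": "Clinical DDI trial designs (perpetrator regimen + victim dose timing on the perpetrator clock, hours). Victim doses described as 'after perpetrator on day N' are placed 1 h after that day's perpetrator dose; '12.5 h after final dose' is literal; bupropion is dosed in the morning of day 8 of evening perpetrator dosing (12 h offset).",
  "midazolam": {
    "perpetrator": "rifampicin",
    "perpetrator_regimen": {"dose_mg": 600, "interval_h": 24, "n_doses": 5},
    "victim_regimen": {"dose_mg": 3, "n_doses": 1, "start_h": 97.0},
    "label": "rifampicin 600 mg qd x5; midazolam 3 mg after rifampicin on day 5"
  },
  "alfentanil": {
    "perpetrator": "rifampicin",
    "perpetrator_regimen": {"dose_mg": 600, "interval_h": 24, "n_doses": 5},
    "victim_regimen": {"dose_mg": 4, "n_doses": 1, "start_h": 97.0},
    "label": "rifampicin 600 mg qd x5; alfentanil 4 mg after rifampicin on day 5"
  },
  "atorvastatin": {
    "perpetrator": "rifampicin",
    "perpetrator_regimen": {"dose_mg": 600, "interval_h": 24, "n_doses": 5},
    "victim_regimen": {"dose_mg": 40, "n_doses": 1, "start_h": 97.0},
    "label": "rifampicin 600 mg qd x5; atorvastatin 40 mg after rifampicin on day 5"
  },
  "omeprazole": {
    "perpetrator": "rifampicin",
    "perpetrator_regimen": {"dose_mg": 450, "interval_h": 24, "n_doses": 6},
    "victim_regimen": {"dose_mg": 20, "n_doses": 1, "start_h": 121.0},
    "label": "rifampicin 450 mg qd x6; omeprazole 20 mg after rifampicin on day 6"
  },
  "pioglitazone": {
    "perpetrator": "rifampicin",
    "perpetrator_regimen": {"dose_mg": 600, "interval_h": 24, "n_doses": 6},
    "victim_regimen": {"dose_mg": 30, "n_doses": 1, "start_h": 97.0},
    "label": "rifampicin 600 mg qd x6; pioglitazone 30 mg after rifampicin on day 5"
  },
  "tolbutamide": {
    "perpetrator": "rifampicin",
    "perpetrator_regimen": {"dose_mg": 600, "interval_h": 24, "n_doses": 14},
    "victim_regimen": {"dose_mg": 500, "n_doses": 1, "start_h": 313.0},
    "label": "rifampicin 600 mg qd x14; tolbutamide 500 mg after rifampicin on day 14"
  },
  "glyburide": {
    "perpetrator": "rifampicin",
    "perpetrator_regimen": {"dose_mg": 600, "interval_h": 24, "n_doses": 5},
    "victim_regimen": {"dose_mg": 1.75, "n_doses": 1, "start_h": 108.5},
    "label": "rifampicin 600 mg qd x5; glyburide 1.75 mg 12.5 h after the final rifampicin dose"
  },
  "bupropion": {
    "perpetrator": "rifampicin",
    "perpetrator_regimen": {"dose_mg": 600, "interval_h": 24, "n_doses": 10},
    "victim_regimen": {"dose_mg": 150, "n_doses": 1, "start_h": 180.0},
    "label": "rifampicin 600 mg qd x10 (evenings); bupropion 150 mg on day 8"
  },
  "repaglinide": {
    "perpetrator": "rifampicin",
    "perpetrator_regimen": {"dose_mg": 600, "interval_h": 24, "n_doses": 10},
    "victim_regimen": {"dose_mg": 0.5, "n_doses": 1, "start_h": 228.5},
    "label": "rifampicin 600 mg qd x10; repaglinide 0.5 mg 12.5 h after the final rifampicin dose"
  },
  "warfarin": {
    "perpetrator": "rifampicin",
    "perpetrator_regimen": {"dose_mg": 600, "interval_h": 24, "n_doses": 3},
    "victim_regimen": {"dose_mg": 105, "n_doses": 1, "start_h": 73.0},
    "label": "rifampicin 600 mg qd x3; warfarin 1.5 mg/kg (70 kg assumed) on day 4 (experimental)"
  }
}
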