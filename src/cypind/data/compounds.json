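{
  "_comment": "Base pharmacokinetic fixtures (literature reconstructions) and victim fm maps. Induction parameter tables live in induction_mrna.csv / induction_activity.csv. fm maps printed as inequalities (e.g. '>0.9') carry the numeric fixture used for computation in fm plus the printed form in provenance.",
  "rifampicin": {
    "role": "perpetrator",
    "pk": {
      "mw_g_mol": 822.94,
      "ka_per_h": 1.0,
      "fa": 0.9,
      "v_L": 55.0,
      "cl_L_h": 11.6,
      "fu_plasma": 0.17,
      "fg0": 1.0,
      "liver_kpuu": 4.0
    },
    "imax_u_uM": 2.0,
    "provenance": {
      "pk": "literature: steady-state 600 mg oral rifampicin, CL/F ~10-13 L/h, V ~0.7-1 L/kg, t1/2 2-3 h, fu 0.11-0.2 (Acocella, Clin Pharmacokinet 1978; Loos et al., Klin Wochenschr 1985)",
      "liver_kpuu": "literature: OATP1B1-mediated hepatocellular uptake; unbound liver-to-plasma ratios of ~4-15 reported in uptake and PET studies (Zamek-Gliszczynski et al., Clin Pharmacol Ther 2013; Marie et al., J Nucl Med 2017)",
      "imax_u_uM": "literature: steady-state Cmax ~10-12 ug/mL at 600 mg qd, fu 0.17"
    }
  },
  "efavirenz": {
    "role": "perpetrator",
    "pk": {
      "mw_g_mol": 315.67,
      "ka_per_h": 0.6,
      "fa": 0.6,
      "v_L": 250.0,
      "cl_L_h": 4.0,
      "fu_plasma": 0.006,
      "fg0": 1.0,
      "liver_kpuu": 1.0
    },
    "imax_u_uM": 0.076,
    "provenance": {
      "pk": "literature: 600 mg qd efavirenz, t1/2 40-55 h, CL/F ~9 L/h, >99% protein bound (product label; Csajka et al., Clin Pharmacol Ther 2003)"
    }
  },
  "carbamazepine": {
    "role": "perpetrator",
    "pk": {
      "mw_g_mol": 236.27,
      "ka_per_h": 0.5,
      "fa": 0.85,
      "v_L": 98.0,
      "cl_L_h": 3.7,
      "fu_plasma": 0.25,
      "fg0": 1.0,
      "liver_kpuu": 1.0
    },
    "imax_u_uM": 8.5,
    "provenance": {
      "pk": "literature: chronic carbamazepine, V ~1.4 L/kg, autoinduced CL/F ~0.05 L/h/kg, fu ~0.25 (Bertilsson, Clin Pharmacokinet 1978)"
    }
  },
  "apalutamide": {
    "role": "perpetrator",
    "pk": {
      "mw_g_mol": 477.44,
      "ka_per_h": 0.4,
      "fa": 1.0,
      "v_L": 276.0,
      "cl_L_h": 1.3,
      "fu_plasma": 0.04,
      "fg0": 1.0,
      "liver_kpuu": 1.0
    },
    "imax_u_uM": 0.5,
    "provenance": {
      "pk": "literature: 240 mg qd apalutamide, V/F 276 L, CL/F 1.3 L/h, 96% bound (product label)"
    }
  },
  "midazolam": {
    "role": "victim",
    "pk": {
      "mw_g_mol": 325.77,
      "ka_per_h": 2.0,
      "fa": 0.9,
      "v_L": 77.0,
      "cl_L_h": 26.0,
      "fu_plasma": 0.032,
      "fg0": 0.51
    },
    "fm": {"CYP3A4": 0.94},
    "provenance": {
      "pk": "literature: iv midazolam CL ~0.4-0.5 L/min, V ~1.1 L/kg, fu 0.03, Fg ~0.5 (Thummel et al., Clin Pharmacol Ther 1996; Gertz et al., Drug Metab Dispos 2010)",
      "fm": "printed '>0.9'; fixture 0.94"
    }
  },
  "alfentanil": {
    "role": "victim",
    "pk": {
      "mw_g_mol": 416.52,
      "ka_per_h": 2.0,
      "fa": 1.0,
      "v_L": 40.0,
      "cl_L_h": 15.0,
      "fu_plasma": 0.08,
      "fg0": 0.75
    },
    "fm": {"CYP3A4": 0.93},
    "provenance": {
      "pk": "literature: alfentanil CL 0.2-0.35 L/min, V 0.4-0.8 L/kg, fu ~0.08; oral availability ~0.4 with hepatic and modest gut first pass (Kharasch et al., Anesthesiology 2011)",
      "fm": "printed '>=0.8'; fixture 0.93 (alfentanil elimination is nearly exclusively CYP3A)"
    }
  },
  "atorvastatin": {
    "role": "victim",
    "pk": {
      "mw_g_mol": 558.64,
      "ka_per_h": 1.5,
      "fa": 0.3,
      "v_L": 380.0,
      "cl_L_h": 34.0,
      "fu_plasma": 0.02,
      "fg0": 0.8
    },
    "fm": {"CYP3A4": 0.90},
    "provenance": {
      "pk": "literature: atorvastatin acid F ~0.14 with Fa ~0.3 (solubility/efflux limited), V ~5.4 L/kg, systemic CL ~0.5 L/min (Lennernas, Clin Pharmacokinet 2003); Fg chosen so F = Fa*Fg*Fh matches ~0.14",
      "fm": "printed '>0.9' in the dosing table and '>0.8' in the outcome table; fixture 0.90 (dosing-table value is the default)"
    }
  },
  "omeprazole": {
    "role": "victim",
    "pk": {
      "mw_g_mol": 345.42,
      "ka_per_h": 1.5,
      "fa": 1.0,
      "v_L": 20.0,
      "cl_L_h": 30.0,
      "fu_plasma": 0.045,
      "fg0": 1.0
    },
    "fm": {"CYP2C19": 0.68, "CYP3A4": 0.32},
    "provenance": {
      "pk": "literature: omeprazole CL ~0.5 L/min, V 0.3 L/kg, t1/2 ~1 h, fu ~0.05, F ~0.5 (Andersson, Clin Pharmacokinet 1996)"
    }
  },
  "pioglitazone": {
    "role": "victim",
    "pk": {
      "mw_g_mol": 356.44,
      "ka_per_h": 0.6,
      "fa": 0.9,
      "v_L": 20.0,
      "cl_L_h": 3.2,
      "fu_plasma": 0.01,
      "fg0": 1.0
    },
    "fm": {"CYP2C8": 0.56, "CYP3A4": 0.37},
    "provenance": {
      "pk": "literature: pioglitazone CL/F 2-4 L/h, V/F 0.2-0.4 L/kg, t1/2 3-7 h, >99% bound (Eckland & Danhof, Exp Clin Endocrinol Diabetes 2000)"
    }
  },
  "tolbutamide": {
    "role": "victim",
    "pk": {
      "mw_g_mol": 270.35,
      "ka_per_h": 1.0,
      "fa": 0.93,
      "v_L": 9.0,
      "cl_L_h": 0.85,
      "fu_plasma": 0.04,
      "fg0": 1.0
    },
    "fm": {"CYP2C9": 0.85},
    "provenance": {
      "pk": "literature: tolbutamide CL ~0.2 mL/min/kg, V 0.1-0.15 L/kg, t1/2 6-8 h, fu ~0.04 (Miners & Birkett, Br J Clin Pharmacol 1996)",
      "fm": "printed 'CYP2C9 0.85, other CYPs 0.15'; the 0.15 residual is treated as uninduced clearance in this fixture"
    }
  },
  "glyburide": {
    "role": "victim",
    "pk": {
      "mw_g_mol": 494.0,
      "ka_per_h": 1.0,
      "fa": 1.0,
      "v_L": 10.0,
      "cl_L_h": 2.2,
      "fu_plasma": 0.002,
      "fg0": 1.0
    },
    "fm": {"CYP3A4": 0.53, "CYP2C9": 0.35, "CYP2C8": 0.12},
    "provenance": {
      "pk": "literature: glyburide CL ~1.3-3 L/h, V ~10 L, t1/2 2-4 h, fu ~0.002 (Pearson, Clin Pharmacokinet 1985)"
    }
  },
  "bupropion": {
    "role": "victim",
    "pk": {
      "mw_g_mol": 239.74,
      "ka_per_h": 1.5,
      "fa": 0.87,
      "v_L": 750.0,
      "cl_L_h": 38.0,
      "fu_plasma": 0.16,
      "fg0": 1.0
    },
    "fm": {"CYP2B6": 0.21, "CYP2C19": 0.18},
    "provenance": {
      "pk": "literature: bupropion V ~20-47 L/kg (apparent), t1/2 ~14-21 h, 84% bound (product label; Findlay et al., Eur J Clin Pharmacol 1981); residual 0.61 treated as uninduced (carbonyl reduction and other pathways)"
    }
  },
  "repaglinide": {
    "role": "victim",
    "pk": {
      "mw_g_mol": 452.59,
      "ka_per_h": 2.0,
      "fa": 1.0,
      "v_L": 30.0,
      "cl_L_h": 33.0,
      "fu_plasma": 0.015,
      "fg0": 1.0
    },
    "fm": {"CYP3A4": 0.74, "CYP2C8": 0.26},
    "provenance": {
      "pk": "literature: repaglinide CL ~33-38 L/h, V 30 L, t1/2 ~1 h, >98% bound, F ~0.6 (Hatorp, Clin Pharmacokinet 2002); hepatic uptake kinetics not modeled (CYP-only treatment)"
    }
  },
  "warfarin": {
    "role": "victim",
    "experimental": true,
    "pk": {
      "mw_g_mol": 308.33,
      "ka_per_h": 1.0,
      "fa": 0.93,
      "v_L": 10.0,
      "cl_L_h": 0.2,
      "fu_plasma": 0.01,
      "fg0": 1.0
    },
    "fm": {"CYP2C9": 0.64, "CYP3A4": 0.05, "CYP2B6": 0.12},
    "provenance": {
      "pk": "literature: racemic warfarin CL ~0.2 L/h, V ~10 L, 99% bound (Holford, Clin Pharmacokinet 1986); registered for completeness, enantiomer kinetics not modeled (experimental)"
    }
  }
}
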