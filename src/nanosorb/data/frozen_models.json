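{
  "schema": "nanosorb-linear-model-registry-v1",
  "response": "log10 k (adsorption affinity)",
  "n_models": 19,
  "models": [
    {"enm_id": "Ag50_Citrat", "intercept": 2.39,
     "terms": [["ALogP", 0.40], ["Fsp3", -0.54], ["khs.sOH", 0.37], ["WTPT.4", -0.04], ["ATSm1", -0.004]],
     "r2_train_adj": 0.82, "r2_validate_adj": 0.83},
    {"enm_id": "Ag200_PVP", "intercept": 2.63,
     "terms": [["ALogP", 0.30], ["khs.sOH", 0.32], ["nAtom", -0.01], ["Fsp3", -0.25], ["nAcid", 0.22]],
     "r2_train_adj": 0.71, "r2_validate_adj": 0.77},
    {"enm_id": "AlOOH", "intercept": 1.79,
     "terms": [["ALogP", 0.49], ["nHBDon", 0.45], ["Fsp3", -0.57], ["ATSm1", 0.004], ["nBase", -0.41]],
     "r2_train_adj": 0.83, "r2_validate_adj": 0.84},
    {"enm_id": "BaSO4_NM220", "intercept": 1.73,
     "terms": [["ALogP", 0.30], ["nAtomP", 0.03], ["nHBDon", 0.23], ["ATSm1", 0.004], ["nSmallRings", 0.11]],
     "r2_train_adj": 0.86, "r2_validate_adj": 0.86},
    {"enm_id": "FullrC60", "intercept": 0.15,
     "terms": [["ALogP", 0.79], ["khs.aasC", -0.14], ["khs.sssSiH", 1.53], ["WPATH", -0.0001], ["khs.aasN", -0.63]],
     "r2_train_adj": 0.91, "r2_validate_adj": 0.90},
    {"enm_id": "sMWCNT", "intercept": 1.76,
     "terms": [["ATSp1", 0.003], ["nAtomP", 0.09], ["khs.ssssC", -0.39], ["khs.sBr", 0.33], ["khs.sOH", -0.13]],
     "r2_train_adj": 0.88, "r2_validate_adj": 0.93},
    {"enm_id": "MWNT_COOH_20nm", "intercept": -0.81,
     "terms": [["AMR", 0.12], ["Fsp3", -1.18], ["ATSm4", 0.02], ["MDEO.11", 0.53], ["khs.aaaC", 0.17]],
     "r2_train_adj": 0.94, "r2_validate_adj": 0.97},
    {"enm_id": "MWNT_COOH_50nm", "intercept": -0.005,
     "terms": [["AMR", 0.11], ["nRotB", -0.15], ["C1SP3", -0.14], ["TopoPSA", 0.006], ["khs.aaaC", 0.19]],
     "r2_train_adj": 0.97, "r2_validate_adj": 0.98},
    {"enm_id": "MWNT_OH", "intercept": -0.35,
     "terms": [["ATSp1", 0.005], ["nAtomP", 0.18], ["khs.ssssC", -0.60], ["khs.sBr", 0.60], ["nHBDon", 0.23]],
     "r2_train_adj": 0.92, "r2_validate_adj": 0.96},
    {"enm_id": "MWNT", "intercept": 1.53,
     "terms": [["ATSp1", 0.004], ["khs.ssssC", -0.65], ["nAtomP", 0.06], ["MDEO.11", 0.44], ["khs.sOH", -0.18]],
     "r2_train_adj": 0.91, "r2_validate_adj": 0.94},
    {"enm_id": "SiO2_Amino", "intercept": 1.71,
     "terms": [["ALogP", 0.50], ["nHBDon", 0.36], ["nBase", -0.41], ["nAcid", 0.31], ["khs.sssSiH", -0.90]],
     "r2_train_adj": 0.85, "r2_validate_adj": 0.87},
    {"enm_id": "SiO2_Naked", "intercept": 2.40,
     "terms": [["XLogP", 0.40], ["Fsp3", -0.49], ["khs.sOH", 0.35], ["Kier2", -0.07], ["khs.ssNH", -0.21]],
     "r2_train_adj": 0.80, "r2_validate_adj": 0.82},
    {"enm_id": "SiO2_PEG", "intercept": 1.58,
     "terms": [["XLogP", 0.49], ["fragC", -0.0004], ["nHBDon", 0.41], ["khs.ssssSi", -0.26], ["nBase", -0.42]],
     "r2_train_adj": 0.77, "r2_validate_adj": 0.77},
    {"enm_id": "SiO2_Phosphat", "intercept": 1.93,
     "terms": [["ALogP", 0.48], ["nHBDon", 0.37], ["Fsp3", -0.22], ["nBase", -0.35], ["nAcid", 0.30]],
     "r2_train_adj": 0.84, "r2_validate_adj": 0.86},
    {"enm_id": "TiO2_NM105", "intercept": 1.96,
     "terms": [["ALogP", 0.40], ["nHBDon", 0.36], ["Fsp3", -0.52], ["SCH.7", 0.41], ["ATSm1", -0.004]],
     "r2_train_adj": 0.85, "r2_validate_adj": 0.86},
    {"enm_id": "ZnO_NM110", "intercept": 1.62,
     "terms": [["ALogP", 0.54], ["nHBDon", 0.41], ["nBase", -0.41], ["Fsp3", -0.32], ["khs.sssSiH", 0.95]],
     "r2_train_adj": 0.86, "r2_validate_adj": 0.87},
    {"enm_id": "ZrO2_Amino", "intercept": 1.71,
     "terms": [["ALogP", 0.53], ["khs.sOH", 0.37], ["ATSp5", -0.0002], ["khs.sssSiH", 1.09], ["nAcid", 0.30]],
     "r2_train_adj": 0.79, "r2_validate_adj": 0.83},
    {"enm_id": "ZrO2_PEG", "intercept": 2.22,
     "terms": [["ALogP", 0.60], ["khs.sOH", 0.45], ["Kier1", -0.07], ["Fsp3", 0.34], ["khs.sssSiH", 1.14]],
     "r2_train_adj": 0.77, "r2_validate_adj": 0.80},
    {"enm_id": "ZrO2_TODacid", "intercept": 1.61,
     "terms": [["XLogP", 0.46], ["khs.sOH", 0.41], ["ECCEN", -0.002], ["khs.ssssSi", 0.22], ["nAcid", -0.36]],
     "r2_train_adj": 0.74, "r2_validate_adj": 0.79}
  ]
}
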