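{
  "version": "1.0",
  "comment": "Monoisotopic adduct mass shifts (Da). m/z = (M + shift_total)/z with shift_total built from standard element masses: proton 1.007276, Na-H 21.981944, K-H 37.955882, NH4-H 17.026549, Cl 34.969402, formate (HCOO) 44.998201, H2O 18.010565.",
  "adducts": [
    {"name": "M+H",     "mode": "positive", "charge": 1, "shift": 1.007276},
    {"name": "M+2H",    "mode": "positive", "charge": 2, "shift": 2.014552},
    {"name": "M+Na",    "mode": "positive", "charge": 1, "shift": 21.981944},
    {"name": "M+K",     "mode": "positive", "charge": 1, "shift": 37.955882},
    {"name": "M+NH4",   "mode": "positive", "charge": 1, "shift": 18.033825},
    {"name": "M-H",     "mode": "negative", "charge": 1, "shift": -1.007276},
    {"name": "M+Cl",    "mode": "negative", "charge": 1, "shift": 34.969402},
    {"name": "M+FA-H",  "mode": "negative", "charge": 1, "shift": 44.998201},
    {"name": "M-H-H2O", "mode": "negative", "charge": 1, "shift": -19.017841}
  ]
}
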