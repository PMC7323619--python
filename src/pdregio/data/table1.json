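{
  "description": "Literature validation set: twelve Pd(OAc)2-catalysed C-H activation reactions. Substrate structures are depicted only graphically in the source, so they are not machine-readable; records carry the reaction conditions verbatim and the qualitative prediction outcome. Energy-level fixtures key off substrate ids, never off these structures.",
  "entries": [
    {"id": "t1e1", "structure": null, "structure_confidence": "none", "conditions": "CO, EtOH, Pd(OAc)2, Cu(OAc)2, KOAc, DMF, KI, 100 C, 13 h", "sear_stable": false, "notes": "no stable intermediate for the electrophilic mechanism"},
    {"id": "t1e2", "structure": null, "structure_confidence": "none", "conditions": "CO, Pd(OAc)2, Cu(OAc)2, PivOH, mesitylene, 120 C, 6 h", "sear_stable": true, "notes": ""},
    {"id": "t1e3", "structure": null, "structure_confidence": "none", "conditions": "Cu(OAc)2, Pd(OAc)2, K2CO3, DMF, 60 C, 0.6 h", "sear_stable": true, "notes": ""},
    {"id": "t1e4", "structure": null, "structure_confidence": "none", "conditions": "PhCOCO2H, Pd(OAc)2, K2S2O8, MeCN, 25 C, 16 h", "sear_stable": true, "notes": ""},
    {"id": "t1e5", "structure": null, "structure_confidence": "none", "conditions": "PhSi(OMe)3, Pd(OAc)2, AgF, dioxane, 80 C, 16 h", "sear_stable": true, "notes": ""},
    {"id": "t1e6", "structure": null, "structure_confidence": "none", "conditions": "Ph-CHO, Pd(OAc)2, TBHP, toluene, 110 C, 5 h", "sear_stable": true, "notes": "reference example used when the mechanism threshold was set"},
    {"id": "t1e7", "structure": null, "structure_confidence": "none", "conditions": "Ph-CHO, Pd(OAc)2, xylene, O2, 120 C, 24 h", "sear_stable": true, "notes": ""},
    {"id": "t1e8", "structure": null, "structure_confidence": "none", "conditions": "PhCOCO2H, Pd(OAc)2, Ag2CO3, DMF, 120 C, 24 h", "sear_stable": true, "notes": ""},
    {"id": "t1e9", "structure": null, "structure_confidence": "none", "conditions": "H-COOPh, Pd(OAc)2, I2, K2CO3, DMF, 100 C, 12 h", "sear_stable": true, "notes": ""},
    {"id": "t1e10", "structure": null, "structure_confidence": "none", "conditions": "PhB(OH)2, Pd(OAc)2, TEMPO, phen, DMAc, O2, 100 C, 48 h", "sear_stable": true, "notes": ""},
    {"id": "t1e11", "structure": null, "structure_confidence": "none", "conditions": "benzene, Pd(OAc)2, O2, HOAc, DMA, 130 C, 20 h", "sear_stable": true, "notes": ""},
    {"id": "t1e12", "structure": null, "structure_confidence": "none", "conditions": "Pd(OAc)2, CuCO3, dioxane, DMSO, 140 C, 16 h", "sear_stable": true, "notes": ""}
  ]
}
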