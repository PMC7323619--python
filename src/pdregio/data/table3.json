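{
  "description": "Second validation set of six Pd(OAc)2-catalysed reactions; the corresponding decision-layer numbers (Gibbs energy, Pd-C distance, stability parameter, calls) are in table4.json, matched by entry number. Structures are depicted only graphically in the source (structure_confidence 'none'). Where the source prints site energies, they are replicated in paper_tables.csv; single 'H1: 0.0' groups added there so the decision layer can replay the published delta are marked sites_source='minimal'.",
  "entries": [
    {"id": "t3e1", "structure": null, "structure_confidence": "none", "conditions": "Pd(OAc)2, TBHP, toluene, 120 C, 6 h", "expected_product_site": null, "delta_kcal": 3.0777, "delta_source": "table4", "sites_source": "minimal"},
    {"id": "t3e2", "structure": null, "structure_confidence": "none", "conditions": "Pd(OAc)2, TBHP, DCE, 80 C, 16 h", "expected_product_site": "H1", "delta_kcal": -1.6369, "delta_source": "table4", "sites_source": "printed-sear-only"},
    {"id": "t3e3", "structure": null, "structure_confidence": "none", "conditions": "Pd(OAc)2, TBHP, toluene, TFA, 40 C, 3 h", "expected_product_site": "H1", "delta_kcal": 1.4558, "delta_source": "table4", "sites_source": "printed"},
    {"id": "t3e4", "structure": null, "structure_confidence": "none", "conditions": "Pd(OAc)2, toluene, TBHP, 110 C, 5 h", "expected_product_site": null, "delta_kcal": null, "delta_source": "sear_absent", "sites_source": "minimal"},
    {"id": "t3e5", "structure": null, "structure_confidence": "none", "conditions": "Pd(OAc)2, 1,4-dioxane, AcOH, DMSO, TBHP, 110 C, 24 h", "expected_product_site": null, "delta_kcal": 2.2326, "delta_source": "table4", "sites_source": "excluded-anomalous"},
    {"id": "t3e6", "structure": null, "structure_confidence": "none", "conditions": "Ag2CO3, Pd(OAc)2, NaOAc, CO, 1,4-dioxane, 130 C, 18 h", "expected_product_site": "H1", "delta_kcal": -21.9298, "delta_source": "table4", "sites_source": "printed"}
  ]
}
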