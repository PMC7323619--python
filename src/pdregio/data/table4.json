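{
  "description": "Published decision-layer numbers for the six second-set substrates: Gibbs free energy of the most probable Pd-substrate intermediate (Hartree, relative to the starting molecule), its Pd-C distance (A), the ipso-complex stability parameter (kcal/mol), and the predicted vs experimentally reported mechanism. Entry 5 is stored verbatim with anomaly_flag=true: its Gibbs value is positive (presumed sign typo), its Pd-C distance exceeds the 2.4 A stability bound, and its stability parameter lies inside the ambiguous band although the published call is SEAR.",
  "entries": [
    {"entry": 1, "gibbs_hartree": -355.5652, "pd_c_angstrom": 2.3005, "relative_stability_kcal": 3.0777, "predicted_mechanism": "AMBIGUOUS", "reported_mechanism": "AMBIGUOUS", "sear_absent": false, "anomaly_flag": false},
    {"entry": 2, "gibbs_hartree": -355.5577, "pd_c_angstrom": 2.3778, "relative_stability_kcal": -1.6369, "predicted_mechanism": "PA", "reported_mechanism": "PA", "sear_absent": false, "anomaly_flag": false},
    {"entry": 3, "gibbs_hartree": -355.5626, "pd_c_angstrom": 2.1345, "relative_stability_kcal": 1.4558, "predicted_mechanism": "AMBIGUOUS", "reported_mechanism": "AMBIGUOUS", "sear_absent": false, "anomaly_flag": false},
    {"entry": 4, "gibbs_hartree": null, "pd_c_angstrom": null, "relative_stability_kcal": null, "predicted_mechanism": "PA", "reported_mechanism": "PA", "sear_absent": true, "anomaly_flag": false},
    {"entry": 5, "gibbs_hartree": 355.5717, "pd_c_angstrom": 7.1781, "relative_stability_kcal": 2.2326, "predicted_mechanism": "SEAR", "reported_mechanism": "SEAR", "sear_absent": false, "anomaly_flag": true},
    {"entry": 6, "gibbs_hartree": -355.5254, "pd_c_angstrom": 2.168, "relative_stability_kcal": -21.9298, "predicted_mechanism": "PA", "reported_mechanism": "PA", "sear_absent": false, "anomaly_flag": false}
  ]
}
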