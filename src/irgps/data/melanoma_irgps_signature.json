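{
  "name": "melanoma-irgps-33",
  "note": "Reference 33-pair immune-related gene-pair (IRGP) prognostic signature for melanoma overall survival, with its companion risk-score cutoff chosen by 3-year time-dependent ROC.",
  "cutoff": -1.13,
  "entries": [
    {"gene_a": "HFE", "gene_b": "SLPI", "coefficient": -0.03375},
    {"gene_a": "HFE", "gene_b": "LHB", "coefficient": -0.18429},
    {"gene_a": "HLA-DQA2", "gene_b": "SLPI", "coefficient": -0.00242},
    {"gene_a": "HLA-DQB1", "gene_b": "S100A8", "coefficient": -0.52645},
    {"gene_a": "HSPA2", "gene_b": "APOBEC3G", "coefficient": 0.00529},
    {"gene_a": "MICB", "gene_b": "OAS1", "coefficient": 0.054884},
    {"gene_a": "PSME1", "gene_b": "IFITM1", "coefficient": 0.120809},
    {"gene_a": "PI3", "gene_b": "FGF1", "coefficient": 0.060244},
    {"gene_a": "PI3", "gene_b": "LCP2", "coefficient": 0.023869},
    {"gene_a": "SLPI", "gene_b": "KDR", "coefficient": 0.24411},
    {"gene_a": "CCL13", "gene_b": "FABP4", "coefficient": -0.13567},
    {"gene_a": "CCL8", "gene_b": "STC1", "coefficient": -0.05866},
    {"gene_a": "CCL8", "gene_b": "APLNR", "coefficient": -0.02258},
    {"gene_a": "TINAGL1", "gene_b": "IGF2", "coefficient": -0.22219},
    {"gene_a": "APOBEC3G", "gene_b": "ACVRL1", "coefficient": -0.00508},
    {"gene_a": "APOBEC3G", "gene_b": "ANGPTL2", "coefficient": -0.13337},
    {"gene_a": "APOBEC3G", "gene_b": "S1PR1", "coefficient": -0.12991},
    {"gene_a": "TLR2", "gene_b": "DLL4", "coefficient": -0.00407},
    {"gene_a": "PAEP", "gene_b": "PTK2B", "coefficient": 0.059944},
    {"gene_a": "PAEP", "gene_b": "TYMP", "coefficient": 0.125313},
    {"gene_a": "FABP3", "gene_b": "MDK", "coefficient": 0.212626},
    {"gene_a": "IRF1", "gene_b": "MET", "coefficient": -0.32083},
    {"gene_a": "APOBEC3F", "gene_b": "EDNRA", "coefficient": -0.14079},
    {"gene_a": "LYZ", "gene_b": "NEO1", "coefficient": -0.04497},
    {"gene_a": "APOBEC3H", "gene_b": "CXCR6", "coefficient": 0.038609},
    {"gene_a": "MARCO", "gene_b": "PLAUR", "coefficient": -0.18686},
    {"gene_a": "IRF7", "gene_b": "RAC3", "coefficient": -0.10045},
    {"gene_a": "PLSCR1", "gene_b": "RAC3", "coefficient": -0.14566},
    {"gene_a": "CXCR6", "gene_b": "IL24", "coefficient": -0.08622},
    {"gene_a": "LTBP1", "gene_b": "LHB", "coefficient": -0.09531},
    {"gene_a": "CCRL2", "gene_b": "CTLA4", "coefficient": 0.092781},
    {"gene_a": "CLCF1", "gene_b": "LHB", "coefficient": -0.2615},
    {"gene_a": "IL1RN", "gene_b": "LCP2", "coefficient": 0.370091}
  ]
}
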