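{
  "format_version": 1,
  "marker_set": {
    "name": "GC-SSA-NHEJ-76",
    "positive_genes": ["BRIP1", "CDC45", "CDC7", "CDCA2", "CENPK", "CLSPN", "DDIAS", "DLGAP5", "DTL", "E2F7", "EZH2", "FANCA", "HELLS", "HIST1H2AH", "KIF11", "KIF15", "KIF18A", "KIF23", "KIF2C", "KNTC1", "LMNB1", "MCM10", "MND1", "NCAPG", "ORC1", "PCNA", "PLK4", "POLE2", "POLQ", "POLR3G", "RAD51AP1", "RAD54L", "RFC4", "RRM2", "TYMS", "UHRF1", "XRCC2"],
    "negative_genes": ["ADCY5", "APOD", "C15orf59", "C16orf89", "C1QTNF2", "C1QTNF7", "CGNL1", "CRYAB", "DAAM2", "DACT3", "DCN", "ELN", "FAM110B", "FMOD", "GHR", "GREM2", "GSTM5", "HSPA2", "HSPB8", "KCNK3", "LRRN4CL", "MFAP4", "NDNF", "NEGR1", "NFATC4", "PDE2A", "PPP1R14A", "PPP1R3C", "SAMD11", "SCN4B", "SCUBE2", "SLC22A17", "SMARCD3", "SRPX", "TCEAL7", "TMEM100", "TMOD1", "TNFAIP8L3", "ZCCHC24"]
  },
  "score_method": "student",
  "survival_cutoff": 3.46,
  "cancer_normal_cutoff": 0.008,
  "provenance": {
    "source": "published gastric-cancer training cohort (RNA-seq, n=242 training tumors)",
    "note": "cutoffs are the published values; they were derived from data this package does not redistribute",
    "training_n": 242,
    "seed": null
  }
}
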