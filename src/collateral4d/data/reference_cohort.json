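{
  "description": "Baseline characteristics of the 92-patient reference anterior-circulation LVO stroke cohort, split by poor (n=42) vs good (n=50) collateral circulation: printed group counts, summary statistics, and the p values the published comparison reported.",
  "n": {"poor": 42, "good": 50},
  "age": {
    "poor": {"n": 42, "mean": 69.45, "sd": 14.05},
    "good": {"n": 50, "mean": 63.54, "sd": 12.82}
  },
  "gender": {"categories": ["male", "female"], "poor": [30, 12], "good": [31, 19]},
  "onset": {"categories": ["<6h", "6-24h", ">24h"], "poor": [17, 11, 14], "good": [15, 8, 27]},
  "treatment": {
    "categories": ["thrombolysis", "endovascular", "bridging", "conservative"],
    "poor": [5, 9, 1, 27],
    "good": [3, 13, 2, 32]
  },
  "hemorrhage": {"categories": ["yes", "no"], "poor": [13, 29], "good": [6, 44]},
  "artery": {
    "categories": ["ICA", "MCA", "ICA+MCA", "ICA+MCA+ACA"],
    "poor": [3, 28, 10, 1],
    "good": [9, 36, 3, 0]
  },
  "toast": {"categories": ["LAA", "CE", "SOE"], "poor": [25, 15, 2], "good": [38, 9, 3]},
  "reported_p": {
    "gender": 0.341,
    "age": 0.038,
    "nihss": 0.001,
    "onset": 0.132,
    "treatment": 0.729,
    "artery": 0.041,
    "toast": 0.126,
    "hemorrhage": 0.025
  },
  "notes": "The artery and toast rows do not reproduce under uncorrected Pearson chi-square from the printed counts (recomputation gives ~0.038 and ~0.156); they are retained for completeness but are not validation targets. NIHSS is reported as median (IQR) only, which under-determines the rank test."
}
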