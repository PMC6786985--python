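{
  "name": "validation-2019",
  "description": "Unmodified EASILUNG score terms recalibrated on the external validation platform (50 Mb capture), with the post-recalibration decision threshold.",
  "binary_terms": [
    {"class": "C>A", "cutoff": 12, "comparator": ">", "points": 175},
    {"class": "G>T", "cutoff": 13, "comparator": ">", "points": 62},
    {"class": "A>G", "cutoff": 5, "comparator": ">", "points": -74},
    {"class": "T>C", "cutoff": 5, "comparator": ">", "points": -73}
  ],
  "continuous_terms": [
    {"class": "C>T", "points": -9},
    {"class": "G>A", "points": -6},
    {"class": "A>C", "points": -17},
    {"class": "T>G", "points": -17}
  ],
  "calibration": {"intercept": 2.094, "slope": 0.008},
  "decision_threshold": -467,
  "low_burden_cutoff": 1.0
}
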