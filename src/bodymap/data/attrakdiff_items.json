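[
  {"item": 1,  "pair": "technical - human",               "subscale": "pragmatic_quality",           "polarity": 1},
  {"item": 2,  "pair": "complicated - simple",            "subscale": "pragmatic_quality",           "polarity": 1},
  {"item": 3,  "pair": "impractical - practical",         "subscale": "pragmatic_quality",           "polarity": 1},
  {"item": 4,  "pair": "cumbersome - straightforward",    "subscale": "pragmatic_quality",           "polarity": 1},
  {"item": 5,  "pair": "unpredictable - predictable",     "subscale": "pragmatic_quality",           "polarity": 1},
  {"item": 6,  "pair": "confusing - clearly structured",  "subscale": "pragmatic_quality",           "polarity": 1},
  {"item": 7,  "pair": "unruly - manageable",             "subscale": "pragmatic_quality",           "polarity": 1},
  {"item": 8,  "pair": "isolating - connective",          "subscale": "hedonic_quality_identity",    "polarity": 1},
  {"item": 9,  "pair": "unprofessional - professional",   "subscale": "hedonic_quality_identity",    "polarity": 1},
  {"item": 10, "pair": "tacky - stylish",                 "subscale": "hedonic_quality_identity",    "polarity": 1},
  {"item": 11, "pair": "cheap - premium",                 "subscale": "hedonic_quality_identity",    "polarity": 1},
  {"item": 12, "pair": "alienating - integrating",        "subscale": "hedonic_quality_identity",    "polarity": 1},
  {"item": 13, "pair": "separates me - brings me closer", "subscale": "hedonic_quality_identity",    "polarity": 1},
  {"item": 14, "pair": "unpresentable - presentable",     "subscale": "hedonic_quality_identity",    "polarity": 1},
  {"item": 15, "pair": "conventional - inventive",        "subscale": "hedonic_quality_stimulation", "polarity": 1},
  {"item": 16, "pair": "unimaginative - creative",        "subscale": "hedonic_quality_stimulation", "polarity": 1},
  {"item": 17, "pair": "cautious - bold",                 "subscale": "hedonic_quality_stimulation", "polarity": 1},
  {"item": 18, "pair": "conservative - innovative",       "subscale": "hedonic_quality_stimulation", "polarity": 1},
  {"item": 19, "pair": "dull - captivating",              "subscale": "hedonic_quality_stimulation", "polarity": 1},
  {"item": 20, "pair": "undemanding - challenging",       "subscale": "hedonic_quality_stimulation", "polarity": 1},
  {"item": 21, "pair": "ordinary - novel",                "subscale": "hedonic_quality_stimulation", "polarity": 1},
  {"item": 22, "pair": "unpleasant - pleasant",           "subscale": "attractiveness",              "polarity": 1},
  {"item": 23, "pair": "ugly - attractive",               "subscale": "attractiveness",              "polarity": 1},
  {"item": 24, "pair": "disagreeable - likeable",         "subscale": "attractiveness",              "polarity": 1},
  {"item": 25, "pair": "rejecting - inviting",            "subscale": "attractiveness",              "polarity": 1},
  {"item": 26, "pair": "bad - good",                      "subscale": "attractiveness",              "polarity": 1},
  {"item": 27, "pair": "repelling - appealing",           "subscale": "attractiveness",              "polarity": 1},
  {"item": 28, "pair": "discouraging - motivating",       "subscale": "attractiveness",              "polarity": 1}
]
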