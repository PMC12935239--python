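{
  "PT": {"100%": 102.37, "75%": 80.05, "50%": 57.07, "25%": 40.89, "0%": 16.99},
  "DK": {"100%": 97.9, "75%": 67.8, "50%": 43.0, "25%": 28.7, "0%": 2.3},
  "not_reproducible": {
    "PT": ["0%"],
    "DK": ["100%", "0%"]
  },
  "notes": [
    "Published global scores for PT 0%, DK 100% and DK 0% are not reproducible from the published partials and weights (recomputation gives about 16.35, 91.9 and -3.1 respectively); the remaining rows agree within +-0.05.",
    "The DK 100% overall score is also quoted as 97.7 in the source narrative versus 97.9 in its summary table.",
    "DK accessibility partials are blank in the source and contribute 0 points."
  ]
}
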