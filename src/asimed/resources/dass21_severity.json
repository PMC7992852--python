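{
  "comment": "Severity bands for doubled DASS-21 subscale scores (0-42 scale). Lower bounds are inclusive; each band runs to the next lower bound.",
  "doubled": true,
  "bands": ["normal", "mild", "moderate", "severe", "extremely_severe"],
  "lower_bounds": {
    "depression": [0, 10, 14, 21, 28],
    "anxiety": [0, 8, 10, 15, 20],
    "stress": [0, 15, 19, 26, 34]
  }
}
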