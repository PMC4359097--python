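{
  "label": "two underdominant rearrangements, s=0.05",
  "architecture": {
    "genome_map": {
      "n_chromosomes": 2
    },
    "pairs": [
      {
        "id": "pair0",
        "kind": "underdominant",
        "locusA": {
          "chromosome": 0,
          "position": 0.5
        },
        "s1": 0.05,
        "s2": 0.0,
        "hA": 0.5,
        "hB": 0.5,
        "s_adv": 0.0,
        "h_adv": 0.5
      },
      {
        "id": "pair1",
        "kind": "underdominant",
        "locusA": {
          "chromosome": 1,
          "position": 0.5
        },
        "s1": 0.05,
        "s2": 0.0,
        "hA": 0.5,
        "hB": 0.5,
        "s_adv": 0.0,
        "h_adv": 0.5
      }
    ]
  },
  "demography": {
    "demes": [
      {
        "label": "H",
        "capacity": 1000,
        "role": "hybrid",
        "founding_f": 0.5,
        "explicit": false
      }
    ],
    "edges": []
  },
  "lifecycle": {
    "brood_mean": 2.0,
    "max_broods": 10,
    "assort_reject_prob": 0.0,
    "max_mate_trials": 10
  },
  "run": {
    "generations": 2000
  }
}
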