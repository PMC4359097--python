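{
  "label": "2-pair swarm with 4Nm=8 immigration from each parent",
  "architecture": {
    "genome_map": {
      "n_chromosomes": 4
    },
    "pairs": [
      {
        "id": "pair0",
        "kind": "coevolving",
        "locusA": {
          "chromosome": 0,
          "position": 0.5
        },
        "locusB": {
          "chromosome": 1,
          "position": 0.5
        },
        "s1": 0.1,
        "s2": 0.1,
        "hA": 0.5,
        "hB": 0.5,
        "s_adv": 0.0,
        "h_adv": 0.5
      },
      {
        "id": "pair1",
        "kind": "coevolving",
        "locusA": {
          "chromosome": 2,
          "position": 0.5
        },
        "locusB": {
          "chromosome": 3,
          "position": 0.5
        },
        "s1": 0.1,
        "s2": 0.1,
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
        "label": "P1",
        "capacity": 1000,
        "role": "parental1",
        "founding_f": 0.5,
        "explicit": false
      },
      {
        "label": "H",
        "capacity": 1000,
        "role": "hybrid",
        "founding_f": 0.5,
        "explicit": false
      },
      {
        "label": "P2",
        "capacity": 1000,
        "role": "parental2",
        "founding_f": 0.5,
        "explicit": false
      }
    ],
    "edges": [
      {
        "source": "P1",
        "dest": "H",
        "rate": 0.002
      },
      {
        "source": "P2",
        "dest": "H",
        "rate": 0.002
      }
    ]
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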