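{
  "planted_mirnas": {
    "miR-1": 1.5,
    "miR-2": -1.5
  },
  "true_pairs": [
    [
      "miR-1",
      "GENE01"
    ],
    [
      "miR-1",
      "GENE02"
    ],
    [
      "miR-1",
      "GENE03"
    ],
    [
      "miR-2",
      "GENE04"
    ],
    [
      "miR-2",
      "GENE05"
    ],
    [
      "miR-2",
      "GENE06"
    ]
  ],
  "bridge": [
    "GENE01",
    "GENE05"
  ],
  "module_membership": {
    "GENE01": 1,
    "GENE04": 1,
    "GENE02": 1,
    "GENE05": 2,
    "GENE03": 2,
    "GENE06": 2
  },
  "seed": 2024
}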