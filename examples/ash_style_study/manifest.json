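{
  "adjacent_pairs": [
    [
      "CA",
      "EA"
    ],
    [
      "CA",
      "EU"
    ],
    [
      "CA",
      "JP"
    ],
    [
      "EA",
      "JP"
    ],
    [
      "ENA",
      "WNA"
    ]
  ],
  "areas": [
    "WNA",
    "ENA",
    "JP",
    "EU",
    "EA",
    "CA"
  ],
  "d": 0.015,
  "e": 0.005,
  "epoch_boundaries": [
    30.0,
    5.0
  ],
  "epoch_multipliers": [
    [
      [
        1.0,
        1.0,
        1.0,
        1.0,
        1.0,
        1.0
      ],
      [
        1.0,
        1.0,
        1.0,
        1.0,
        1.0,
        1.0
      ],
      [
        1.0,
        1.0,
        1.0,
        1.0,
        1.0,
        1.0
      ],
      [
        1.0,
        1.0,
        1.0,
        1.0,
        1.0,
        1.0
      ],
      [
        1.0,
        1.0,
        1.0,
        1.0,
        1.0,
        1.0
      ],
      [
        1.0,
        1.0,
        1.0,
        1.0,
        1.0,
        1.0
      ]
    ],
    [
      [
        1.0,
        1.0,
        1.0,
        0.5,
        1.0,
        1.0
      ],
      [
        1.0,
        1.0,
        1.0,
        1.0,
        1.0,
        1.0
      ],
      [
        1.0,
        1.0,
        1.0,
        1.0,
        1.0,
        1.0
      ],
      [
        0.5,
        1.0,
        1.0,
        1.0,
        1.0,
        1.0
      ],
      [
        1.0,
        1.0,
        1.0,
        1.0,
        1.0,
        1.0
      ],
      [
        1.0,
        1.0,
        1.0,
        1.0,
        1.0,
        1.0
      ]
    ],
    [
      [
        1.0,
        1.0,
        1.0,
        1.0,
        0.5,
        1.0
      ],
      [
        1.0,
        1.0,
        1.0,
        0.25,
        1.0,
        1.0
      ],
      [
        1.0,
        1.0,
        1.0,
        1.0,
        1.0,
        1.0
      ],
      [
        1.0,
        0.25,
        1.0,
        1.0,
        1.0,
        1.0
      ],
      [
        0.5,
        1.0,
        1.0,
        1.0,
        1.0,
        1.0
      ],
      [
        1.0,
        1.0,
        1.0,
        1.0,
        1.0,
        1.0
      ]
    ]
  ],
  "family": "DEC",
  "j": 0.0,
  "max_range_size": 6,
  "root_range": "WNA",
  "schema": 1,
  "seed": 1011
}
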