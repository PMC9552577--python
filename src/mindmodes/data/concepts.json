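[
  {
    "name": "blanket",
    "basis": {"labels": ["warm", "soft", "rectangular", "colorful", "cotton"]},
    "amplitudes": [0.62, 0.55, 0.4, 0.3, 0.25],
    "observations": ["warm", "soft", "rectangular", "colorful", "cotton"]
  },
  {
    "name": "island",
    "basis": {"labels": ["land", "water", "shoreline", "tropical", "finland"]},
    "amplitudes": [0.75, 0.62, 0.17, 0.1, 0.06],
    "observations": ["land", "water", "shoreline"]
  },
  {
    "name": "dog",
    "basis": {"labels": ["furry", "tail", "loyal", "bark", "rollover", "hunt", "smell"]},
    "amplitudes": [0.5292, 0.469, 0.3873, 0.3606, 0.3162, 0.2646, 0.2236],
    "observations": ["furry", "tail", "bark", "rollover", "hunt", "smell"]
  },
  {
    "name": "bird",
    "basis": {"labels": ["sparrow", "robin", "penguin", "animal", "feathers", "colorful", "nests", "tree"]},
    "amplitudes": [0.5477, 0.5, 0.2236, 0.2828, 0.3873, 0.2646, 0.2449, 0.2],
    "observations": ["sparrow", "robin", "penguin", "feathers", "colorful", "nests", "tree"]
  },
  {
    "name": "planet",
    "basis": {"labels": ["sphere", "round", "orbits", "mars", "bright_dot"]},
    "amplitudes": [0.6, 0.45, 0.5, 0.3, 0.3],
    "observations": ["bright_dot"]
  },
  {
    "name": "earth_globe",
    "basis": {"labels": ["ground", "sky", "sphere", "round", "blue"]},
    "amplitudes": [0.7, 0.5, 0.35, 0.3, 0.2],
    "observations": ["ground", "sky", "blue"]
  }
]
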