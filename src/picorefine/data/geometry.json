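{
  "comment": "Minimal geometry-restraint dictionary for the toy residue types: bond ideals (A) and angle ideals (deg) with sigmas. Synthetic stand-in covering only the residues the toy generator emits.",
  "nonbonded": {"min_distance": 2.2, "sigma": 0.2},
  "residues": {
    "GLY": {
      "atoms": {"N": "N", "CA": "C", "C": "C", "O": "O"},
      "bonds": [
        ["N", "CA", 1.47, 0.02],
        ["CA", "C", 1.52, 0.02],
        ["C", "O", 1.23, 0.02]
      ],
      "angles": [
        ["N", "CA", "C", 110.4, 2.0],
        ["CA", "C", "O", 120.8, 2.0]
      ]
    },
    "LIG": {
      "atoms": {"C1": "C", "C2": "C", "S1": "S"},
      "bonds": [
        ["C1", "C2", 1.54, 0.02],
        ["C2", "S1", 1.81, 0.025]
      ],
      "angles": [
        ["C1", "C2", "S1", 112.0, 2.5]
      ]
    },
    "HOH": {
      "atoms": {"O": "O"},
      "bonds": [],
      "angles": []
    }
  }
}
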