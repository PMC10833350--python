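{
  "version": "1.0",
  "comment": "Ideal protein backbone covalent geometry (Engh-Huber-style target values) used by the chain builder and the geometry outlier flag. Lengths in Angstrom, angles in degrees.",
  "bonds": {
    "N-CA": {"mean": 1.458, "sigma": 0.019},
    "CA-C": {"mean": 1.525, "sigma": 0.021},
    "C-N": {"mean": 1.329, "sigma": 0.014},
    "C-O": {"mean": 1.231, "sigma": 0.020},
    "CA-CB": {"mean": 1.530, "sigma": 0.020}
  },
  "angles": {
    "N-CA-C": {"mean": 111.0, "sigma": 2.7},
    "CA-C-N": {"mean": 117.2, "sigma": 2.2},
    "C-N-CA": {"mean": 121.7, "sigma": 2.5},
    "CA-C-O": {"mean": 120.1, "sigma": 2.1},
    "N-CA-CB": {"mean": 110.5, "sigma": 1.7}
  }
}
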