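{
  "version": "1.0",
  "comment": "Coarse Ramachandran basin polygons for wrong-minimum detection. These identify basins, not outlier contours: alpha covers the right-handed helical well, beta the extended upper-left basin (including its psi wrap near -180), left_alpha the positive-phi well. Everything else is 'other'. Vertices are (phi, psi) in degrees; first matching region in 'order' wins.",
  "order": ["alpha", "beta", "left_alpha"],
  "regions": {
    "alpha": [[[-180, -100], [-20, -100], [-20, 60], [-180, 60]]],
    "beta": [
      [[-180, 60], [-20, 60], [-20, 180], [-180, 180]],
      [[-180, -180], [-20, -180], [-20, -150], [-180, -150]]
    ],
    "left_alpha": [[[0, -60], [90, -60], [90, 100], [0, 100]]]
  }
}
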