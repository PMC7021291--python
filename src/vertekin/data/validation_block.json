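{
 "description": "Synthetic rigid validation block: six 1.6 mm beads forming two orthogonal 3-bead coordinate systems with an exactly known offset. Bead spacing 12-18 mm, chosen to mimic vertebral RSA bead placement. Synthetic stand-in: not the coordinates of any physical block.",
 "units": "mm",
 "bead_diameter_mm": 1.6,
 "beads": [
  [0.0, 0.0, 0.0],
  [15.0, 0.0, 0.0],
  [0.0, 15.0, 0.0],
  [25.0, 5.0, 10.0],
  [25.0, 19.0, 10.0],
  [25.0, 5.0, 24.0]
 ],
 "frameA_ids": [0, 1, 2],
 "frameB_ids": [3, 4, 5]
}
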