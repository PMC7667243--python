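# Canonical "pidot-v1" threshold set for the manual-gating engine.
#
# cuts: per marker, the (neg|lo, lo|pos, pos|hi) cut points in transformed
# (asinh, cofactor 150) units.  With the default band model (band means
# 0 / 1.5 / 3.0 / 4.5) the cuts sit at the band midpoints.
version: pidot-v1
cofactor: 150.0
cuts:
  CD45:      [0.75, 2.25, 3.75]
  CD3:       [0.75, 2.25, 3.75]
  CD19:      [0.75, 2.25, 3.75]
  CD16&CD56: [0.75, 2.25, 3.75]
  CD4:       [0.75, 2.25, 3.75]
  CD8:       [0.75, 2.25, 3.75]
  TCRgd:     [0.75, 2.25, 3.75]
  CD27:      [0.75, 2.25, 3.75]
  CD45RA:    [0.75, 2.25, 3.75]
  IgM:       [0.75, 2.25, 3.75]
  IgD:       [0.75, 2.25, 3.75]
# Lymphocyte scatter rectangle (raw channel units); events below the FSC-A
# floor count as debris.
lymphocyte_gate:
  fsc_a: [20000, 95000]
  ssc_a: [1000, 30000]
doublet_ratio_tolerance: 0.25
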