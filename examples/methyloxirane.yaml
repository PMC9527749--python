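# Full pipeline example: the printed (R)-2-methyloxirane CH parameter set
# with seeded synthetic placeholder tensors (the published tensor scans are
# not available as numbers).  Run from this directory:
#
#     lmvcd run methyloxirane.yaml
#
# Outputs land in ./out: a line list, one spectrum per CH region (text +
# JCAMP-DX), and a log echoing every toggle and constant.

seed: 1
quanta: [1, 2, 3]
mechanical: true
electrical_order: 2
output:
  directory: out
  prefix: meox
  jcamp: true
bonds:
  - {label: C5-H6,  omega0: 3115.01, chi: 62.28, direction: [0.00,  0.82,  0.57], tensors_seed: 61}
  - {label: C2-H4,  omega0: 3145.23, chi: 61.17, direction: [0.94, -0.23,  0.25], tensors_seed: 62}
  - {label: C2-H3,  omega0: 3139.60, chi: 61.26, direction: [0.41, -0.41, -0.82], tensors_seed: 63}
  - {label: C7-H8,  omega0: 3089.49, chi: 59.39, direction: [-0.82, 0.41,  0.41], tensors_seed: 64}
  - {label: C7-H9,  omega0: 3107.14, chi: 59.34, direction: [-0.41, -0.82, 0.41], tensors_seed: 65}
  - {label: C7-H10, omega0: 3091.87, chi: 59.91, direction: [-0.57, 0.00, -0.82], tensors_seed: 66}
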