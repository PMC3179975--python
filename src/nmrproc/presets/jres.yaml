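# 2D J-resolved preset (documentation of the recommended parameters; the
# 2D path is driven from the library API: process_jres -> tilt_jres ->
# project).  F2 window: SEM (shifted sine times exponential); F1: squared
# cosine; skyline projection after tilting.
inputs: []
output: processed-jres
format: auto
seed: 0
steps:
  - op: zero_fill
    factor: 2
  - op: apodize
    kind: sem
    lb: 0.5
  - op: fourier_transform
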