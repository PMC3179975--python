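# HSQC preset (documentation of the recommended parameters; the 2D path is
# driven from the library API: process_hsqc with squared-cosine windows in
# both dimensions, then library assignment via nmrproc assign).
inputs: []
output: processed-hsqc
format: auto
seed: 0
steps:
  - op: zero_fill
    factor: 2
  - op: apodize
    kind: cos2
  - op: fourier_transform
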