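# Default 1D batch preset: zero-fill x2, mild exponential apodization,
# Fourier transform, automated phasing, TMSP referencing, then series
# post-processing (baseline over shared anchors, water/edge exclusion,
# total-area scaling, re-alignment to the first spectrum, glog) and export.
# Replace `inputs`/`output` (and the baseline anchors) for your data.
inputs: []
output: processed
format: auto
seed: 0
steps:
  - op: zero_fill
    factor: 2
  - op: apodize
    kind: em
    lb: 0.3
  - op: gibbs_correct
  - op: fourier_transform
  - op: autophase
    algorithm: auto
  - op: reference
    standard: TMSP
  - op: baseline_spline
    baseline_points: [9.8, 8.9, 7.6, 6.5, 5.8, 4.3, 3.6, 2.7, 1.7, 0.7, -0.4]
    baseline_average_points: 5
  - op: exclude_regions
    regions: [[4.5, 5.1], [9.5, 11.0], [-2.0, -0.5]]
  - op: scale_total_area
  - op: align_to_reference
    ref_index: 0
  - op: glog
    lam: auto
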