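# nmrproc

Reproducible processing and analysis of NMR metabolomics spectra: batch
processing of series of 1D and 2D spectra (apodization, Fourier transform,
automated phasing, referencing), series-level post-processing for
statistics (spline baseline, alignment, normalisation, glog transform,
bucketing, matrix export), and library-driven assignment of 1H,13C-HSQC
spectra.  Everything is scriptable, every step is recorded, and identical
inputs always reproduce identical outputs — the properties multivariate
analysis of large spectral series depends on.

Who it is for: metabolomics practitioners who need to take tens to
hundreds of free induction decays from the spectrometer to a
statistics-ready data matrix without a GUI in the loop, and method
developers who need a fully synthetic, ground-truth-bearing test bed for
NMR processing algorithms.

## What is inside

- **`nmrproc.synthetic`** — parametric generators for every input the
  suite handles: 1D FIDs built from Lorentzian line lists (with planted
  phase errors, polynomial baselines, solvent residual, TMSP with its
  carbon-13 satellites), J-resolved and echo/anti-echo HSQC datasets, and
  multi-spectrum series with known dilutions/shifts/classes; plus writers
  for the two supported on-disk dialects (see `docs/formats.md`).
- **`nmrproc.proc1d`** — zero filling, `em`/`cos2`/`sem` windows, first
  point (Gibbs) and DC corrections, time-domain solvent filters, Fourier
  transform, manual phasing, and two automated phasers: one anchored on
  the TMSP signal and its satellites (zero + first order), one using
  signal-free strips at both spectrum edges (zero order).  Referencing to
  TMS/TMSP/DSS or, failing that, to the temperature-dependent water shift.
- **`nmrproc.proc2d`** — absorption-mode reconstruction of echo/anti-echo
  HSQC data, J-resolved processing, 45-degree tilt, skyline/sum
  projections.
- **`nmrproc.postproc`** — exclusions and class labels, shared-anchor
  spline baseline, alignment to TMSP or to a reference spectrum,
  total-area / probabilistic-quotient / TMSP scaling, glog with automated
  lambda optimisation, Pareto/autoscaling, bucketing.
- **`nmrproc.assign`** — region-of-interest peak picking against a
  metabolite shift library, duplicate/ambiguity flagging, assignment
  transfer between spectra, intensity tables across series.
- **`nmrproc.pipeline` / `nmrproc` CLI** — declarative YAML pipelines
  validated before execution, batch runs with content-hash logs, and
  emission of stand-alone editable Python runners.

## The core statistics, briefly

For a spectral series X (spectra x points), dilution is corrected by
probabilistic quotient normalisation: after total-area scaling, each
spectrum is divided by median_j(x_ij / ref_j) where ref is the pointwise
median spectrum.  Heteroscedastic peak-dominated variance is stabilised by
the generalised logarithm y = ln(x + sqrt(x^2 + lambda)); lambda is chosen
to maximise the total between-spectrum variance of the transformed,
sum-normalised matrix over a log-spaced grid with golden-section
refinement.  Automated phasing minimises a baseline-flatness objective
(squared deviation of the real part from a local straight line over
signal-free windows) anchored between the TMSP signal and its carbon-13
satellites.  Details and assumptions: `docs/methods.md`.

## Worked example

Generate a synthetic two-class series, process it with the shipped 1D
preset, and export the data matrix:

```sh
nmrproc generate --out demo/data --n 10 --seed 1
nmrproc preset 1d --out demo/pipeline.yaml
# edit demo/pipeline.yaml: point `inputs` at demo/data/spectrum_*, set
# `classes` from demo/data/classes.txt and `output: demo/out`
nmrproc process demo/pipeline.yaml
```

which prints (hash identical on every rerun):

```
matrix: demo/out/matrix.csv
matrix.csv  sha256:5a1accbafd8b8f6bae566d718d18d4749ae26afd8efad85900e0c11b8fd63d72
```

`demo/out/matrix.csv` holds one row per spectrum (`id,class,...`) and one
column per included axis point, ready for PCA/PLS; `demo/out/run_log.json`
records every step with its parameters and the output hashes.  The same
run is available from Python:

```python
from nmrproc.pipeline import run_pipeline
result = run_pipeline("demo/pipeline.yaml")
print(result.hashes)           # {'matrix.csv': '5a1accbafd8b...'}
print(result.series.matrix.shape)  # (10, 16384)
```

For HSQC work, `nmrproc assign --echo-dir ... --antiecho-dir ...
--metabolite glutamate` processes an echo/anti-echo pair, picks the
closest local maximum inside a tolerance box around each library shift,
and prints picked positions, intensities and duplicate/ambiguity flags.

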