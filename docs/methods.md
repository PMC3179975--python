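# Methods

This note records the models, conventions and numerical choices behind
`nmrproc`, in the order data flow through the package.

## Signal model and axis conventions

A 1D free induction decay (FID) is modelled as a sum of exponentially
damped complex oscillations sampled at `t = k/sw_hz`:

    s(k) = sum_lines A * exp(2*pi*i*f_rel*k*dt) * exp(-pi*lw*k*dt)

where `f_rel` is the line's offset from the transmitter in Hz and `lw` its
Lorentzian full width at half maximum in Hz — the decay constant `pi*lw`
makes the transformed line's FWHM exactly `lw`, which every linewidth test
exploits through an independent Lorentzian least-squares fit.

The discrete Fourier transform is unnormalised
(`sum|fid|^2 = (1/N) sum|spec|^2`) and reordered so point `j` of the
spectrum sits at

    ppm[j] = o1_ppm + (sw_hz/2 - j*sw_hz/N) / sf_mhz ,

a strictly decreasing axis with the carrier at the centre index.  A
scalar-coupled line is a static doublet at +-J/2; no coupling evolution or
relaxation beyond the monoexponential decay is simulated.  The reference
standard (TMSP) carries carbon-13 satellites as two lines at +-59 Hz
(half the one-bond C-H coupling, taken as 118 Hz) holding a configurable
fraction of the parent amplitude (default 1.1%, natural abundance).

Planted phase errors are applied in the frequency domain — multiply the
ideal spectrum by `exp(i*(phi0 + phi1*(ppm-pivot)/sw_ppm))` and transform
back — so the ground truth for phase recovery is exact to machine
precision, not merely approximate.  Polynomial baselines are likewise
synthesised in the frequency domain and carried to the time domain by the
inverse transform, making baseline ground truth exact as well.

## Window functions

- `em`: `exp(-pi*lb*k*dt)`, line broadening `lb` in Hz (1D default).
- `cos2`: `cos^2(pi*k/(2(N-1)))` (2D default in both dimensions).
- `sem`: `sin(pi*(k+1)/(N+1)) * exp(-pi*lb*k*dt)` — shifted sine times
  exponential, available for J-resolved direct dimensions.

The first time-domain point is halved inside the 2D transform (and
available as `gibbs_correct` for 1D) to cancel the constant offset the
k = 0 term of the DFT spreads across the spectrum.

## Automated phase correction

The phasing objective operationalises baseline flatness: over a set of
signal-free index windows, the squared deviation of the real part from
each window's own least-squares straight line, each window normalised by
its mean squared magnitude (a phase-invariant scale) so weak windows count
as much as strong ones.

`autophase_tmsp` uses three windows: the strips between the TMSP parent
and each of its satellites (15%–85% of the parent-satellite distance on
both sides), and a strip at the downfield end.  When a clear downfield
peak exists, the strip between the spectrum edge and that peak is used
instead of a fixed strip — the peak's dispersion leakage makes the local
phase there sharply defined and its sign checkable.  The algorithm first
estimates the local phase angle at TMSP and at the downfield anchor by a
5-degree grid plus bounded scalar refinement, resolves the 180-degree
flatness ambiguity by requiring the anchor peaks positive, solves the
two-point linear system for `(phi0, phi1)` choosing the branch with the
smallest |phi1| (neighbouring branches lie ~200 degrees away, far outside
the moderate errors the method targets), and polishes both angles with a
bounded Nelder-Mead on the joint objective.  The first-order pivot is the
carrier (spectrum centre).  `autophase_ends` runs the same machinery with
only a zero-order angle over 5% strips at both spectrum edges, resolving
the sign toward positive total intensity.

Residual recovery error is a small systematic bias (~0.3 degrees
zero-order, ~0.5 degrees first-order at 16k points) caused by the
curvature of discrete truncated-Lorentzian tails inside the fit windows;
it shrinks with acquisition length and is independent of the planted
error.  Heavily truncated FIDs (acquisition times so short the decay
retains more than ~10% at the end) bias the estimate by several degrees —
apodize or acquire longer.

## Solvent suppression

`water_filter` estimates the on-resonance component by convolving the FID
(reflect edge handling) with a rectangular kernel of half-width
`sw/width_hz` points, or a Gaussian whose frequency response has FWHM
`width_hz`, and subtracts it: a time-domain high-pass centred on the
carrier.  The rectangular kernel's sinc sidelobes perturb resonances
~500 Hz off-carrier by ~1%; the Gaussian kernel is smoother but wider.

## Referencing

`reference_to_standard` shifts the axis so the strongest real maximum in
the search window (default +-0.5 ppm) lands exactly at 0 ppm; a peak must
be an interior window maximum at least 10x the window median, which
rejects smooth tails leaking in from outside.  Without a standard,
`reference_to_water` assumes the transmitter sat on the water resonance
and places the axis centre at the temperature-dependent water shift

    delta_w(T) = 5.060 - 0.0122*T + 2.11e-5*T^2   (T in Celsius),

isolated in `water_shift_ppm` so a different calibration can be swapped in.

## 2D processing

HSQC echo/anti-echo pairs are recombined as `cos = (AE + E)/2`,
`sin = (AE - E)/(2i)`; after the direct-dimension transform the two real
parts form the complex indirect interferogram whose transform's real part
is pure 2D absorption.  J-resolved data are generated as cosine/sine
amplitude-modulated t1 channels and processed the same way, yielding
absorption-mode J-res spectra; this choice (rather than magnitude-mode
processing of a single phase-twisted channel) is what makes the tilt's
intensity-conservation property meaningful at the 1e-6 level, since
absorption tails fall off quadratically while magnitude tails fall off
only linearly.  Whether to tilt before or after apodization is a free
choice; here the full 2D transform happens first, then the tilt.

The tilt shears each F1 row by its own frequency along F2 with linear
interpolation (out-of-range points are zero, no wrap).  Linear
interpolation smooths at the grid scale: a tilt/untilt round trip on a
peak a few points wide loses ~5–10% of peak height, so conservation is
stated for integrals, not maxima.  Projections are per-column maximum
(skyline) or sum.

## Series post-processing

Operations record themselves in `post_state`; replaying the records on the
raw series reproduces the final matrix bit-exactly.  The shipped default
order is baseline -> exclusions -> total-area scaling -> alignment to a
reference -> quotient/TMSP normalisation -> transform -> bucketing.

- **Baseline**: one shared set of anchor ppm positions for the whole
  series (reducing between-spectrum variability); each spectrum's anchor
  value is the mean over an odd window (`baseline_average_points`,
  truncated at axis edges), interpolated by a natural cubic spline and
  subtracted.  Anchor gaps wider than `linear_points` grid points may be
  bridged linearly instead.
- **Alignment**: global integer-point circular shifts only, either moving
  each spectrum's TMSP maximum to 0 ppm or maximising cross-correlation
  with a reference spectrum over included points (ties go to the smallest
  |shift|, then the more negative lag).  No segmental warping.
- **Normalisation**: total-area scaling divides by the sum over included
  points.  Quotient normalisation (PQN) area-scales first, takes the
  pointwise median of included spectra as reference, and divides each
  spectrum by the median of its point quotients against that reference
  (nonpositive reference points ignored); the recorded "combined" factor
  (area x quotient) is proportional to the sample dilution.  PQN is meant
  to run after signal-free regions are excluded — quotients at pure-noise
  points carry no dilution information and would swamp the median.
- **glog**: `y = ln((x-y0) + sqrt((x-y0)^2 + lambda))`.  The lambda
  optimiser maximises the total between-spectrum column variance of the
  transformed matrix after rescaling it to unit total sum (making the
  objective comparable across lambda): a log-spaced grid (default
  1e-12..1e2, 8 points/decade) followed by bounded golden-section
  refinement between the argmax's neighbours, never returning anything
  worse than the grid argmax.  The normalisation inside the objective is
  one documented choice among several defensible ones and is isolated in
  a single function; manual lambda override is always available.
- **Pareto/autoscale**: column-wise `(x-mean)/sqrt(sd)` and
  `(x-mean)/sd`; zero-variance columns are centred only, with a warning.
- **Bucketing**: fixed-width contiguous buckets, value = sum of member
  points (so total included intensity is conserved exactly), axis = bucket
  centre; runs of included points are bucketed independently so no bucket
  straddles an exclusion boundary.

## HSQC assignment

A region of interest is a tolerance box (defaults 0.03 ppm 1H, 0.3 ppm
13C) around a library position.  The pick is the strict 8-neighbourhood
local maximum inside the box closest to the centre in
tolerance-normalised distance, ties (within 1e-9) resolved toward higher
intensity; plateau points never qualify.  Reported intensity is the grid
value at the picked point — no volume integration or shape fitting.
Ambiguity (another library entry's box containing the pick) and
duplicates (two assignments picking one grid point) are flagged, never
silently resolved.  Transfer re-picks each assignment on a target spectrum
using the source pick as the new box centre, absorbing small global
shifts such as pH-induced ones.

## Synthetic data: what it does and does not emulate

The generator produces multi-spectrum series with class labels, dilution
factors, per-spectrum axis jitter, planted phase errors, polynomial
baselines, additive complex Gaussian noise, a solvent residual (broad line
on the carrier) and a TMSP reference with satellites — the distortions the
post-processing pipeline exists to remove, each with exact ground truth.
It does not simulate coupling evolution, relaxation dispersion,
temperature drift within a series, lineshape asymmetry, radiation damping
or t1 noise.  Passing tests therefore demonstrate that each correction
removes the artifact class it targets and that the pipeline is
deterministic and reconstructable; they do not certify performance on
artifacts outside this model (e.g. non-polynomial rolling baselines or
segmentally misaligned spectra).

## Problem sizes and defaults

Tests and the acceptance script use 8k–16k complex points for 1D spectra
(typical of 1D metabolomics acquisitions; the automated phaser's bias
grows on much shorter FIDs), 2048 x 128 J-resolved grids, 2048 x 512 HSQC
grids, and series of 10–20 spectra — sizes at which every check runs in
seconds while all quoted tolerances hold with wide margins.
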