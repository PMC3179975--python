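"""Series-level post-processing for statistics.

Operates on a :class:`~nmrproc.core.SpectrumSeries`: exclusion of axis
regions and spectra, class labels, spline baseline correction with shared
anchor points, alignment (to TMSP or to a reference spectrum), scaling
(total area, probabilistic quotient, TMSP integral), variance-stabilising
transforms (glog with automated lambda optimisation, Pareto, autoscaling)
and fixed-width bucketing.  Every step appends to ``series.post_state`` so
the processed matrix can be reconstructed from the raw series by replay.

The shipped default order is: baseline -> exclusions -> total-area scaling
-> alignment to a reference -> quotient/TMSP normalisation -> transform ->
bucketing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar

from .core import SpectrumSeries

__all__ = [
    "BaselineSplineParams",
    "GlogParams",
    "exclude_regions",
    "exclude_spectra",
    "include_spectra",
    "assign_classes",
    "baseline_spline",
    "align_to_tmsp",
    "align_to_reference",
    "scale_total_area",
    "scale_pqn",
    "scale_to_tmsp",
    "glog",
    "glog_transform",
    "optimize_glog_lambda",
    "pareto",
    "autoscale",
    "bucket",
]


@dataclass(frozen=True)
class BaselineSplineParams:
    """Shared spline-baseline anchors for a whole series.

    ``baseline_points``: anchor positions (ppm), identical for every
    spectrum of the series so the correction introduces no extra
    between-spectrum variability.  ``baseline_average_points``: odd number
    of grid points averaged around each anchor to form its value.
    ``linear``: where True, anchor gaps wider than ``linear_points`` grid
    points are bridged by a straight line instead of the cubic spline.
    """

    baseline_points: tuple
    baseline_average_points: int = 1
    linear: bool = False
    linear_points: int = 0

    def __post_init__(self) -> None:
        if self.baseline_average_points < 1 or self.baseline_average_points % 2 == 0:
            raise ValueError("baseline_average_points must be an odd integer >= 1")
        if len(self.baseline_points) < 4:
            raise ValueError("need >= 4 baseline points for a cubic spline")


@dataclass(frozen=True)
class GlogParams:
    """Generalised-log parameters: ``lam`` (> 0) and optional offset ``y0``."""

    lam: float
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("glog lambda must be > 0")


# ---------------------------------------------------------------------------
# exclusions and classes


def exclude_regions(series: SpectrumSeries, regions) -> SpectrumSeries:
    """Flag ppm intervals as excluded (union with previous exclusions)."""
    mask = series.included_mask.copy()
    for lo, hi in regions:
        if lo > hi:
            raise ValueError(f"inverted interval ({lo}, {hi})")
        mask &= ~((series.ppm >= lo) & (series.ppm <= hi))
    return series.evolve("exclude_regions",
                         {"regions": [(float(a), float(b)) for a, b in regions]},
                         included_mask=mask)


def exclude_spectra(series: SpectrumSeries, ids) -> SpectrumSeries:
    inc = series.included_spectra.copy()
    for i in ids:
        if not 0 <= i < series.n_spectra:
            raise ValueError(f"unknown spectrum id {i}")
        inc[i] = False
    return series.evolve("exclude_spectra", {"ids": [int(i) for i in ids]},
                         included_spectra=inc)


def include_spectra(series: SpectrumSeries, ids) -> SpectrumSeries:
    inc = series.included_spectra.copy()
    for i in ids:
        if not 0 <= i < series.n_spectra:
            raise ValueError(f"unknown spectrum id {i}")
        inc[i] = True
    return series.evolve("include_spectra", {"ids": [int(i) for i in ids]},
                         included_spectra=inc)


def assign_classes(series: SpectrumSeries, labels) -> SpectrumSeries:
    if len(labels) != series.n_spectra:
        raise ValueError("one class label per spectrum required")
    return series.evolve("assign_classes", {"labels": [str(l) for l in labels]},
                         classes=[str(l) for l in labels])


# ---------------------------------------------------------------------------
# baseline


def _anchor_indices(series: SpectrumSeries, points) -> np.ndarray:
    idx = np.array([int(np.argmin(np.abs(series.ppm - p))) for p in points])
    return np.sort(np.unique(idx))


def baseline_spline(series: SpectrumSeries, params: BaselineSplineParams) -> SpectrumSeries:
    """Subtract a per-spectrum natural cubic spline through shared anchors.

    Each anchor value is the mean of ``baseline_average_points`` points
    centred on the anchor (window truncated at the axis edges).  With
    ``linear=True``, segments between anchors further apart than
    ``linear_points`` grid points use straight-line interpolation.
    """
    idx = _anchor_indices(series, params.baseline_points)
    if len(idx) < 4:
        raise ValueError("need >= 4 distinct anchor grid points for a cubic spline")
    half = params.baseline_average_points // 2
    n = len(series.ppm)
    x = np.arange(n, dtype=float)
    mat = series.matrix.copy()
    for row in range(series.n_spectra):
        y = series.matrix[row]
        anchors = np.array([
            float(np.mean(y[max(0, i - half): min(n, i + half + 1)])) for i in idx
        ])
        spline = CubicSpline(idx.astype(float), anchors, bc_type="natural")
        base = spline(x)
        if params.linear and params.linear_points > 0:
            for a, b in zip(idx[:-1], idx[1:]):
                if b - a > params.linear_points:
                    seg = slice(a, b + 1)
                    base[seg] = np.interp(x[seg], [a, b],
                                          [base[a], base[b]])
        mat[row] = y - base
    return series.evolve(
        "baseline_spline",
        {"baseline_points": [float(p) for p in params.baseline_points],
         "baseline_average_points": params.baseline_average_points,
         "linear": params.linear, "linear_points": params.linear_points},
        matrix=mat)


# ---------------------------------------------------------------------------
# alignment (global integer-point shifts; circular)


def _roll_rows(matrix: np.ndarray, shifts) -> np.ndarray:
    out = matrix.copy()
    for i, s in enumerate(shifts):
        if s:
            out[i] = np.roll(matrix[i], int(s))
    return out


def align_to_tmsp(series: SpectrumSeries,
                  search_window_ppm: tuple[float, float] = (-0.3, 0.3)) -> SpectrumSeries:
    """Shift every spectrum by an integer number of points so its TMSP
    maximum lands on the grid point nearest 0.00 ppm."""
    lo, hi = min(search_window_ppm), max(search_window_ppm)
    sel = np.where((series.ppm >= lo) & (series.ppm <= hi))[0]
    if len(sel) == 0:
        raise ValueError("TMSP search window contains no axis points")
    target = int(np.argmin(np.abs(series.ppm)))
    shifts = []
    for i in range(series.n_spectra):
        y = series.matrix[i, sel]
        med = np.median(y)
        mad = np.median(np.abs(y - med)) or 1e-300
        if np.max(y) < 5.0 * mad:
            raise ValueError(f"no TMSP maximum found in spectrum {i}")
        peak = sel[int(np.argmax(y))]
        shifts.append(target - peak)
    mat = _roll_rows(series.matrix, shifts)
    return series.evolve("align_to_tmsp", {"shifts": [int(s) for s in shifts]},
                         matrix=mat)


def align_to_reference(series: SpectrumSeries, ref_index: int = 0,
                       max_shift: int = 100) -> SpectrumSeries:
    """Shift each spectrum to maximise its cross-correlation with the
    reference spectrum over included points; ties resolved toward the
    smallest |shift|, then the more negative lag."""
    if not series.included_spectra[ref_index]:
        raise ValueError(f"reference spectrum {ref_index} is excluded")
    mask = series.included_mask
    ref = series.matrix[ref_index]
    lags = np.arange(-max_shift, max_shift + 1)
    order = np.argsort(np.abs(lags) * 2 + (lags > 0))  # |lag| asc, neg first
    shifts = []
    for i in range(series.n_spectra):
        row = series.matrix[i]
        best_lag, best_c = 0, -np.inf
        for lag in lags[order]:
            c = float(np.dot(ref[mask], np.roll(row, lag)[mask]))
            if c > best_c:
                best_lag, best_c = int(lag), c
        shifts.append(best_lag)
    mat = _roll_rows(series.matrix, shifts)
    return series.evolve("align_to_reference",
                         {"ref_index": int(ref_index), "max_shift": int(max_shift),
                          "shifts": [int(s) for s in shifts]},
                         matrix=mat)


# ---------------------------------------------------------------------------
# scaling


def _apply_factors(series: SpectrumSeries, factors, op: str, extra=None) -> SpectrumSeries:
    mat = series.matrix.copy()
    for i, f in enumerate(factors):
        if series.included_spectra[i]:
            mat[i] = mat[i] / f
    params = {"factors": [float(f) for f in factors]}
    if extra:
        params.update(extra)
    return series.evolve(op, params, matrix=mat)


def scale_total_area(series: SpectrumSeries) -> SpectrumSeries:
    """Divide each included spectrum by the sum of its included points."""
    mask = series.included_mask
    if not np.any(mask):
        raise ValueError("no included axis points to scale on")
    factors = np.ones(series.n_spectra)
    for i in range(series.n_spectra):
        if not series.included_spectra[i]:
            continue
        total = float(np.sum(series.matrix[i, mask]))
        if total <= 0:
            raise ValueError(f"nonpositive total spectral area in spectrum {i}")
        factors[i] = total
    return _apply_factors(series, factors, "scale_total_area")


def scale_pqn(series: SpectrumSeries) -> SpectrumSeries:
    """Probabilistic quotient normalisation.

    Total-area scaling first; the reference is the pointwise median of the
    included, area-scaled spectra; each spectrum is divided by the median
    of its point quotients against the reference (points with nonpositive
    reference ignored).  The recorded per-spectrum factor is the combined
    divisor (area x quotient), i.e. proportional to the sample dilution.
    """
    if int(np.sum(series.included_spectra)) < 2:
        raise ValueError("PQN needs at least 2 included spectra")
    scaled = scale_total_area(series)
    area_factors = np.asarray(scaled.post_state[-1][1]["factors"])
    mask = scaled.included_mask
    sub = scaled.matrix[np.ix_(scaled.included_spectra, mask)]
    ref = np.median(sub, axis=0)
    good = ref > 0
    if not np.any(good):
        raise ValueError("degenerate PQN reference (no positive points)")
    quotients = np.ones(series.n_spectra)
    for i in range(series.n_spectra):
        if not scaled.included_spectra[i]:
            continue
        q = scaled.matrix[i, mask][good] / ref[good]
        quotients[i] = float(np.median(q))
        if quotients[i] <= 0:
            raise ValueError(f"nonpositive PQN quotient for spectrum {i}")
    out = _apply_factors(scaled, quotients, "scale_pqn",
                         {"combined_factors":
                          [float(a * q) for a, q in zip(area_factors, quotients)]})
    return out


def scale_to_tmsp(series: SpectrumSeries,
                  window_ppm: tuple[float, float] = (-0.05, 0.05)) -> SpectrumSeries:
    """Divide each spectrum by its TMSP integral (sum over the window
    around 0 ppm)."""
    lo, hi = min(window_ppm), max(window_ppm)
    sel = (series.ppm >= lo) & (series.ppm <= hi)
    if not np.any(sel):
        raise ValueError("TMSP integration window contains no axis points")
    factors = np.ones(series.n_spectra)
    for i in range(series.n_spectra):
        if not series.included_spectra[i]:
            continue
        integral = float(np.sum(series.matrix[i, sel]))
        if integral <= 0:
            raise ValueError(f"nonpositive TMSP integral in spectrum {i}")
        factors[i] = integral
    return _apply_factors(series, factors, "scale_to_tmsp",
                          {"window_ppm": (float(lo), float(hi))})


# ---------------------------------------------------------------------------
# transforms


def glog(x, lam: float, y0: float = 0.0):
    """Generalised logarithm y = ln((x - y0) + sqrt((x - y0)^2 + lambda))."""
    z = np.asarray(x, dtype=float) - y0
    return np.log(z + np.sqrt(z * z + lam))


def glog_transform(series: SpectrumSeries, params: GlogParams) -> SpectrumSeries:
    mat = series.matrix.copy()
    mat[series.included_spectra] = glog(mat[series.included_spectra],
                                        params.lam, params.y0)
    return series.evolve("glog_transform", {"lam": params.lam, "y0": params.y0},
                         matrix=mat)


def _glog_objective(sub: np.ndarray, lam: float, y0: float) -> float:
    """Total column variance of the glog-transformed matrix after rescaling
    it to unit total sum, making values comparable across lambda."""
    y = glog(sub, lam, y0)
    total = float(np.sum(y))
    if total == 0.0:
        return -np.inf
    y = y / total
    return float(np.sum(np.var(y, axis=0)))


def optimize_glog_lambda(series: SpectrumSeries, lambda_grid=None,
                         y0: float = 0.0) -> GlogParams:
    """Choose the glog lambda maximising the between-spectrum variance of
    the transformed series.

    The objective is evaluated on a log-spaced grid (default 1e-12..1e2,
    8 points per decade) and the grid argmax is refined by a bounded
    golden-section search on log10(lambda).  The result is a starting
    point that can be overridden manually.
    """
    sub = series.included_submatrix()
    if sub.shape[0] < 2:
        raise ValueError("glog optimisation needs >= 2 included spectra")
    if float(np.ptp(sub)) == 0.0:
        raise ValueError("constant matrix: glog objective is flat")
    if lambda_grid is None:
        lambda_grid = np.logspace(-12, 2, 14 * 8 + 1)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    vals = np.array([_glog_objective(sub, lam, y0) for lam in lambda_grid])
    if not np.any(np.isfinite(vals)):
        raise ValueError("glog objective undefined on the whole grid")
    k = int(np.argmax(vals))
    lo = lambda_grid[max(0, k - 1)]
    hi = lambda_grid[min(len(lambda_grid) - 1, k + 1)]
    if lo == hi:
        return GlogParams(float(lambda_grid[k]), y0)
    res = minimize_scalar(lambda t: -_glog_objective(sub, 10.0 ** t, y0),
                          bounds=(np.log10(lo), np.log10(hi)), method="bounded",
                          options={"xatol": 1e-6})
    lam_ref = float(10.0 ** res.x)
    # refinement never returns anything worse than the grid argmax
    if _glog_objective(sub, lam_ref, y0) < vals[k]:
        lam_ref = float(lambda_grid[k])
    return GlogParams(lam_ref, y0)


def _column_moments(series: SpectrumSeries):
    sub = series.matrix[series.included_spectra]
    mean = np.mean(sub, axis=0)
    sd = np.std(sub, axis=0, ddof=0)
    return mean, sd


def autoscale(series: SpectrumSeries) -> SpectrumSeries:
    """Column-wise (x - mean)/sd across included spectra; zero-sd columns
    are centred only, with a warning recorded."""
    if int(np.sum(series.included_spectra)) < 2:
        raise ValueError("autoscaling needs >= 2 included spectra")
    mean, sd = _column_moments(series)
    zero = sd == 0.0
    if np.any(zero & series.included_mask):
        warnings.warn(f"{int(np.sum(zero & series.included_mask))} zero-variance "
                      "columns left centred only", stacklevel=2)
    safe = np.where(zero, 1.0, sd)
    mat = series.matrix.copy()
    mat[series.included_spectra] = (mat[series.included_spectra] - mean) / safe
    return series.evolve("autoscale", {"zero_sd_columns": int(np.sum(zero))},
                         matrix=mat)


def pareto(series: SpectrumSeries) -> SpectrumSeries:
    """Column-wise (x - mean)/sqrt(sd) across included spectra."""
    if int(np.sum(series.included_spectra)) < 2:
        raise ValueError("Pareto scaling needs >= 2 included spectra")
    mean, sd = _column_moments(series)
    zero = sd == 0.0
    if np.any(zero & series.included_mask):
        warnings.warn(f"{int(np.sum(zero & series.included_mask))} zero-variance "
                      "columns left centred only", stacklevel=2)
    safe = np.where(zero, 1.0, np.sqrt(sd))
    mat = series.matrix.copy()
    mat[series.included_spectra] = (mat[series.included_spectra] - mean) / safe
    return series.evolve("pareto", {"zero_sd_columns": int(np.sum(zero))},
                         matrix=mat)


# ---------------------------------------------------------------------------
# bucketing


def bucket(series: SpectrumSeries, width_ppm: float) -> SpectrumSeries:
    """Sum contiguous fixed-width ppm buckets over included regions.

    Buckets never straddle an exclusion boundary: each run of consecutive
    included points is partitioned independently (the last bucket of a run
    may be truncated).  Bucket value = sum of member points; the bucket
    axis holds bucket-centre ppm values.  Summing preserves total included
    intensity exactly.
    """
    step = abs(float(np.median(np.diff(series.ppm))))
    if width_ppm < step:
        raise ValueError(f"bucket width {width_ppm} ppm smaller than the "
                         f"grid step {step:.6g} ppm")
    per_bucket = max(1, int(round(width_ppm / step)))
    mask = series.included_mask
    # runs of consecutive included points
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    starts, stops = edges[0::2], edges[1::2]
    cols, centers = [], []
    for a, b in zip(starts, stops):
        for s in range(a, b, per_bucket):
            e = min(s + per_bucket, b)
            cols.append((s, e))
            centers.append(float(np.mean(series.ppm[s:e])))
    if not cols:
        raise ValueError("no included points to bucket")
    mat = np.column_stack([series.matrix[:, s:e].sum(axis=1) for s, e in cols])
    order = np.argsort(centers)[::-1]  # keep the axis descending
    mat = mat[:, order]
    centers = np.asarray(centers)[order]
    return SpectrumSeries(
        mat, centers, list(series.classes), series.included_spectra.copy(),
        np.ones(len(centers), dtype=bool),
        series.post_state + [("bucket", {"width_ppm": float(width_ppm),
                                         "points_per_bucket": per_bucket})],
    )
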