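"""1D spectral processing: apodization, Fourier transform, phasing, referencing.

The pipeline for a single spectrum is: zero-fill -> apodize -> first-point
(Gibbs) and DC handling -> optional time-domain solvent filter -> Fourier
transform -> phase -> reference.  Two automated phasing algorithms are
provided: one anchored on the TMSP resonance and its carbon-13 satellites
(:func:`autophase_tmsp`), one using signal-free strips at both spectrum
edges (:func:`autophase_ends`).  Both minimise a baseline-flatness
objective: the squared deviation of the real part from a local straight
line, summed over signal-free windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .core import AcqParams, Fid1D, Spectrum1D, ppm_axis

__all__ = [
    "ApodParams",
    "PhaseParams",
    "zero_fill",
    "apodize",
    "gibbs_correct",
    "water_filter",
    "fourier_transform",
    "inverse_fourier_transform",
    "phase",
    "autophase_tmsp",
    "autophase_ends",
    "dc_correct",
    "reference_to_standard",
    "reference_to_water",
    "water_shift_ppm",
]

# One-bond C-H coupling of the TMSP methyl groups: the 13C satellites sit
# at +- J_SAT/2 Hz around the parent resonance.
TMSP_J_SAT_HZ = 118.0


@dataclass(frozen=True)
class ApodParams:
    """Window-function choice: ``em`` (exponential), ``cos2`` (squared
    cosine) or ``sem`` (shifted sine times exponential); ``lb`` is the
    exponential line broadening in Hz (used by em/sem)."""

    kind: str = "em"
    lb: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("em", "cos2", "sem"):
            raise ValueError(f"unknown apodization kind {self.kind!r}")
        if self.lb < 0:
            raise ValueError("lb must be >= 0")


@dataclass(frozen=True)
class PhaseParams:
    """Zero-order (``phi0_deg``) and first-order (``phi1_deg``, degrees
    across the full spectral width) phase, with the first-order pivot in
    ppm (defaults to the carrier)."""

    phi0_deg: float
    phi1_deg: float = 0.0
    pivot_ppm: float | None = None

    def canonical(self) -> "PhaseParams":
        """Angles folded into (-180, 180]."""
        def fold(a: float) -> float:
            a = (a + 180.0) % 360.0 - 180.0
            return 180.0 if a == -180.0 else a
        return PhaseParams(fold(self.phi0_deg), fold(self.phi1_deg), self.pivot_ppm)


# ---------------------------------------------------------------------------
# time-domain operations


def zero_fill(fid: Fid1D, target_points: int) -> Fid1D:
    if target_points < len(fid.data):
        raise ValueError(
            f"target_points {target_points} smaller than data length {len(fid.data)}"
        )
    data = np.zeros(int(target_points), dtype=np.complex128)
    data[: len(fid.data)] = fid.data
    return fid.evolve(data, fid.acq.with_points(target_points), "zero_fill",
                      {"target_points": int(target_points)})


def apodize(fid: Fid1D, params: ApodParams) -> Fid1D:
    n = len(fid.data)
    k = np.arange(n)
    dt = fid.acq.dwell_s
    if params.kind == "em":
        w = np.exp(-np.pi * params.lb * k * dt)
    elif params.kind == "cos2":
        w = np.cos(np.pi * k / (2.0 * (n - 1))) ** 2
    elif params.kind == "sem":
        w = np.sin(np.pi * (k + 1) / (n + 1)) * np.exp(-np.pi * params.lb * k * dt)
    else:  # pragma: no cover - guarded by ApodParams
        raise ValueError(params.kind)
    return fid.evolve(fid.data * w, None, "apodize",
                      {"kind": params.kind, "lb": params.lb})


def gibbs_correct(fid: Fid1D) -> Fid1D:
    """Halve the first complex point, removing the constant spectral offset
    contributed by the k=0 term of the discrete transform.  Deliberately
    not idempotent (twice gives a factor 0.25)."""
    if len(fid.data) == 0:
        raise ValueError("empty FID")
    data = fid.data.copy()
    data[0] *= 0.5
    return fid.evolve(data, None, "gibbs_correct", {})


def water_filter(fid: Fid1D, method: str = "moving_average", width_hz: float = 30.0) -> Fid1D:
    """Post-acquisition solvent suppression.

    The on-resonance (slowly varying) component of the FID is estimated by
    convolving real and imaginary parts with a smoothing kernel and
    subtracted; edges are handled by reflection.  ``width_hz`` sets the
    approximate width of the suppressed region around the carrier.
    """
    if width_hz <= 0:
        raise ValueError("width_hz must be > 0")
    n = len(fid.data)
    if method == "moving_average":
        size = 2 * int(round(fid.acq.sw_hz / width_hz)) + 1  # half-width sw/width
        if size >= n:
            raise ValueError("smoothing kernel wider than FID")
        low = (ndimage.uniform_filter1d(fid.data.real, size, mode="reflect")
               + 1j * ndimage.uniform_filter1d(fid.data.imag, size, mode="reflect"))
    elif method == "gaussian":
        # kernel whose frequency response has FWHM ~= width_hz
        sigma_pts = fid.acq.sw_hz * np.sqrt(np.log(256.0)) / (2.0 * np.pi * width_hz)
        if 6 * sigma_pts >= n:
            raise ValueError("smoothing kernel wider than FID")
        low = (ndimage.gaussian_filter1d(fid.data.real, sigma_pts, mode="reflect")
               + 1j * ndimage.gaussian_filter1d(fid.data.imag, sigma_pts, mode="reflect"))
    else:
        raise ValueError(f"unknown water filter method {method!r}")
    return fid.evolve(fid.data - low, None, "water_filter",
                      {"method": method, "width_hz": width_hz})


# ---------------------------------------------------------------------------
# Fourier transform and its inverse (used by the synthetic generator)


def _ft_array(data: np.ndarray) -> np.ndarray:
    """Unnormalised DFT reordered onto the descending-ppm axis:
    output[j] corresponds to offset frequency (n/2 - j) * sw / n."""
    n = len(data)
    f = np.fft.fft(data)
    idx = (n // 2 - np.arange(n)) % n
    return f[idx]


def _ift_array(spec: np.ndarray) -> np.ndarray:
    n = len(spec)
    idx = (n // 2 - np.arange(n)) % n
    f = np.empty(n, dtype=np.complex128)
    f[idx] = spec
    return np.fft.ifft(f)


def fourier_transform(fid: Fid1D) -> Spectrum1D:
    """Discrete FT onto the descending ppm axis; the carrier maps to the
    axis centre.  No normalisation is applied (Parseval:
    sum|fid|^2 = (1/N) sum|spec|^2)."""
    if len(fid.data) == 0:
        raise ValueError("empty FID")
    spec = _ft_array(fid.data)
    return Spectrum1D(spec, ppm_axis(fid.acq), fid.acq,
                      fid.history + [("fourier_transform", {})])


def inverse_fourier_transform(spec: Spectrum1D) -> Fid1D:
    data = _ift_array(np.asarray(spec.data, dtype=np.complex128))
    return Fid1D(data, spec.acq, spec.history + [("inverse_fourier_transform", {})])


# ---------------------------------------------------------------------------
# frequency-domain operations


def _phase_factor(ppm: np.ndarray, params: PhaseParams, acq: AcqParams) -> np.ndarray:
    pivot = acq.o1_ppm if params.pivot_ppm is None else params.pivot_ppm
    ang = np.deg2rad(params.phi0_deg + params.phi1_deg * (ppm - pivot) / acq.sw_ppm)
    return np.exp(1j * ang)


def phase(spec: Spectrum1D, params: PhaseParams) -> Spectrum1D:
    """Multiply point j by exp(i*(phi0 + phi1*(ppm_j - pivot)/sw_ppm))."""
    factor = _phase_factor(spec.ppm, params, spec.acq)
    return spec.evolve(np.asarray(spec.data, dtype=np.complex128) * factor, "phase",
                       {"phi0_deg": params.phi0_deg, "phi1_deg": params.phi1_deg,
                        "pivot_ppm": params.pivot_ppm})


def _window_objective(spec: Spectrum1D, windows: list[np.ndarray]):
    """Return f(phi0, phi1) evaluating baseline flatness on the given index
    windows only (cheap: phase is applied to window points alone).

    Each window's squared deviation of the real part from its own
    least-squares straight line is normalised by the window's mean squared
    magnitude — a phase-invariant scale — so weak windows (the signal-free
    edge strip, which carries the first-order information) weigh as much as
    the strong strips flanking TMSP.
    """
    acq = spec.acq
    pivot = acq.o1_ppm
    data_w = [np.asarray(spec.data, dtype=np.complex128)[w] for w in windows]
    coef_w = [(spec.ppm[w] - pivot) / acq.sw_ppm for w in windows]
    x_w = [np.linspace(-1.0, 1.0, len(w)) for w in windows]
    norm_w = [max(float(np.mean(np.abs(d) ** 2)), 1e-300) for d in data_w]

    def objective(p):
        a, b = np.deg2rad(p[0]), np.deg2rad(p[1])
        total = 0.0
        for d, c, x, norm in zip(data_w, coef_w, x_w, norm_w):
            y = np.real(d * np.exp(1j * (a + b * c)))
            coef = np.polynomial.polynomial.polyfit(x, y, 1)
            resid = y - np.polynomial.polynomial.polyval(x, coef)
            total += float(resid @ resid) / len(y) / norm
        return total

    return objective


def _noise_mad(values: np.ndarray) -> float:
    med = np.median(values)
    return float(np.median(np.abs(values - med))) or 1e-300


def _find_tmsp(spec: Spectrum1D, window_ppm=(-0.3, 0.3)):
    """Index of the dominant peak near 0 ppm, or None if absent.

    A genuine reference peak is an interior maximum of the search window
    that towers over the window median; a smooth tail from signals outside
    the window is monotone (argmax at the window boundary) and flat."""
    lo, hi = min(window_ppm), max(window_ppm)
    sel = np.where((spec.ppm >= lo) & (spec.ppm <= hi))[0]
    if len(sel) < 5:
        return None
    mag = np.abs(np.asarray(spec.data))[sel]
    k = int(np.argmax(mag))
    if k < 2 or k > len(sel) - 3:
        return None
    if mag[k] < 10.0 * (float(np.median(mag)) or 1e-300):
        return None
    return int(sel[k])


def autophase_tmsp(spec: Spectrum1D) -> PhaseParams:
    """Automated zero- plus first-order phasing anchored on TMSP.

    Baseline-flatness windows: (a) the signal-free strips between the TMSP
    parent peak and each of its 13C satellites (located ~+-59 Hz away),
    (b) a signal-free strip at the downfield edge of the spectrum, which
    provides the long lever arm for the first-order term.  Local phase
    angles flattening (a) and (b) are found by grid search plus bounded
    refinement, combined into a (phi0, phi1) estimate, and polished by a
    bounded Nelder-Mead on the joint flatness objective.
    """
    peak = _find_tmsp(spec)
    if peak is None:
        raise ValueError(
            "no TMSP resonance found in the search window; use autophase_ends"
        )
    n = len(spec.ppm)
    hz_per_pt = spec.acq.sw_hz / n
    sat_off = TMSP_J_SAT_HZ / 2.0 / hz_per_pt  # points
    windows: list[np.ndarray] = []
    for sign in (-1, +1):
        a = peak + sign * int(round(0.15 * sat_off))
        b = peak + sign * int(round(0.85 * sat_off))
        lo, hi = sorted((a, b))
        if lo < 0 or hi >= n:
            raise ValueError("TMSP satellites fall outside the spectrum")
        windows.append(np.arange(lo, hi + 1))
    # Window (b): baseline at the downfield end.  If a clear peak exists in
    # the downfield region, use the signal-free strip between the spectrum
    # edge and that peak (its dispersion leakage makes the local phase
    # there sharply defined, and its sign is resolvable); otherwise fall
    # back to a fixed edge strip.
    start = max(1, n // 200)
    mag = np.abs(np.asarray(spec.data))
    down = slice(start, int(0.4 * n))
    cand = start + int(np.argmax(mag[down]))
    edge_peak: int | None = None
    strip = mag[start:max(4, int(0.04 * n))]
    if mag[cand] > 20.0 * (np.median(strip) or 1e-300) and cand - start > 30:
        edge_peak = cand
        gap = cand - start
        edge = np.arange(cand - int(round(0.85 * gap)), cand - int(round(0.15 * gap)))
    else:
        edge = np.arange(start, max(4, int(0.04 * n)))
    windows.append(edge)

    def local_phase(wins: list[np.ndarray]) -> float:
        """Constant rotation flattening the given windows (grid + bounded
        refinement; defined mod 180)."""
        obj = _window_objective(spec, wins)
        grid = np.arange(-90.0, 90.0, 5.0)
        a0 = grid[int(np.argmin([obj((a, 0.0)) for a in grid]))]
        res = optimize.minimize_scalar(lambda a: obj((a, 0.0)),
                                       bounds=(a0 - 5.0, a0 + 5.0),
                                       method="bounded", options={"xatol": 1e-6})
        return float(res.x)

    # local phase at TMSP (sign resolved: the parent must come out positive)
    theta_t = local_phase(windows[:2])
    if np.real(spec.data[peak] * np.exp(1j * np.deg2rad(theta_t))) < 0:
        theta_t += 180.0
    # local phase at the downfield anchor; sign resolved against the
    # downfield peak when one exists, otherwise left to the branch choice
    theta_e = local_phase([edge])
    if edge_peak is not None and np.real(
            spec.data[edge_peak] * np.exp(1j * np.deg2rad(theta_e))) < 0:
        theta_e += 180.0

    # solve phi0 + phi1*c = theta at both anchors; the edge angle is known
    # only mod 180, so take the branch with the smallest |phi1| — for
    # moderate phase errors the neighbouring branches are ~200 deg away
    pivot = spec.acq.o1_ppm
    c_t = float((spec.ppm[peak] - pivot) / spec.acq.sw_ppm)
    c_e = float(np.mean((spec.ppm[edge] - pivot) / spec.acq.sw_ppm))
    base = theta_e - theta_t
    steps = (-2, 0, 2) if edge_peak is not None else range(-3, 4)
    phi1 = min(((base + 180.0 * m) / (c_e - c_t) for m in steps), key=abs)
    phi0 = theta_t - phi1 * c_t

    # joint refinement of both angles on all windows at once
    objective = _window_objective(spec, windows)
    res = optimize.minimize(
        objective, (phi0, phi1), method="Nelder-Mead",
        bounds=[(phi0 - 20.0, phi0 + 20.0), (phi1 - 30.0, phi1 + 30.0)],
        options={"xatol": 1e-5, "fatol": 1e-16, "maxiter": 4000})
    params = PhaseParams(float(res.x[0]), float(res.x[1])).canonical()
    # flatness cannot tell positive from negative absorption; require the
    # TMSP peak to come out positive
    if np.real(spec.data[peak] * _phase_factor(spec.ppm[peak:peak + 1],
                                               params, spec.acq))[0] < 0:
        params = PhaseParams(params.phi0_deg + 180.0, params.phi1_deg).canonical()
    return params


def autophase_ends(spec: Spectrum1D, edge_fraction: float = 0.05) -> PhaseParams:
    """Zero-order-only automated phasing from signal-free strips at both
    spectrum edges; used when no TMSP is present."""
    n = len(spec.ppm)
    m = max(4, int(edge_fraction * n))
    windows = [np.arange(max(1, n // 200), m), np.arange(n - m, n - max(1, n // 200))]
    objective = _window_objective(spec, windows)

    def f0(a: float) -> float:
        return objective((a, 0.0))

    grid = np.arange(-180.0, 180.0, 5.0)
    vals = [f0(a) for a in grid]
    a0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(f0, bounds=(a0 - 5.0, a0 + 5.0), method="bounded",
                                   options={"xatol": 1e-6})
    params = PhaseParams(float(res.x), 0.0).canonical()
    # resolve the +-180 deg flatness ambiguity toward positive total signal
    rotated = np.real(np.asarray(spec.data) * np.exp(1j * np.deg2rad(params.phi0_deg)))
    if float(np.sum(rotated)) < 0:
        params = PhaseParams(params.phi0_deg + 180.0, 0.0).canonical()
    return params


def dc_correct(spec: Spectrum1D, noise_region_ppm: tuple[float, float]) -> Spectrum1D:
    lo, hi = min(noise_region_ppm), max(noise_region_ppm)
    sel = (spec.ppm >= lo) & (spec.ppm <= hi)
    if not np.any(sel):
        raise ValueError("noise region contains no axis points")
    data = np.asarray(spec.data, dtype=np.complex128)
    offset = np.mean(data.real[sel]) + 1j * np.mean(data.imag[sel])
    return spec.evolve(data - offset, "dc_correct",
                       {"noise_region_ppm": (float(lo), float(hi))})


def reference_to_standard(spec: Spectrum1D, standard: str = "TMSP",
                          search_window_ppm: tuple[float, float] = (-0.5, 0.5)) -> Spectrum1D:
    """Shift the ppm axis so the strongest real maximum in the search
    window lands at exactly 0.000 ppm (TMS/TMSP/DSS all resonate at 0)."""
    if standard.upper() not in ("TMSP", "DSS", "TMS"):
        raise ValueError(f"unknown shift standard {standard!r}")
    lo, hi = min(search_window_ppm), max(search_window_ppm)
    sel = np.where((spec.ppm >= lo) & (spec.ppm <= hi))[0]
    if len(sel) == 0:
        raise ValueError("referencing window contains no axis points")
    y = np.real(np.asarray(spec.data))[sel]
    if np.max(y) < 5.0 * _noise_mad(y):
        raise ValueError("no reference peak above the noise in the window")
    found = spec.ppm[sel[int(np.argmax(y))]]
    new_ppm = spec.ppm - found
    return Spectrum1D(np.asarray(spec.data).copy(), new_ppm, spec.acq,
                      spec.history + [("reference_to_standard",
                                       {"standard": standard, "shift_ppm": float(-found)})])


def water_shift_ppm(temperature_c: float) -> float:
    """Temperature-dependent chemical shift of water (ppm, T in Celsius)."""
    t = temperature_c
    return 5.060 - 0.0122 * t + 2.11e-5 * t * t


def reference_to_water(spec: Spectrum1D) -> Spectrum1D:
    """Reference assuming the transmitter offset was set on the water
    resonance: the axis centre is moved to the temperature-dependent water
    shift."""
    t = spec.acq.temperature_c
    if t is None:
        raise ValueError(
            "sample temperature unknown: set acq.temperature_c to use water referencing"
        )
    target = water_shift_ppm(t)
    # the carrier sits at the axis centre index regardless of any previous
    # axis shifts
    delta = target - float(spec.ppm[len(spec.ppm) // 2])
    new_ppm = spec.ppm + delta
    from dataclasses import replace as _replace
    acq = _replace(spec.acq, o1_ppm=target)
    return Spectrum1D(np.asarray(spec.data).copy(), new_ppm, acq,
                      spec.history + [("reference_to_water", {"shift_ppm": float(delta)})])
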