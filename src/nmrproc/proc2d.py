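"""2D processing: HSQC echo/anti-echo reconstruction, J-res tilt, projections.

Echo/anti-echo HSQC data are recombined into States-equivalent cosine and
sine channels, apodized (squared cosine by default in both dimensions),
Fourier transformed along F2, recombined into a complex indirect-dimension
interferogram from the two absorptive real parts, and transformed along F1;
the real part is pure 2D absorption.  J-resolved data generated as
amplitude-modulated cosine/sine channels follow the same indirect-dimension
path (States processing).
"""

from __future__ import annotations

import numpy as np

from .core import Fid2D, Spectrum1D, Spectrum2D, hz_axis, ppm_axis
from .proc1d import ApodParams, _ft_array

__all__ = ["process_hsqc", "process_jres", "tilt_jres", "project"]


def _window(n: int, params: ApodParams, dwell_s: float) -> np.ndarray:
    k = np.arange(n)
    if params.kind == "em":
        return np.exp(-np.pi * params.lb * k * dwell_s)
    if params.kind == "cos2":
        return np.cos(np.pi * k / (2.0 * (n - 1))) ** 2
    if params.kind == "sem":
        return np.sin(np.pi * (k + 1) / (n + 1)) * np.exp(-np.pi * params.lb * k * dwell_s)
    raise ValueError(f"unknown apodization kind {params.kind!r}")


def _states_ft(cos_ch: np.ndarray, sin_ch: np.ndarray, acq_f1, acq_f2,
               apod_f1: ApodParams, apod_f2: ApodParams,
               f1_unit: str, history) -> Spectrum2D:
    """Common States-style 2D transform from cosine/sine t1 channels."""
    w2 = _window(cos_ch.shape[1], apod_f2, acq_f2.dwell_s)
    w1 = _window(cos_ch.shape[0], apod_f1, acq_f1.dwell_s)
    w2 = w2.copy()
    w2[0] *= 0.5  # first-point halving removes the per-row F2 offset
    a = np.empty(cos_ch.shape)
    b = np.empty(cos_ch.shape)
    for i in range(cos_ch.shape[0]):
        a[i] = np.real(_ft_array(cos_ch[i] * w2))
        b[i] = np.real(_ft_array(sin_ch[i] * w2))
    inter = (a + 1j * b) * w1[:, None]
    inter[0] *= 0.5  # first t1 point: suppress the F1 ridge (Gibbs term)
    out = np.empty(cos_ch.shape)
    for j in range(cos_ch.shape[1]):
        out[:, j] = np.real(_ft_array(inter[:, j]))
    axis_f1 = (ppm_axis(acq_f1) if f1_unit == "ppm"
               else hz_axis(acq_f1.sw_hz, acq_f1.n_points))
    return Spectrum2D(out, axis_f1, ppm_axis(acq_f2), acq_f1, acq_f2,
                      f1_unit=f1_unit, history=history)


def process_hsqc(echo_fid: Fid2D, antiecho_fid: Fid2D,
                 apod_f2: ApodParams | None = None,
                 apod_f1: ApodParams | None = None) -> Spectrum2D:
    """Reconstruct an absorptive HSQC spectrum from an echo/anti-echo pair.

    The States-equivalent quadrature channels are
    cos = (antiecho + echo)/2 and sin = (antiecho - echo)/(2i).
    """
    if echo_fid.data.shape != antiecho_fid.data.shape:
        raise ValueError("echo and anti-echo data shapes differ")
    apod_f2 = apod_f2 or ApodParams("cos2")
    apod_f1 = apod_f1 or ApodParams("cos2")
    cos_ch = (antiecho_fid.data + echo_fid.data) / 2.0
    sin_ch = (antiecho_fid.data - echo_fid.data) / 2j
    return _states_ft(
        cos_ch, sin_ch, echo_fid.acq_f1, echo_fid.acq_f2, apod_f1, apod_f2,
        echo_fid.f1_unit,
        echo_fid.history + [("process_hsqc",
                             {"apod_f2": apod_f2.kind, "apod_f1": apod_f1.kind})])


def process_jres(fid: Fid2D, apod_f2: ApodParams | None = None,
                 apod_f1: ApodParams | None = None) -> Spectrum2D:
    """Transform a J-resolved dataset (cosine/sine amplitude-modulated t1
    channels) into an absorptive 2D spectrum with F1 in Hz.  Both
    dimensions default to the squared-cosine window; the SEM function
    (shifted sine times exponential) is available for F2."""
    if fid.data_b is None:
        raise ValueError("J-res processing needs both t1 quadrature channels")
    apod_f2 = apod_f2 or ApodParams("cos2")
    apod_f1 = apod_f1 or ApodParams("cos2")
    return _states_ft(
        fid.data, fid.data_b, fid.acq_f1, fid.acq_f2, apod_f1, apod_f2,
        fid.f1_unit,
        fid.history + [("process_jres",
                        {"apod_f2": apod_f2.kind, "apod_f1": apod_f1.kind})])


def tilt_jres(spec: Spectrum2D, inverse: bool = False) -> Spectrum2D:
    """Shear each F1 row along F2 by its own F1 frequency (45-degree tilt)
    so both components of a multiplet line up in one F2 column.

    Linear interpolation; points shifted in from outside the matrix are
    zero (no wrap-around).
    """
    if spec.f1_unit != "hz":
        raise ValueError("tilt expects a J-resolved spectrum with F1 in Hz")
    n2 = spec.data.shape[1]
    df2 = spec.acq_f2.sw_hz / n2
    cols = np.arange(n2, dtype=float)
    out = np.empty_like(spec.data)
    sign = -1.0 if inverse else 1.0
    for i, f1 in enumerate(spec.axis_f1):
        shift = sign * f1 / df2  # fractional column offset toward lower freq
        out[i] = np.interp(cols - shift, cols, spec.data[i], left=0.0, right=0.0)
    return spec.evolve(out, "tilt_jres", {"inverse": inverse})


def project(spec: Spectrum2D, method: str = "skyline") -> Spectrum1D:
    """Collapse the F1 dimension: ``skyline`` takes the per-column maximum,
    ``sum`` the per-column sum."""
    if method == "skyline":
        prof = spec.data.max(axis=0)
    elif method == "sum":
        prof = spec.data.sum(axis=0)
    else:
        raise ValueError(f"unknown projection method {method!r}")
    return Spectrum1D(prof, spec.axis_f2, spec.acq_f2,
                      spec.history + [("project", {"method": method})])
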