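"""Parametric synthetic NMR data with known ground truth.

Every test input used in this package is generated here: 1D FIDs built
from Lorentzian line lists (with controlled phase errors, polynomial
baselines, solvent residual, a TMSP reference line with carbon-13
satellites), J-resolved and echo/anti-echo HSQC 2D data, and multi-spectrum
series with class structure, dilution factors and axis jitter.  Writers for
the two supported on-disk dialects live here as well, so the readers in
:mod:`nmrproc.io` can be exercised round-trip.

Conventions: FID point k is sampled at t = k*dt; a line of full width at
half maximum ``lw`` Hz decays as exp(-pi*lw*t), which yields a Lorentzian
of FWHM exactly ``lw`` Hz after Fourier transform.  Phase errors are
planted exactly by dephasing in the frequency domain (multiplying the ideal
spectrum by exp(+i*(phi0 + phi1*(ppm-pivot)/sw_ppm)) and transforming
back), so applying the opposite phase correction restores a pure absorption
spectrum to machine precision.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import AcqParams, Fid1D, Fid2D, ppm_axis
from .proc1d import PhaseParams, _ft_array, _ift_array, _phase_factor, TMSP_J_SAT_HZ

__all__ = [
    "LineSpec",
    "SeriesSpec",
    "make_fid",
    "make_series",
    "make_jres",
    "make_hsqc",
    "write_bruker",
    "write_varian",
    "tmsp_line",
    "water_line",
]


@dataclass(frozen=True)
class LineSpec:
    """One Lorentzian resonance.

    ``j_hz`` splits the line into a doublet at +-J/2 (half amplitude each);
    ``satellite_frac`` moves that fraction of the amplitude into two
    satellites at +-``j_sat_hz``/2, modelling the 13C satellites of TMSP.
    """

    ppm: float
    amplitude: float
    lw: float
    j_hz: float | None = None
    satellite_frac: float = 0.0
    j_sat_hz: float = TMSP_J_SAT_HZ

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.lw <= 0:
            raise ValueError("lw must be > 0")
        if not 0.0 <= self.satellite_frac <= 0.1:
            raise ValueError("satellite_frac must lie in [0, 0.1]")

    def components(self, sf_mhz: float) -> list[tuple[float, float]]:
        """(offset_hz_from_ppm0, amplitude) components of this line; the
        offset is the line position expressed in Hz at ppm scale origin,
        i.e. ppm*sf + extra Hz offsets."""
        base_hz = self.ppm * sf_mhz
        parent = self.amplitude * (1.0 - self.satellite_frac)
        comps: list[tuple[float, float]] = []
        if self.j_hz:
            comps += [(base_hz - self.j_hz / 2.0, parent / 2.0),
                      (base_hz + self.j_hz / 2.0, parent / 2.0)]
        else:
            comps.append((base_hz, parent))
        if self.satellite_frac > 0:
            half = self.amplitude * self.satellite_frac / 2.0
            comps += [(base_hz - self.j_sat_hz / 2.0, half),
                      (base_hz + self.j_sat_hz / 2.0, half)]
        return comps


def tmsp_line(amplitude: float = 100.0, lw: float = 1.2,
              satellite_frac: float = 0.011, ppm: float = 0.0) -> LineSpec:
    """TMSP reference line at 0 ppm with natural-abundance 13C satellites."""
    return LineSpec(ppm=ppm, amplitude=amplitude, lw=lw, satellite_frac=satellite_frac)


def water_line(acq: AcqParams, amplitude: float = 500.0, lw: float = 30.0) -> LineSpec:
    """Broad residual-solvent line sitting on the carrier."""
    return LineSpec(ppm=acq.o1_ppm, amplitude=amplitude, lw=lw)


def _check_in_window(offset_hz: float, acq: AcqParams, what: str) -> None:
    rel = offset_hz - acq.o1_ppm * acq.sf_mhz
    if abs(rel) >= acq.sw_hz / 2.0:
        raise ValueError(
            f"{what} at {rel:+.1f} Hz from the carrier falls outside the "
            f"spectral window (+-{acq.sw_hz / 2.0:.1f} Hz)"
        )


def _clean_fid(lines: list[LineSpec], acq: AcqParams) -> np.ndarray:
    t = np.arange(acq.n_points) * acq.dwell_s
    data = np.zeros(acq.n_points, dtype=np.complex128)
    for line in lines:
        for off_hz, amp in line.components(acq.sf_mhz):
            _check_in_window(off_hz, acq, f"line at {line.ppm} ppm")
            f_rel = off_hz - acq.o1_ppm * acq.sf_mhz
            data += amp * np.exp((2j * np.pi * f_rel - np.pi * line.lw) * t)
    return data


def _dephase(data: np.ndarray, acq: AcqParams, phi0_deg: float, phi1_deg: float) -> np.ndarray:
    if phi0_deg == 0.0 and phi1_deg == 0.0:
        return data
    spec = _ft_array(data)
    factor = _phase_factor(ppm_axis(acq, len(data)), PhaseParams(phi0_deg, phi1_deg), acq)
    return _ift_array(spec * factor)


def _baseline_fid(coeffs, acq: AcqParams) -> np.ndarray:
    """Time-domain equivalent of a polynomial baseline on the ppm axis.

    The polynomial (ascending coefficients in x, where x spans [-1, 1] over
    the descending axis) is evaluated on the frequency grid and transformed
    back, so that a Fourier transform of the returned FID contribution
    reproduces the baseline exactly."""
    n = acq.n_points
    x = np.linspace(-1.0, 1.0, n)
    base = np.polynomial.polynomial.polyval(x, np.asarray(coeffs, dtype=float))
    return _ift_array(base.astype(np.complex128))


def make_fid(lines: list[LineSpec], acq: AcqParams, phase0_deg: float = 0.0,
             phase1_deg: float = 0.0, noise_sd: float = 0.0,
             seed: int | None = 0, baseline_coeffs=None,
             shift_ppm: float = 0.0) -> Fid1D:
    """Synthesise a 1D FID from a line list.

    ``shift_ppm`` displaces every line (axis jitter for series);
    ``baseline_coeffs`` adds a polynomial baseline (frequency domain,
    exactly representable).  Noise is complex Gaussian with standard
    deviation ``noise_sd`` per quadrature channel.
    """
    if shift_ppm:
        lines = [LineSpec(l.ppm + shift_ppm, l.amplitude, l.lw, l.j_hz,
                          l.satellite_frac, l.j_sat_hz) for l in lines]
    data = _clean_fid(lines, acq)
    data = _dephase(data, acq, phase0_deg, phase1_deg)
    if baseline_coeffs is not None:
        data = data + _baseline_fid(baseline_coeffs, acq)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + noise_sd * (rng.standard_normal(acq.n_points)
                                  + 1j * rng.standard_normal(acq.n_points))
    return Fid1D(data, acq, [("make_fid", {"seed": seed})])


@dataclass(frozen=True)
class SeriesSpec:
    """Recipe for a multi-spectrum series with known ground truth.

    Per-spectrum vectors must all have length ``n_spectra``.  ``dilution``
    multiplies every signal line of that spectrum; ``shift_jitter_ppm``
    scales random per-spectrum axis shifts; ``phase_errors`` are planted
    (phi0, phi1) pairs in degrees; ``baseline_coeffs`` are per-spectrum
    polynomial baseline coefficient vectors.
    """

    n_spectra: int
    classes: tuple = ()
    dilution: tuple = ()
    shift_jitter_ppm: float = 0.0
    baseline_coeffs: tuple = ()
    phase_errors: tuple = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("classes", "dilution", "baseline_coeffs", "phase_errors"):
            v = getattr(self, name)
            if v and len(v) != self.n_spectra:
                raise ValueError(f"{name} must have one entry per spectrum")
        if any(d <= 0 for d in self.dilution):
            raise ValueError("dilution factors must be > 0")


def make_series(spec: SeriesSpec, lines: list[LineSpec], acq: AcqParams):
    """Generate a series of FIDs plus a ground-truth record.

    Returns ``(fids, truth)`` where ``truth`` holds the per-spectrum true
    dilutions, axis shifts (ppm), planted phases, baseline value matrix and
    class labels, sufficient to predict the processed result for noiseless
    cases."""
    rng = np.random.default_rng(spec.seed)
    dil = list(spec.dilution) or [1.0] * spec.n_spectra
    classes = list(spec.classes) or [""] * spec.n_spectra
    phases = list(spec.phase_errors) or [(0.0, 0.0)] * spec.n_spectra
    bases = list(spec.baseline_coeffs) or [None] * spec.n_spectra
    shifts = (rng.normal(0.0, spec.shift_jitter_ppm, spec.n_spectra)
              if spec.shift_jitter_ppm > 0 else np.zeros(spec.n_spectra))

    x = np.linspace(-1.0, 1.0, acq.n_points)
    fids, base_rows = [], []
    for i in range(spec.n_spectra):
        scaled = [LineSpec(l.ppm, l.amplitude * dil[i], l.lw, l.j_hz,
                           l.satellite_frac, l.j_sat_hz) for l in lines]
        fid = make_fid(scaled, acq, phases[i][0], phases[i][1],
                       noise_sd=spec.noise_sd,
                       seed=int(rng.integers(0, 2**31 - 1)),
                       baseline_coeffs=bases[i], shift_ppm=float(shifts[i]))
        fids.append(fid)
        base_rows.append(np.polynomial.polynomial.polyval(
            x, np.asarray(bases[i], dtype=float)) if bases[i] is not None
            else np.zeros(acq.n_points))
    truth = {
        "dilution": np.asarray(dil, dtype=float),
        "shift_ppm": np.asarray(shifts, dtype=float),
        "phase_errors": [tuple(p) for p in phases],
        "baseline": np.vstack(base_rows),
        "classes": classes,
    }
    return fids, truth


# ---------------------------------------------------------------------------
# 2D generators


def make_jres(lines: list[LineSpec], acq_f2: AcqParams, sw1_hz: float,
              n_f1: int, lw_f1_hz: float = 1.0) -> Fid2D:
    """2D J-resolved dataset (untilted convention).

    Each doublet component at chemical shift delta and coupling offset
    s*J/2 appears at F2 = delta + s*J/2 (ppm axis) and F1 = s*J/2 (Hz).
    The indirect dimension is stored as two amplitude-modulated channels
    (cosine/sine) so the processor can reconstruct pure-absorption
    lineshapes.
    """
    if sw1_hz <= 0 or n_f1 < 2:
        raise ValueError("invalid F1 dimension parameters")
    for line in lines:
        if line.j_hz is not None and abs(line.j_hz) >= sw1_hz:
            raise ValueError(
                f"coupling {line.j_hz} Hz outside the F1 window (+-{sw1_hz / 2} Hz)"
            )
    t2 = np.arange(acq_f2.n_points) * acq_f2.dwell_s
    t1 = np.arange(n_f1) / sw1_hz
    cos_ch = np.zeros((n_f1, acq_f2.n_points), dtype=np.complex128)
    sin_ch = np.zeros_like(cos_ch)
    for line in lines:
        comps = ([(-line.j_hz / 2.0, 0.5), (line.j_hz / 2.0, 0.5)]
                 if line.j_hz else [(0.0, 1.0)])
        for f1, w in comps:
            off_hz = line.ppm * acq_f2.sf_mhz + f1
            _check_in_window(off_hz, acq_f2, f"line at {line.ppm} ppm")
            f2_rel = off_hz - acq_f2.o1_ppm * acq_f2.sf_mhz
            s2 = np.exp((2j * np.pi * f2_rel - np.pi * line.lw) * t2)
            m = w * line.amplitude * np.exp(-np.pi * lw_f1_hz * t1)
            cos_ch += np.outer(m * np.cos(2 * np.pi * f1 * t1), s2)
            sin_ch += np.outer(m * np.sin(2 * np.pi * f1 * t1), s2)
    acq_f1 = AcqParams(sw_hz=sw1_hz, sf_mhz=acq_f2.sf_mhz, o1_ppm=0.0,
                       n_points=n_f1)
    return Fid2D(cos_ch, acq_f1, acq_f2, data_b=sin_ch, scheme="states",
                 f1_unit="hz", history=[("make_jres", {})])


def make_hsqc(peaks, acq_h: AcqParams, acq_c: AcqParams,
              lw_f1_hz: float = 2.0) -> tuple[Fid2D, Fid2D]:
    """Echo/anti-echo HSQC pair.

    ``peaks`` is a list of ``(ppm_h, ppm_c, amplitude, lw_h, lw_c)``;
    F2 is the direct 1H dimension (``acq_h``), F1 the indirect 13C
    dimension (``acq_c``).  Returns ``(echo, antiecho)`` whose recombination
    in :func:`nmrproc.proc2d.process_hsqc` yields absorptive peaks at the
    stated coordinates.
    """
    t2 = np.arange(acq_h.n_points) * acq_h.dwell_s
    t1 = np.arange(acq_c.n_points) * acq_c.dwell_s
    echo = np.zeros((acq_c.n_points, acq_h.n_points), dtype=np.complex128)
    anti = np.zeros_like(echo)
    for (ppm_h, ppm_c, amp, lw_h, lw_c) in peaks:
        _check_in_window(ppm_h * acq_h.sf_mhz, acq_h, f"1H peak at {ppm_h} ppm")
        _check_in_window(ppm_c * acq_c.sf_mhz, acq_c, f"13C peak at {ppm_c} ppm")
        f2 = (ppm_h - acq_h.o1_ppm) * acq_h.sf_mhz
        f1 = (ppm_c - acq_c.o1_ppm) * acq_c.sf_mhz
        s2 = amp * np.exp((2j * np.pi * f2 - np.pi * lw_h) * t2)
        decay1 = np.exp(-np.pi * max(lw_c, lw_f1_hz) * t1)
        echo += np.outer(decay1 * np.exp(-2j * np.pi * f1 * t1), s2)
        anti += np.outer(decay1 * np.exp(+2j * np.pi * f1 * t1), s2)
    e = Fid2D(echo, acq_c, acq_h, scheme="echo-antiecho", f1_unit="ppm",
              history=[("make_hsqc", {"channel": "echo"})])
    a = Fid2D(anti, acq_c, acq_h, scheme="echo-antiecho", f1_unit="ppm",
              history=[("make_hsqc", {"channel": "antiecho"})])
    return e, a


# ---------------------------------------------------------------------------
# on-disk dialect writers (readers live in nmrproc.io)

_BRUKER_INT_MAX = 2**30


def _int_scale(maxabs: float) -> float:
    """Power-of-two scale filling the int32 range; power-of-two scaling
    keeps integer-valued data exact while giving ~2^-30 relative
    quantization otherwise."""
    if maxabs == 0.0:
        return 1.0
    return float(2.0 ** np.floor(np.log2(_BRUKER_INT_MAX / maxabs)))


def _interleave(data: np.ndarray) -> np.ndarray:
    out = np.empty(data.size * 2, dtype=float)
    out[0::2] = data.real.ravel()
    out[1::2] = data.imag.ravel()
    return out


def write_bruker(fid: Fid1D | Fid2D, directory: str | Path,
                 byte_order: str = "little") -> Path:
    """Write the Bruker-style dialect: ``fid`` (1D) or ``ser`` (2D) as
    interleaved real/imaginary int32, plus an ``acqus`` key-value text file
    (and ``acqu2s`` for 2D).  See ``docs/formats.md`` for the dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bytorda = {"little": 0, "big": 1}[byte_order]
    dtype = "<i4" if bytorda == 0 else ">i4"

    if isinstance(fid, Fid1D):
        payload = np.concatenate(
            [np.zeros(2 * fid.acq.group_delay), _interleave(fid.data)])
        acqs = [("acqus", fid.acq, len(fid.data) + fid.acq.group_delay)]
        binary = directory / "fid"
    else:
        rows = fid.data if fid.data_b is None else np.concatenate(
            [np.stack([a, b]) for a, b in zip(fid.data, fid.data_b)])
        payload = _interleave(np.asarray(rows))
        acqs = [("acqus", fid.acq_f2, fid.acq_f2.n_points),
                ("acqu2s", fid.acq_f1, fid.acq_f1.n_points)]
        binary = directory / "ser"

    scale = _int_scale(float(np.max(np.abs(payload))) if payload.size else 0.0)
    ints = np.round(payload * scale).astype(np.int64)
    if np.max(np.abs(ints), initial=0) > 2**31 - 1:  # pragma: no cover
        raise AssertionError("integer overflow in vendor writer")
    ints.astype(dtype).tofile(binary)

    for name, acq, npts in acqs:
        lines = [
            "##TITLE= nmrproc synthetic dataset",
            f"##$SW= {acq.sw_hz!r}",
            f"##$SFO1= {acq.sf_mhz!r}",
            f"##$O1= {acq.o1_ppm * acq.sf_mhz!r}",
            f"##$TD= {2 * npts}",
            f"##$GRPDLY= {acq.group_delay if isinstance(fid, Fid1D) else 0}",
            f"##$BYTORDA= {bytorda}",
            f"##$SCALE= {scale!r}",
        ]
        if acq.temperature_c is not None:
            lines.append(f"##$TE= {acq.temperature_c + 273.15!r}")
        if isinstance(fid, Fid2D):
            lines.append(f"##$QUADSCHEME= {fid.scheme or 'none'}")
            lines.append(f"##$F1UNIT= {fid.f1_unit}")
            if name == "acqu2s":
                lines.append(f"##$NCHAN= {1 if fid.data_b is None else 2}")
        lines.append("##END=")
        (directory / name).write_text("\n".join(lines) + "\n")
    return directory


_VARIAN_MAGIC = 0x6E6D7266  # "nmrf"


def write_varian(fid: Fid1D, directory: str | Path) -> Path:
    """Write the Varian-style dialect: one big-endian binary ``fid`` file
    (16-byte header + float32 interleaved data) plus a ``procpar`` text
    file of ``key value`` lines."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    acq = fid.acq
    payload = np.concatenate(
        [np.zeros(2 * acq.group_delay), _interleave(fid.data)]).astype(">f4")
    n_complex = len(fid.data) + acq.group_delay
    with open(directory / "fid", "wb") as fh:
        fh.write(struct.pack(">iiii", _VARIAN_MAGIC, n_complex, acq.group_delay, 0))
        payload.tofile(fh)
    lines = [
        f"sw {acq.sw_hz!r}",
        f"sfrq {acq.sf_mhz!r}",
        f"tof {acq.o1_ppm * acq.sf_mhz!r}",
        f"np {2 * n_complex}",
        f"grpdly {acq.group_delay}",
    ]
    if acq.temperature_c is not None:
        lines.append(f"temp {acq.temperature_c!r}")
    (directory / "procpar").write_text("\n".join(lines) + "\n")
    return directory
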