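"""Core in-memory containers for NMR time- and frequency-domain data.

Axis convention used throughout the package
-------------------------------------------
A 1D acquisition with spectral width ``sw_hz`` (Hz), spectrometer frequency
``sf_mhz`` (MHz), transmitter offset ``o1_ppm`` (ppm) and ``n`` complex
points places frequency-domain point ``j`` (0-based, left to right) at

    ppm[j] = o1_ppm + (sw_hz / 2 - j * sw_hz / n) / sf_mhz

so the ppm axis is strictly decreasing and the carrier (``o1_ppm``) sits at
the centre index ``n // 2``.  Point ``k`` of the FID is sampled at
``t = k * dt`` with dwell time ``dt = 1 / sw_hz``.

Every processing operation appends an append-only history record
``(op_name, params)`` so that any processed object can be reconstructed by
replaying its history on the raw input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np

__all__ = [
    "AcqParams",
    "Fid1D",
    "Fid2D",
    "Spectrum1D",
    "Spectrum2D",
    "SpectrumSeries",
    "ppm_axis",
    "hz_axis",
]


@dataclass(frozen=True)
class AcqParams:
    """Acquisition parameters of one dimension.

    Parameters
    ----------
    sw_hz : float
        Spectral width in Hz (> 0).
    sf_mhz : float
        Spectrometer (observe) frequency in MHz (> 0).
    o1_ppm : float
        Transmitter offset position in ppm.
    n_points : int
        Number of complex points (>= 2).
    group_delay : int
        Digital-filter delay in points (>= 0); present on disk, never in
        memory.
    temperature_c : float or None
        Sample temperature in Celsius (needed for water referencing).
    """

    sw_hz: float
    sf_mhz: float
    o1_ppm: float
    n_points: int
    group_delay: int = 0
    temperature_c: float | None = None

    def __post_init__(self) -> None:
        if self.sw_hz <= 0:
            raise ValueError("sw_hz must be > 0")
        if self.sf_mhz <= 0:
            raise ValueError("sf_mhz must be > 0")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.group_delay < 0 or int(self.group_delay) != self.group_delay:
            raise ValueError("group_delay must be a non-negative integer")

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.sw_hz

    @property
    def sw_ppm(self) -> float:
        return self.sw_hz / self.sf_mhz

    def with_points(self, n: int) -> "AcqParams":
        return replace(self, n_points=int(n))


def ppm_axis(acq: AcqParams, n: int | None = None) -> np.ndarray:
    """Descending ppm axis for ``n`` (default ``acq.n_points``) points."""
    n = acq.n_points if n is None else int(n)
    j = np.arange(n)
    return acq.o1_ppm + (acq.sw_hz / 2.0 - j * acq.sw_hz / n) / acq.sf_mhz


def hz_axis(sw_hz: float, n: int) -> np.ndarray:
    """Descending offset-frequency axis in Hz, centred on 0."""
    j = np.arange(n)
    return sw_hz / 2.0 - j * sw_hz / n


def _as_history(history: Sequence[tuple[str, dict]] | None) -> list[tuple[str, dict]]:
    return list(history) if history else []


@dataclass
class Fid1D:
    """Complex 1D free induction decay plus acquisition parameters."""

    data: np.ndarray
    acq: AcqParams
    history: list[tuple[str, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 1:
            raise ValueError("Fid1D data must be one-dimensional")
        if len(self.data) != self.acq.n_points:
            raise ValueError(
                f"data length {len(self.data)} != acq.n_points {self.acq.n_points}"
            )

    def evolve(self, data: np.ndarray, acq: AcqParams | None, op: str, params: dict) -> "Fid1D":
        return Fid1D(data, acq or self.acq, self.history + [(op, dict(params))])

    def copy(self) -> "Fid1D":
        return Fid1D(self.data.copy(), self.acq, list(self.history))


@dataclass
class Fid2D:
    """2D time-domain data.

    ``data`` holds the first quadrature channel as a complex matrix with one
    row per t1 increment; ``data_b`` optionally holds the second channel.
    ``scheme`` names the indirect-dimension quadrature convention:

    * ``"states"`` — ``data``/``data_b`` are cosine/sine amplitude-modulated
      t1 channels (used for J-resolved data);
    * ``"echo-antiecho"`` — ``data``/``data_b`` are the echo and anti-echo
      gradient-selected channels (HSQC);
    * ``None`` — single-channel complex modulation.
    """

    data: np.ndarray
    acq_f1: AcqParams
    acq_f2: AcqParams
    data_b: np.ndarray | None = None
    scheme: str | None = None
    f1_unit: str = "ppm"
    history: list[tuple[str, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 2:
            raise ValueError("Fid2D data must be a matrix")
        if self.data_b is not None:
            self.data_b = np.asarray(self.data_b, dtype=np.complex128)
            if self.data_b.shape != self.data.shape:
                raise ValueError("quadrature channels must have equal shapes")
        if self.data.shape != (self.acq_f1.n_points, self.acq_f2.n_points):
            raise ValueError("data shape does not match acquisition parameters")


@dataclass
class Spectrum1D:
    """Frequency-domain 1D spectrum on a descending ppm axis."""

    data: np.ndarray
    ppm: np.ndarray
    acq: AcqParams
    history: list[tuple[str, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.data.shape != self.ppm.shape:
            raise ValueError("data and ppm axis lengths differ")
        if len(self.ppm) > 1 and not np.all(np.diff(self.ppm) < 0):
            raise ValueError("ppm axis must be strictly decreasing")

    @property
    def real(self) -> np.ndarray:
        return np.real(self.data)

    def evolve(self, data: np.ndarray, op: str, params: dict, ppm: np.ndarray | None = None) -> "Spectrum1D":
        return Spectrum1D(
            data,
            self.ppm if ppm is None else ppm,
            self.acq,
            self.history + [(op, dict(params))],
        )

    def index_of_ppm(self, value: float) -> int:
        """Grid index closest to a ppm value."""
        return int(np.argmin(np.abs(self.ppm - value)))

    def copy(self) -> "Spectrum1D":
        return Spectrum1D(self.data.copy(), self.ppm.copy(), self.acq, list(self.history))


@dataclass
class Spectrum2D:
    """Real-valued 2D spectrum on descending F1/F2 axes.

    ``axis_f1`` is in ppm for HSQC-type data and in Hz for J-resolved data
    (``f1_unit`` records which).
    """

    data: np.ndarray
    axis_f1: np.ndarray
    axis_f2: np.ndarray
    acq_f1: AcqParams
    acq_f2: AcqParams
    f1_unit: str = "ppm"
    history: list[tuple[str, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.axis_f1 = np.asarray(self.axis_f1, dtype=float)
        self.axis_f2 = np.asarray(self.axis_f2, dtype=float)
        if self.data.shape != (len(self.axis_f1), len(self.axis_f2)):
            raise ValueError("axis lengths do not match matrix shape")

    def evolve(self, data: np.ndarray, op: str, params: dict) -> "Spectrum2D":
        return Spectrum2D(
            data, self.axis_f1, self.axis_f2, self.acq_f1, self.acq_f2,
            self.f1_unit, self.history + [(op, dict(params))],
        )

    def copy(self) -> "Spectrum2D":
        return Spectrum2D(
            self.data.copy(), self.axis_f1.copy(), self.axis_f2.copy(),
            self.acq_f1, self.acq_f2, self.f1_unit, list(self.history),
        )


@dataclass
class SpectrumSeries:
    """Stack of real 1D spectra sharing one ppm axis.

    Excluded spectra and excluded axis regions are carried but flagged —
    they are never silently dropped; downstream scaling, bucketing and
    export operate on included entries only.
    """

    matrix: np.ndarray
    ppm: np.ndarray
    classes: list[str] = field(default_factory=list)
    included_spectra: np.ndarray | None = None
    included_mask: np.ndarray | None = None
    post_state: list[tuple[str, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("series matrix must be 2D (spectra x points)")
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.matrix.shape[1] != len(self.ppm):
            raise ValueError("matrix column count != ppm axis length")
        n = self.matrix.shape[0]
        if not self.classes:
            self.classes = [""] * n
        if len(self.classes) != n:
            raise ValueError("one class label per spectrum required")
        if self.included_spectra is None:
            self.included_spectra = np.ones(n, dtype=bool)
        else:
            self.included_spectra = np.asarray(self.included_spectra, dtype=bool)
        if self.included_mask is None:
            self.included_mask = np.ones(len(self.ppm), dtype=bool)
        else:
            self.included_mask = np.asarray(self.included_mask, dtype=bool)

    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[0]

    def included_submatrix(self) -> np.ndarray:
        """Rows of included spectra restricted to included axis points."""
        return self.matrix[np.ix_(self.included_spectra, self.included_mask)]

    def evolve(self, op: str, params: dict[str, Any], **changes: Any) -> "SpectrumSeries":
        out = SpectrumSeries(
            changes.get("matrix", self.matrix.copy()),
            changes.get("ppm", self.ppm.copy()),
            list(changes.get("classes", self.classes)),
            changes.get("included_spectra", self.included_spectra.copy()),
            changes.get("included_mask", self.included_mask.copy()),
            self.post_state + [(op, dict(params))],
        )
        return out

    def copy(self) -> "SpectrumSeries":
        return SpectrumSeries(
            self.matrix.copy(), self.ppm.copy(), list(self.classes),
            self.included_spectra.copy(), self.included_mask.copy(),
            list(self.post_state),
        )


def from_spectra(spectra: Sequence[Spectrum1D], classes: Sequence[str] | None = None) -> SpectrumSeries:
    """Stack finalized (real) 1D spectra into a series on their common axis."""
    if not spectra:
        raise ValueError("cannot build a series from zero spectra")
    axis = spectra[0].ppm
    for s in spectra[1:]:
        if len(s.ppm) != len(axis) or not np.allclose(s.ppm, axis, rtol=0, atol=1e-12):
            raise ValueError("all spectra must share one ppm axis")
    mat = np.vstack([np.real(s.data) for s in spectra])
    return SpectrumSeries(mat, axis.copy(), list(classes) if classes else [])
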