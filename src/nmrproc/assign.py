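"""Library-driven assignment of 1H,13C-HSQC spectra.

For every (metabolite, atom) entry of a shift library, a tolerance box
(region of interest) is centred on the library position and the strict
8-neighbourhood local maximum closest to the centre — in
tolerance-normalised distance — is picked.  Reported intensity is the grid
value at the picked position.  Duplicate picks (two assignments claiming
one grid point) and ambiguous picks (another library entry's ROI also
containing the picked position) are flagged rather than resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import Spectrum2D
from .io import ShiftLibrary

__all__ = [
    "Roi",
    "Assignment",
    "DEFAULT_TOL",
    "pick_peak_roi",
    "assign_spectrum",
    "detect_duplicates",
    "transfer_assignments",
    "intensity_table",
]

#: default ROI half-widths (1H ppm, 13C ppm)
DEFAULT_TOL = (0.03, 0.3)


@dataclass(frozen=True)
class Roi:
    """Tolerance box around a library position: ``center`` and ``tol`` are
    (1H ppm, 13C ppm) pairs; both tolerances must be positive."""

    center: tuple[float, float]
    tol: tuple[float, float] = DEFAULT_TOL

    def __post_init__(self) -> None:
        if self.tol[0] <= 0 or self.tol[1] <= 0:
            raise ValueError("ROI tolerances must be > 0 in both dimensions")


@dataclass(frozen=True)
class Assignment:
    metabolite: str
    atom_label: str
    library_pos: tuple[float, float]
    picked_pos: tuple[float, float] | None
    intensity: float | None
    status: str  # ok | no_peak | duplicate | ambiguous
    candidates: tuple = ()  # alternative (metabolite, atom) claims


def _local_maxima(data: np.ndarray) -> np.ndarray:
    """Boolean mask of strict 8-neighbourhood local maxima (plateau points
    excluded; border points can qualify against their existing neighbours)."""
    d = data
    mask = np.ones_like(d, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            shifted = np.full_like(d, -np.inf)
            src_i = slice(max(0, di), d.shape[0] + min(0, di))
            dst_i = slice(max(0, -di), d.shape[0] + min(0, -di))
            src_j = slice(max(0, dj), d.shape[1] + min(0, dj))
            dst_j = slice(max(0, -dj), d.shape[1] + min(0, -dj))
            shifted[dst_i, dst_j] = d[src_i, src_j]
            mask &= d > shifted
    return mask


def pick_peak_roi(spec: Spectrum2D, roi: Roi):
    """Closest local maximum inside the ROI.

    Among grid points inside the box that are strict local maxima, return
    ``((h_ppm, c_ppm), intensity)`` for the one minimising
    sqrt((dH/h_tol)^2 + (dC/c_tol)^2) from the ROI centre; exact distance
    ties go to the higher intensity.  Returns ``None`` when the ROI holds
    no local maximum.
    """
    (h0, c0), (ht, ct) = roi.center, roi.tol
    h_ax, c_ax = spec.axis_f2, spec.axis_f1  # F2 = 1H, F1 = 13C
    jj = np.where(np.abs(h_ax - h0) <= ht)[0]
    ii = np.where(np.abs(c_ax - c0) <= ct)[0]
    if len(ii) == 0 or len(jj) == 0:
        return None
    maxima = _local_maxima(spec.data)
    best = None  # (distance, -intensity, position)
    for i in ii:
        for j in jj:
            if not maxima[i, j]:
                continue
            d = float(np.hypot((h_ax[j] - h0) / ht, (c_ax[i] - c0) / ct))
            val = float(spec.data[i, j])
            if best is None or d < best[0] - 1e-9 or (
                    d <= best[0] + 1e-9 and val > -best[1]):
                best = (d, -val, (float(h_ax[j]), float(c_ax[i])))
    if best is None:
        return None
    return best[2], -best[1]


def assign_spectrum(spec: Spectrum2D, lib: ShiftLibrary, metabolites,
                    tol: tuple[float, float] = DEFAULT_TOL) -> list[Assignment]:
    """One Assignment per (metabolite, atom) of the requested metabolites.

    A pick whose position also falls inside the ROI of a different library
    entry is flagged ``ambiguous`` with the competing entries attached;
    exact grid collisions are then flagged ``duplicate`` by
    :func:`detect_duplicates`.
    """
    entries = []
    for met in metabolites:
        for label, h, c in lib.peaks(met):  # KeyError for unknown metabolite
            entries.append((met, label, (float(h), float(c))))
    out: list[Assignment] = []
    for met, label, pos in entries:
        picked = pick_peak_roi(spec, Roi(pos, tol))
        if picked is None:
            out.append(Assignment(met, label, pos, None, None, "no_peak"))
            continue
        p, val = picked
        rivals = tuple(
            (m2, l2) for m2, l2, pos2 in entries
            if (m2, l2) != (met, label)
            and abs(pos2[0] - p[0]) <= tol[0] and abs(pos2[1] - p[1]) <= tol[1]
        )
        status = "ambiguous" if rivals else "ok"
        out.append(Assignment(met, label, pos, p, val, status, rivals))
    return detect_duplicates(out)


def detect_duplicates(assignments: list[Assignment]) -> list[Assignment]:
    """Flag every group of assignments sharing one picked grid position."""
    counts: dict[tuple[float, float], int] = {}
    for a in assignments:
        if a.picked_pos is not None:
            counts[a.picked_pos] = counts.get(a.picked_pos, 0) + 1
    return [
        replace(a, status="duplicate")
        if a.picked_pos is not None and counts[a.picked_pos] > 1 else a
        for a in assignments
    ]


def transfer_assignments(assignments: list[Assignment], spec_target: Spectrum2D,
                         tol: tuple[float, float] = DEFAULT_TOL) -> list[Assignment]:
    """Re-pick each assignment on another spectrum, using the source picked
    position (falling back to the library position) as the new ROI centre;
    absorbs small global shifts, e.g. from pH differences."""
    out: list[Assignment] = []
    for a in assignments:
        center = a.picked_pos if a.picked_pos is not None else a.library_pos
        picked = pick_peak_roi(spec_target, Roi(center, tol))
        if picked is None:
            out.append(replace(a, picked_pos=None, intensity=None, status="no_peak"))
        else:
            p, val = picked
            out.append(replace(a, picked_pos=p, intensity=val, status="ok"))
    return detect_duplicates(out)


def intensity_table(spectra: list[Spectrum2D], assignments: list[Assignment],
                    tol: tuple[float, float] = DEFAULT_TOL) -> pd.DataFrame:
    """Intensity matrix (assignment rows x spectrum columns).

    Assignments are transferred to each spectrum in turn; ``no_peak`` cells
    are left empty (NaN).  The first columns carry the library and picked
    positions from the source assignment.
    """
    rows = {
        "metabolite": [a.metabolite for a in assignments],
        "atom": [a.atom_label for a in assignments],
        "library_h_ppm": [a.library_pos[0] for a in assignments],
        "library_c_ppm": [a.library_pos[1] for a in assignments],
    }
    df = pd.DataFrame(rows)
    for k, spec in enumerate(spectra):
        transferred = transfer_assignments(assignments, spec, tol)
        df[f"spectrum_{k}"] = [
            a.intensity if a.intensity is not None else np.nan for a in transferred
        ]
    return df
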