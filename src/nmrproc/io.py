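"""Vendor-dialect readers, metabolite shift library, and matrix export.

The two on-disk dialects (Bruker-style ``fid``/``ser`` + ``acqus`` and
Varian-style ``fid`` + ``procpar``) are documented in ``docs/formats.md``;
the matching writers live in :mod:`nmrproc.synthetic`.  Readers are total
on writer output: write -> read recovers the FID up to integer/float32
quantization (exactly, when the stored scale maps values onto integers).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AcqParams, Fid1D, Fid2D, SpectrumSeries

__all__ = [
    "read_bruker",
    "read_varian",
    "ShiftLibrary",
    "load_library",
    "save_library",
    "export_matrix",
    "read_matrix",
]


class ParseError(ValueError):
    """Malformed vendor file or library file."""


# ---------------------------------------------------------------------------
# Bruker-style dialect


def _read_acqus(path: Path) -> dict[str, str]:
    if not path.is_file():
        raise ParseError(f"missing parameter file {path}")
    params: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if line.startswith("##$") and "=" in line:
            key, _, value = line[3:].partition("=")
            params[key.strip()] = value.strip()
    return params


def _require(params: dict[str, str], key: str, path: Path) -> str:
    if key not in params:
        raise ParseError(f"mandatory key {key} missing from {path}")
    return params[key]


def _acq_from_bruker(params: dict[str, str], path: Path) -> tuple[AcqParams, float, int]:
    sw = float(_require(params, "SW", path))
    sfo1 = float(_require(params, "SFO1", path))
    o1_hz = float(_require(params, "O1", path))
    td = int(_require(params, "TD", path))
    if td % 2 != 0:
        raise ParseError(f"TD={td} in {path} is odd; complex pairs expected")
    grpdly = int(float(params.get("GRPDLY", "0")))
    scale = float(params.get("SCALE", "1"))
    temp = params.get("TE")
    acq = AcqParams(
        sw_hz=sw, sf_mhz=sfo1, o1_ppm=o1_hz / sfo1,
        n_points=td // 2 - grpdly, group_delay=grpdly,
        temperature_c=float(temp) - 273.15 if temp is not None else None,
    )
    return acq, scale, td


def _deinterleave(raw: np.ndarray) -> np.ndarray:
    return raw[0::2] + 1j * raw[1::2]


def _strip_group_delay(data: np.ndarray, grpdly: int) -> np.ndarray:
    """Remove the digital-filter delay by circular left shift, then drop
    the trailing delay points."""
    if grpdly == 0:
        return data
    return np.roll(data, -grpdly)[: len(data) - grpdly]


def read_bruker(directory: str | Path) -> Fid1D | Fid2D:
    """Read a Bruker-style dataset directory (``fid`` -> Fid1D,
    ``ser`` -> Fid2D)."""
    directory = Path(directory)
    params = _read_acqus(directory / "acqus")
    acq, scale, td = _acq_from_bruker(params, directory / "acqus")
    bytorda = int(params.get("BYTORDA", "0"))
    dtype = "<i4" if bytorda == 0 else ">i4"

    ser = directory / "ser"
    if ser.is_file():
        params2 = _read_acqus(directory / "acqu2s")
        acq1, _, _ = _acq_from_bruker(params2, directory / "acqu2s")
        nchan = int(params2.get("NCHAN", "1"))
        scheme = params.get("QUADSCHEME", "none")
        f1_unit = params.get("F1UNIT", "ppm")
        raw = np.fromfile(ser, dtype=dtype).astype(float) / scale
        expect = nchan * acq1.n_points * (td // 2) * 2
        if raw.size != expect:
            raise ParseError(
                f"ser file has {raw.size} values, expected {expect}")
        cx = _deinterleave(raw).reshape(nchan * acq1.n_points, td // 2)
        if nchan == 2:
            data, data_b = cx[0::2], cx[1::2]
        else:
            data, data_b = cx, None
        return Fid2D(data, acq1, acq, data_b=data_b,
                     scheme=None if scheme == "none" else scheme,
                     f1_unit=f1_unit, history=[("read_bruker", {"path": str(directory)})])

    binary = directory / "fid"
    if not binary.is_file():
        raise ParseError(f"no fid or ser file in {directory}")
    raw = np.fromfile(binary, dtype=dtype)
    if raw.size != td:
        raise ParseError(
            f"fid file has {raw.size} values but TD={td} in acqus")
    data = _deinterleave(raw.astype(float) / scale)
    data = _strip_group_delay(data, acq.group_delay)
    return Fid1D(data, acq, [("read_bruker", {"path": str(directory)})])


# ---------------------------------------------------------------------------
# Varian-style dialect

_VARIAN_MAGIC = 0x6E6D7266


def _read_procpar(path: Path) -> dict[str, str]:
    if not path.is_file():
        raise ParseError(f"missing parameter file {path}")
    params: dict[str, str] = {}
    for line in path.read_text().splitlines():
        parts = line.split()
        if len(parts) >= 2:
            params[parts[0]] = parts[1]
    return params


def read_varian(directory: str | Path) -> Fid1D:
    """Read a Varian-style dataset directory into a Fid1D."""
    directory = Path(directory)
    params = _read_procpar(directory / "procpar")
    for key in ("sw", "sfrq", "tof", "np"):
        if key not in params:
            raise ParseError(f"mandatory key {key} missing from {directory / 'procpar'}")
    sw, sfrq = float(params["sw"]), float(params["sfrq"])
    tof, np_total = float(params["tof"]), int(params["np"])
    grpdly = int(float(params.get("grpdly", "0")))
    temp = float(params["temp"]) if "temp" in params else None
    if np_total % 2 != 0:
        raise ParseError(f"np={np_total} is odd; complex pairs expected")

    binary = directory / "fid"
    if not binary.is_file():
        raise ParseError(f"no fid file in {directory}")
    with open(binary, "rb") as fh:
        header = fh.read(16)
        if len(header) < 16:
            raise ParseError("truncated Varian-style header")
        magic, n_complex, h_grpdly, _ = struct.unpack(">iiii", header)
        if magic != _VARIAN_MAGIC:
            raise ParseError("bad magic number in Varian-style fid file")
        raw = np.fromfile(fh, dtype=">f4")
    if raw.size != 2 * n_complex or n_complex != np_total // 2:
        raise ParseError("Varian-style fid file truncated or inconsistent with procpar")
    data = _strip_group_delay(_deinterleave(raw.astype(float)), h_grpdly)
    acq = AcqParams(sw_hz=sw, sf_mhz=sfrq, o1_ppm=tof / sfrq,
                    n_points=n_complex - h_grpdly, group_delay=grpdly,
                    temperature_c=temp)
    return Fid1D(data, acq, [("read_varian", {"path": str(directory)})])


# ---------------------------------------------------------------------------
# metabolite chemical-shift library
#
# Text schema (one metabolite block, one atom per line):
#
#   [metabolite name]
#   ATOM_LABEL  1H_ppm  13C_ppm
#
# Blank lines and '#' comments are ignored.


@dataclass
class ShiftLibrary:
    """Metabolite name -> list of (atom_label, 1H ppm, 13C ppm)."""

    entries: dict[str, list[tuple[str, float, float]]] = field(default_factory=dict)

    def metabolites(self) -> list[str]:
        return list(self.entries)

    def peaks(self, metabolite: str) -> list[tuple[str, float, float]]:
        if metabolite not in self.entries:
            raise KeyError(f"metabolite {metabolite!r} not in library")
        return list(self.entries[metabolite])

    def add_metabolite(self, name: str, peaks: list[tuple[str, float, float]],
                       overwrite: bool = False) -> "ShiftLibrary":
        if name in self.entries and not overwrite:
            raise ValueError(f"metabolite {name!r} already in library "
                             "(pass overwrite=True to replace)")
        labels = [p[0] for p in peaks]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate atom labels within {name!r}: {dupes}")
        self.entries[name] = [(str(l), float(h), float(c)) for l, h, c in peaks]
        return self


def load_library(path: str | Path) -> ShiftLibrary:
    lib = ShiftLibrary()
    current: str | None = None
    peaks: list[tuple[str, float, float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            if current is not None:
                lib.add_metabolite(current, peaks)
            current, peaks = line[1:-1].strip(), []
            continue
        parts = line.split()
        if current is None or len(parts) != 3:
            raise ParseError(f"{path}:{lineno}: expected 'LABEL H_ppm C_ppm' inside a "
                             "[metabolite] block")
        try:
            peaks.append((parts[0], float(parts[1]), float(parts[2])))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    if current is not None:
        lib.add_metabolite(current, peaks)
    return lib


def save_library(lib: ShiftLibrary, path: str | Path) -> Path:
    lines = ["# nmrproc metabolite shift library", ""]
    for name, peaks in lib.entries.items():
        lines.append(f"[{name}]")
        for label, h, c in peaks:
            lines.append(f"{label}  {h:.4f}  {c:.4f}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
    return Path(path)


def bundled_library() -> ShiftLibrary:
    """The small shift library shipped with the package."""
    return load_library(Path(__file__).parent / "data" / "library.txt")


# ---------------------------------------------------------------------------
# data-matrix export for multivariate statistics


def export_matrix(series: SpectrumSeries, path: str | Path) -> Path:
    """Write the included spectra x included points matrix as CSV with a
    ppm header (4 decimals) and leading id/class columns."""
    if not np.any(series.included_spectra):
        raise ValueError("no included spectra to export")
    sub = series.included_submatrix()
    ppm = series.ppm[series.included_mask]
    ids = np.where(series.included_spectra)[0]
    df = pd.DataFrame(sub, columns=[f"{p:.4f}" for p in ppm])
    df.insert(0, "class", [series.classes[i] for i in ids])
    df.insert(0, "id", ids)
    df.to_csv(path, index=False)
    return Path(path)


def read_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[int], list[str]]:
    """Read back an exported matrix: (matrix, ppm, ids, classes)."""
    df = pd.read_csv(path, keep_default_na=False)
    ids = [int(i) for i in df["id"]]
    classes = [str(c) for c in df["class"]]
    ppm = np.array([float(c) for c in df.columns[2:]])
    return df.iloc[:, 2:].to_numpy(dtype=float), ppm, ids, classes
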