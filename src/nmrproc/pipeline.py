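"""Declarative processing pipelines: the script builder as data.

A pipeline configuration is a YAML document listing input FID directories,
an ordered list of fully parameterised processing steps, and an output
directory.  Configurations are validated completely — step names, parameter
names, types and value constraints, and stage ordering — before any data is
touched.  Running a pipeline writes the exported data matrix plus a JSON
run log recording every step, its parameters and content hashes of the
outputs, so identical configurations and inputs always reproduce identical
hashes.  :func:`emit_script` converts a configuration into an equivalent
stand-alone, human-editable Python runner.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as nio
from . import postproc as pp
from . import proc1d as p1
from .core import Fid1D, SpectrumSeries, from_spectra

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "run_pipeline",
           "emit_script", "preset_path", "list_presets"]


class ConfigError(ValueError):
    """Invalid pipeline configuration (reported before execution)."""


def _positive(x):
    return x > 0


def _nonneg(x):
    return x >= 0


# name -> (stage, {param: (types, required, check)})
_FLOATS = (int, float)
OPS: dict[str, tuple[str, dict]] = {
    "zero_fill": ("fid", {"factor": (_FLOATS, False, _positive),
                          "target_points": ((int,), False, lambda v: v >= 2)}),
    "apodize": ("fid", {"kind": ((str,), True, lambda v: v in ("em", "cos2", "sem")),
                        "lb": (_FLOATS, False, _nonneg)}),
    "gibbs_correct": ("fid", {}),
    "water_filter": ("fid", {"method": ((str,), False,
                                        lambda v: v in ("moving_average", "gaussian")),
                             "width_hz": (_FLOATS, False, _positive)}),
    "fourier_transform": ("ft", {}),
    "phase": ("spectrum", {"phi0_deg": (_FLOATS, True, lambda v: True),
                           "phi1_deg": (_FLOATS, False, lambda v: True)}),
    "autophase": ("spectrum", {"algorithm": ((str,), False,
                                             lambda v: v in ("tmsp", "ends", "auto"))}),
    "dc_correct": ("spectrum", {"noise_region_ppm": ((list, tuple), True,
                                                     lambda v: len(v) == 2)}),
    "reference": ("spectrum", {"standard": ((str,), False,
                                            lambda v: v.upper() in ("TMSP", "DSS", "TMS")),
                               "search_window_ppm": ((list, tuple), False,
                                                     lambda v: len(v) == 2)}),
    "reference_to_water": ("spectrum", {}),
    "baseline_spline": ("series", {
        "baseline_points": ((list, tuple), True, lambda v: len(v) >= 4),
        "baseline_average_points": ((int,), False, lambda v: v >= 1 and v % 2 == 1),
        "linear": ((bool,), False, lambda v: True),
        "linear_points": ((int,), False, _nonneg)}),
    "exclude_regions": ("series", {"regions": ((list, tuple), True,
                                               lambda v: all(len(r) == 2 for r in v))}),
    "assign_classes": ("series", {"labels": ((list, tuple), True, lambda v: True)}),
    "exclude_spectra": ("series", {"ids": ((list, tuple), True, lambda v: True)}),
    "align_to_tmsp": ("series", {"search_window_ppm": ((list, tuple), False,
                                                       lambda v: len(v) == 2)}),
    "align_to_reference": ("series", {"ref_index": ((int,), False, _nonneg),
                                      "max_shift": ((int,), False, _positive)}),
    "scale_total_area": ("series", {}),
    "scale_pqn": ("series", {}),
    "scale_to_tmsp": ("series", {"window_ppm": ((list, tuple), False,
                                                lambda v: len(v) == 2)}),
    "glog": ("series", {"lam": (_FLOATS + (str,), False,
                                lambda v: v == "auto" if isinstance(v, str) else v > 0),
                        "y0": (_FLOATS, False, lambda v: True)}),
    "pareto": ("series", {}),
    "autoscale": ("series", {}),
    "bucket": ("series", {"width_ppm": (_FLOATS, True, _positive)}),
}

_STAGE_ORDER = {"fid": 0, "ft": 1, "spectrum": 2, "series": 3}


@dataclass
class PipelineConfig:
    inputs: list[str]
    steps: list[dict]
    output: str
    fmt: str = "auto"
    classes: list[str] = field(default_factory=list)
    seed: int = 0

    def stage_of(self, i: int) -> str:
        return OPS[self.steps[i]["op"]][0]


def _validate_step(i: int, step: dict) -> None:
    if not isinstance(step, dict) or "op" not in step:
        raise ConfigError(f"step {i}: every step needs an 'op' field")
    op = step["op"]
    if op not in OPS:
        raise ConfigError(f"step {i}: unknown operation {op!r}")
    _, schema = OPS[op]
    for name, value in step.items():
        if name == "op":
            continue
        if name not in schema:
            raise ConfigError(f"step {i} ({op}): unknown parameter {name!r}")
        types, _, check = schema[name]
        if isinstance(value, bool) and bool not in types:
            raise ConfigError(f"step {i} ({op}): parameter {name!r} has wrong type")
        if not isinstance(value, types):
            raise ConfigError(f"step {i} ({op}): parameter {name!r} has wrong type")
        if not check(value):
            raise ConfigError(f"step {i} ({op}): parameter {name!r} violates its "
                              "contract")
    for name, (_, required, _) in schema.items():
        if required and name not in step:
            raise ConfigError(f"step {i} ({op}): missing required parameter {name!r}")


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Parse and fully validate a pipeline configuration (path to a YAML
    file, YAML text, or an already-parsed mapping)."""
    if isinstance(source, dict):
        raw = source
    else:
        path = Path(source)
        text = path.read_text() if path.is_file() else str(source)
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    for key in ("inputs", "steps", "output"):
        if key not in raw:
            raise ConfigError(f"missing required field {key!r}")
    known = {"inputs", "steps", "output", "format", "classes", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown configuration fields: {sorted(unknown)}")
    steps = list(raw["steps"] or [])
    for i, step in enumerate(steps):
        _validate_step(i, step)
    stages = [_STAGE_ORDER[OPS[s["op"]][0]] for s in steps]
    if stages != sorted(stages):
        raise ConfigError("steps out of stage order: time-domain steps must precede "
                          "fourier_transform, spectrum steps the series steps")
    if stages.count(1) > 1:
        raise ConfigError("fourier_transform may appear only once")
    cfg = PipelineConfig(
        inputs=[str(p) for p in raw["inputs"]],
        steps=steps,
        output=str(raw["output"]),
        fmt=str(raw.get("format", "auto")),
        classes=[str(c) for c in raw.get("classes", [])],
        seed=int(raw.get("seed", 0)),
    )
    if cfg.fmt not in ("auto", "bruker", "varian"):
        raise ConfigError(f"unknown input format {cfg.fmt!r}")
    if cfg.classes and len(cfg.classes) != len(cfg.inputs):
        raise ConfigError("classes must have one label per input")
    return cfg


def _read_input(directory: str, fmt: str) -> Fid1D:
    d = Path(directory)
    if fmt == "bruker" or (fmt == "auto" and (d / "acqus").is_file()):
        fid = nio.read_bruker(d)
    elif fmt == "varian" or (fmt == "auto" and (d / "procpar").is_file()):
        fid = nio.read_varian(d)
    else:
        raise nio.ParseError(f"cannot identify the dialect of {d}")
    if not isinstance(fid, Fid1D):
        raise nio.ParseError(f"{d} holds 2D data; the batch pipeline processes 1D FIDs")
    return fid


def _apply_fid_step(fid: Fid1D, step: dict) -> Fid1D:
    op = step["op"]
    if op == "zero_fill":
        target = step.get("target_points") or int(len(fid.data) * step.get("factor", 2))
        return p1.zero_fill(fid, target)
    if op == "apodize":
        return p1.apodize(fid, p1.ApodParams(step["kind"], step.get("lb", 0.0)))
    if op == "gibbs_correct":
        return p1.gibbs_correct(fid)
    if op == "water_filter":
        return p1.water_filter(fid, step.get("method", "moving_average"),
                               step.get("width_hz", 30.0))
    raise AssertionError(op)


def _apply_spectrum_step(spec, step: dict):
    op = step["op"]
    if op == "phase":
        return p1.phase(spec, p1.PhaseParams(step["phi0_deg"], step.get("phi1_deg", 0.0)))
    if op == "autophase":
        algo = step.get("algorithm", "auto")
        if algo in ("tmsp", "auto"):
            try:
                return p1.phase(spec, p1.autophase_tmsp(spec))
            except ValueError:
                if algo == "tmsp":
                    raise
        return p1.phase(spec, p1.autophase_ends(spec))
    if op == "dc_correct":
        return p1.dc_correct(spec, tuple(step["noise_region_ppm"]))
    if op == "reference":
        return p1.reference_to_standard(
            spec, step.get("standard", "TMSP"),
            tuple(step.get("search_window_ppm", (-0.5, 0.5))))
    if op == "reference_to_water":
        return p1.reference_to_water(spec)
    raise AssertionError(op)


def _apply_series_step(series: SpectrumSeries, step: dict) -> SpectrumSeries:
    op = step["op"]
    if op == "baseline_spline":
        return pp.baseline_spline(series, pp.BaselineSplineParams(
            tuple(step["baseline_points"]),
            step.get("baseline_average_points", 1),
            step.get("linear", False), step.get("linear_points", 0)))
    if op == "exclude_regions":
        return pp.exclude_regions(series, [tuple(r) for r in step["regions"]])
    if op == "assign_classes":
        return pp.assign_classes(series, list(step["labels"]))
    if op == "exclude_spectra":
        return pp.exclude_spectra(series, list(step["ids"]))
    if op == "align_to_tmsp":
        return pp.align_to_tmsp(series, tuple(step.get("search_window_ppm", (-0.3, 0.3))))
    if op == "align_to_reference":
        return pp.align_to_reference(series, step.get("ref_index", 0),
                                     step.get("max_shift", 100))
    if op == "scale_total_area":
        return pp.scale_total_area(series)
    if op == "scale_pqn":
        return pp.scale_pqn(series)
    if op == "scale_to_tmsp":
        return pp.scale_to_tmsp(series, tuple(step.get("window_ppm", (-0.05, 0.05))))
    if op == "glog":
        lam = step.get("lam", "auto")
        params = (pp.optimize_glog_lambda(series, y0=step.get("y0", 0.0))
                  if lam == "auto" else pp.GlogParams(float(lam), step.get("y0", 0.0)))
        return pp.glog_transform(series, params)
    if op == "pareto":
        return pp.pareto(series)
    if op == "autoscale":
        return pp.autoscale(series)
    if op == "bucket":
        return pp.bucket(series, float(step["width_ppm"]))
    raise AssertionError(op)


def _on_common_axis(spectra):
    """Resample referenced spectra onto the first spectrum's ppm axis.

    Per-spectrum referencing displaces each axis by its own offset while
    the grid spacing stays identical; the data are rolled by the nearest
    integer number of points (sub-grid remainders, at most half a step,
    are absorbed by the later alignment steps)."""
    if len(spectra) < 2:
        return spectra
    from .core import Spectrum1D
    ref = spectra[0]
    step = float(ref.ppm[1] - ref.ppm[0])
    out = [ref]
    for s in spectra[1:]:
        if len(s.ppm) != len(ref.ppm):
            raise RuntimeError("inputs produced spectra of different lengths; "
                               "check zero_fill settings")
        r = int(round(float(s.ppm[0] - ref.ppm[0]) / step))
        data = np.roll(np.asarray(s.data), -r) if r else np.asarray(s.data)
        out.append(Spectrum1D(data, ref.ppm.copy(), s.acq,
                              s.history + [("resample_to_common_axis",
                                            {"shift_points": -r})]))
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunResult:
    series: SpectrumSeries
    matrix_path: Path
    log_path: Path
    hashes: dict[str, str]


def run_pipeline(config: PipelineConfig | str | Path | dict) -> RunResult:
    """Execute a validated pipeline over all inputs.

    Any step failure aborts the run with the offending input and step named;
    outputs written before the failure are kept.
    """
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    out_dir = Path(cfg.output)
    out_dir.mkdir(parents=True, exist_ok=True)

    fid_steps = [s for s in cfg.steps if cfg_stage(s) == "fid"]
    has_ft = any(cfg_stage(s) == "ft" for s in cfg.steps)
    spec_steps = [s for s in cfg.steps if cfg_stage(s) == "spectrum"]
    series_steps = [s for s in cfg.steps if cfg_stage(s) == "series"]

    spectra = []
    for directory in cfg.inputs:
        try:
            obj = _read_input(directory, cfg.fmt)
            for step in fid_steps:
                obj = _apply_fid_step(obj, step)
            if has_ft or spec_steps or series_steps:
                obj = p1.fourier_transform(obj)
            for step in spec_steps:
                obj = _apply_spectrum_step(obj, step)
            spectra.append(obj)
        except Exception as exc:
            raise RuntimeError(
                f"processing failed for input {directory!r}: {exc}") from exc

    if spectra and isinstance(spectra[0], Fid1D):
        raise RuntimeError("the pipeline must include a fourier_transform step "
                           "before spectra can be stacked and exported")
    series = from_spectra(_on_common_axis(spectra), cfg.classes or None)
    for k, step in enumerate(series_steps):
        try:
            series = _apply_series_step(series, step)
        except Exception as exc:
            raise RuntimeError(
                f"series step {k} ({step['op']!r}) failed: {exc}") from exc

    matrix_path = out_dir / "matrix.csv"
    nio.export_matrix(series, matrix_path)
    hashes = {"matrix.csv": _sha256(matrix_path)}
    log = {
        "inputs": cfg.inputs,
        "seed": cfg.seed,
        "steps": cfg.steps,
        "post_state": [[op, params] for op, params in series.post_state],
        "hashes": hashes,
    }
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True, default=float))
    return RunResult(series, matrix_path, log_path, hashes)


def cfg_stage(step: dict) -> str:
    return OPS[step["op"]][0]


_SCRIPT_HEADER = '''\
#!/usr/bin/env python
"""Stand-alone pipeline runner emitted by nmrproc; edit freely.

Equivalent to `nmrproc process` on the configuration embedded below.
"""

from nmrproc.pipeline import run_pipeline

CONFIG = {config!r}

if __name__ == "__main__":
    result = run_pipeline(CONFIG)
    print("wrote", result.matrix_path)
    for name, digest in result.hashes.items():
        print(name, digest)
'''


def emit_script(config: PipelineConfig | str | Path | dict, path: str | Path) -> Path:
    """Write an editable Python runner equivalent to ``run_pipeline(config)``."""
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    as_dict = {
        "inputs": cfg.inputs, "steps": cfg.steps, "output": cfg.output,
        "format": cfg.fmt, "classes": cfg.classes, "seed": cfg.seed,
    }
    Path(path).write_text(_SCRIPT_HEADER.format(config=as_dict))
    return Path(path)


def preset_path(name: str) -> Path:
    """Path of a shipped preset configuration (e.g. ``1d``)."""
    p = Path(__file__).parent / "presets" / f"{name}.yaml"
    if not p.is_file():
        raise FileNotFoundError(f"no preset named {name!r} (have: {list_presets()})")
    return p


def list_presets() -> list[str]:
    return sorted(p.stem for p in (Path(__file__).parent / "presets").glob("*.yaml"))
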