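"""File-format plumbing and manifest-driven batch runs.

The interchange dialect is plain CSV with unit-suffixed headers; images
are 8/16-bit grayscale PNG or TIFF.  A YAML manifest lists conditions
(label, squeezing-flow trace files with per-file geometry, frequency
sweeps, volume trajectories, images) and ``run_pipeline`` turns it into
a directory of per-condition result CSVs plus a plain-text log.  Runs
are deterministic: identical manifest, identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fermentation import VolumeTrajectory, strain_rates
from .lsf import LSFTrace, process_trace
from .pna import Micrograph, compute_pna
from .shear import FrequencySweep, fit_gstar
from .shi import DEFAULT_STRAIN_GRID, DEFAULT_TARGET_RATES, shi_from_processed, shi_time_course

__all__ = [
    "RunManifest",
    "ConditionSpec",
    "read_trace_csv",
    "write_trace_csv",
    "read_sweep_csv",
    "read_trajectory_csv",
    "write_csv",
    "run_pipeline",
]

_FLOAT_FMT = "%.12g"  # 12 significant digits: lossless round trip for our data

log = logging.getLogger("doughrheo")


def write_csv(df: pd.DataFrame, path: Path | str) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trace_csv(
    path: Path | str, *, platen_speed: float, initial_height: float, plate_radius: float, label: str = ""
) -> LSFTrace:
    """Read a ``time_s, force_N`` trace CSV; geometry comes from the caller
    (sidecar manifest or CLI flags)."""
    df = pd.read_csv(path)
    return LSFTrace(
        time=df["time_s"].to_numpy(),
        force=df["force_N"].to_numpy(),
        platen_speed=platen_speed,
        initial_height=initial_height,
        plate_radius=plate_radius,
        label=label or Path(path).stem,
    )


def write_trace_csv(trace: LSFTrace, path: Path | str) -> None:
    write_csv(pd.DataFrame({"time_s": trace.time, "force_N": trace.force}), path)


def read_sweep_csv(path: Path | str, *, angular: bool = False, label: str = "") -> FrequencySweep:
    """Read a ``frequency_hz, g_star_pa`` sweep CSV."""
    df = pd.read_csv(path)
    return FrequencySweep(
        frequency=df["frequency_hz"].to_numpy(),
        g_star=df["g_star_pa"].to_numpy(),
        angular=angular,
        label=label or Path(path).stem,
    )


def read_trajectory_csv(path: Path | str, *, label: str = "") -> VolumeTrajectory:
    """Read a ``time_s, v_rel`` relative-volume trajectory CSV."""
    df = pd.read_csv(path)
    return VolumeTrajectory(
        time=df["time_s"].to_numpy(), v_rel=df["v_rel"].to_numpy(), label=label or Path(path).stem
    )


def read_micrograph(path: Path | str, pixel_size: float, label: str = "") -> Micrograph:
    data = np.asarray(iio.imread(path))
    if data.ndim == 3:  # collapse an RGB(A) image to grayscale by averaging
        data = data[..., :3].mean(axis=-1)
    return Micrograph(data=data, pixel_size=pixel_size, label=label or Path(path).stem)


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition inside a manifest."""

    label: str
    traces: tuple[dict[str, Any], ...] = ()  # {path, platen_speed, initial_height, plate_radius}
    sweeps: tuple[str, ...] = ()
    trajectories: tuple[str, ...] = ()
    images: tuple[dict[str, Any], ...] = ()  # {path, pixel_size}
    target_rates: tuple[float, ...] = DEFAULT_TARGET_RATES
    strain_grid: tuple[float, ...] = DEFAULT_STRAIN_GRID


@dataclass(frozen=True)
class RunManifest:
    """Validated list of condition blocks for a batch run."""

    conditions: tuple[ConditionSpec, ...]
    source: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunManifest":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "RunManifest":
        base = base_dir or Path(".")
        blocks = raw.get("conditions", [])
        if not blocks:
            raise ValueError("manifest lists no conditions")
        conds = []
        for b in blocks:
            traces = []
            for t in b.get("traces", []):
                t = dict(t)
                t["path"] = str(base / t["path"])
                for key in ("platen_speed", "initial_height", "plate_radius"):
                    if key not in t:
                        raise ValueError(f"trace {t['path']} is missing geometry key {key!r}")
                traces.append(t)
            images = []
            for im in b.get("images", []):
                im = dict(im)
                im["path"] = str(base / im["path"])
                if "pixel_size" not in im:
                    raise ValueError(f"image {im['path']} is missing pixel_size")
                images.append(im)
            for entry in traces + images:
                if not Path(entry["path"]).exists():
                    raise FileNotFoundError(entry["path"])
            sweeps = tuple(str(base / s) for s in b.get("sweeps", []))
            trajs = tuple(str(base / s) for s in b.get("trajectories", []))
            for p in sweeps + trajs:
                if not Path(p).exists():
                    raise FileNotFoundError(p)
            conds.append(
                ConditionSpec(
                    label=str(b["label"]),
                    traces=tuple(traces),
                    sweeps=sweeps,
                    trajectories=trajs,
                    images=tuple(images),
                    target_rates=tuple(b.get("target_rates", DEFAULT_TARGET_RATES)),
                    strain_grid=tuple(b.get("strain_grid", DEFAULT_STRAIN_GRID)),
                )
            )
        return cls(conditions=tuple(conds), source=raw)


def _config_hash(manifest: RunManifest) -> str:
    blob = json.dumps(manifest.source, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _run_condition(cond: ConditionSpec, outdir: Path) -> list[str]:
    written: list[str] = []
    if cond.traces:
        processed = []
        for t in cond.traces:
            trace = read_trace_csv(
                t["path"],
                platen_speed=t["platen_speed"],
                initial_height=t["initial_height"],
                plate_radius=t["plate_radius"],
            )
            p = process_trace(trace)
            processed.append(p)
            out = outdir / f"{cond.label}_{Path(t['path']).stem}_processed.csv"
            write_csv(p.to_frame(), out)
            written.append(out.name)
        if len({p.platen_speed for p in processed}) >= 3:
            results = shi_from_processed(processed, cond.target_rates, cond.strain_grid)
            table = shi_time_course([(0.0, r) for r in results])
            table.insert(0, "condition", cond.label)
            out = outdir / f"{cond.label}_shi.csv"
            write_csv(table, out)
            written.append(out.name)
        else:
            log.warning("%s: <3 distinct speeds, SHI cascade skipped", cond.label)
    if cond.sweeps:
        rows = []
        for s in cond.sweeps:
            fitres = fit_gstar(read_sweep_csv(s))
            rows.append(
                {
                    "condition": cond.label,
                    "sweep": Path(s).stem,
                    "a_f": fitres.A_f,
                    "z": fitres.z,
                    "stderr_a_f": fitres.stderr_A_f,
                    "stderr_z": fitres.stderr_z,
                    "r2_adj": fitres.r2_adj,
                }
            )
        out = outdir / f"{cond.label}_gstar.csv"
        write_csv(pd.DataFrame(rows), out)
        written.append(out.name)
    for traj_path in cond.trajectories:
        series = strain_rates(read_trajectory_csv(traj_path))
        out = outdir / f"{cond.label}_{Path(traj_path).stem}_rates.csv"
        write_csv(series.to_frame(), out)
        written.append(out.name)
    if cond.images:
        rows = []
        for im in cond.images:
            mg = read_micrograph(im["path"], pixel_size=im["pixel_size"])
            metrics = compute_pna(mg)
            rows.append({"condition": cond.label, "image": Path(im["path"]).stem, **vars(metrics)})
        out = outdir / f"{cond.label}_pna.csv"
        write_csv(pd.DataFrame(rows), out)
        written.append(out.name)
    return written


def run_pipeline(manifest: RunManifest, outdir: Path | str) -> dict[str, list[str]]:
    """Process every condition in the manifest into ``outdir``.

    Per-condition failures are isolated (logged, other conditions still
    run); an exception propagates only if every condition fails.
    Returns {condition label: [output file names]}.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: dict[str, list[str]] = {}
    failures: dict[str, str] = {}
    try:
        log.info("doughrheo %s, config hash %s", __version__, _config_hash(manifest))
        for cond in manifest.conditions:
            try:
                results[cond.label] = _run_condition(cond, outdir)
                log.info("condition %s: wrote %s", cond.label, results[cond.label])
            except Exception as exc:  # noqa: BLE001 - isolate per condition
                failures[cond.label] = str(exc)
                log.error("condition %s failed: %s", cond.label, exc)
        if failures and not results:
            raise RuntimeError(f"all conditions failed: {failures}")
    finally:
        log.removeHandler(handler)
        handler.close()
    return results
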