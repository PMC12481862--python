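"""End-to-end runs: simulate -> trace -> NSL -> volumetry -> compare.

Each stage is a thin orchestration over the library modules, driven by a
cohort manifest and a flat key:value config.  One global seed expands
deterministically into per-phantom sub-seeds (SeedSequence), so reruns are
bit-identical and partial reruns reproducible.  Failures are per-unit (per
mouse / per phantom): a cohort run continues past a failed member and reports
it in the summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import InvalidArgumentError, OctMorphError
from .io import (
    OCTVolume,
    parse_index_list,
    parse_profile_map,
    read_manifest,
    read_profile,
    read_volume,
    write_results,
)
from .nsl import aggregate_mouse, compute_nsl
from .stats import compare_groups
from .synthetic import PhantomSpec, generate_phantom, save_phantom
from .tracing import TracerParams, select_bscans, trace_surface
from .volumetry import SegmentationParams, measure_objects, segment_objects

__all__ = [
    "RunConfig",
    "default_normal_spec",
    "default_tumor_spec",
    "run_simulate",
    "run_nsl",
    "run_volumes",
    "run_compare",
    "write_provenance",
]

log = logging.getLogger("octmorph")

MOUSE_COLUMNS = ("mouse_id", "group", "n_bscans", "mean_nsl")


@dataclass
class RunConfig:
    """Configuration of a pipeline run (flat key:value file on disk)."""

    manifest_path: str = ""
    output_dir: str = "."
    tracer: TracerParams = field(default_factory=TracerParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    n_equally_spaced: int = 5
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise InvalidArgumentError("alpha must lie in (0, 1)")
        if self.n_equally_spaced < 1:
            raise InvalidArgumentError("n_equally_spaced must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat config: top-level keys, plus tracer.* and segmentation.*."""
        kv = {}
        for ln, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise InvalidArgumentError(f"{path}: line {ln + 1} is not 'key: value'")
            k, v = (t.strip() for t in line.split(":", 1))
            kv[k] = v
        tracer_kw, seg_kw, top = {}, {}, {}
        for k, v in kv.items():
            if k.startswith("tracer."):
                tracer_kw[k[7:]] = v
            elif k.startswith("segmentation."):
                seg_kw[k[13:]] = v
            else:
                top[k] = v
        cfg = cls(
            manifest_path=top.get("manifest_path", ""),
            output_dir=top.get("output_dir", "."),
            tracer=_coerce_dataclass(TracerParams, tracer_kw),
            segmentation=_coerce_dataclass(SegmentationParams, seg_kw),
            n_equally_spaced=int(top.get("n_equally_spaced", 5)),
            alpha=float(top.get("alpha", 0.05)),
            seed=int(top.get("seed", 0)),
            log_level=top.get("log_level", "INFO"),
        )
        return cfg


def _coerce_dataclass(cls, kv: dict):
    kwargs = {}
    for k, v in kv.items():
        if k not in cls.__dataclass_fields__:
            raise InvalidArgumentError(f"unknown {cls.__name__} key {k!r}")
        typ = cls.__dataclass_fields__[k].type
        if typ in ("int", int):
            kwargs[k] = int(v)
        elif typ in ("float", float):
            kwargs[k] = float(v)
        elif typ in ("bool", bool):
            kwargs[k] = str(v).lower() in ("1", "true", "yes")
        else:
            kwargs[k] = v
    return cls(**kwargs)


def subseeds(seed: int, n: int) -> list[int]:
    """Expand a global seed into n reproducible sub-seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


# ---------------------------------------------------------------------------
# study-condition cohort specs (scaled-down grids; see docs/methods.md)
# ---------------------------------------------------------------------------

def default_normal_spec(seed: int) -> PhantomSpec:
    """Normal-ovary phantom: smooth polynomial surface, no outgrowths."""
    return PhantomSpec(
        lateral_extent_um=600.0,
        depth_extent_um=480.0,
        n_bscans=10,
        baseline_depth_um=210.0,
        baseline_curvature=(0.02, 3e-4, 0.0),
        roughness_amplitude_um=0.0,
        n_outgrowths=0,
        seed=seed,
    )


def default_tumor_spec(seed: int) -> PhantomSpec:
    """Tumor phantom: rough surface plus attached outgrowth bumps."""
    return PhantomSpec(
        lateral_extent_um=600.0,
        depth_extent_um=480.0,
        n_bscans=10,
        baseline_depth_um=210.0,
        baseline_curvature=(0.02, 3e-4, 0.0),
        roughness_amplitude_um=60.0,
        roughness_wavelength_um=100.0,
        n_outgrowths=4,
        outgrowth_radius_range_um=(40.0, 150.0),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(
    specs: Sequence[tuple[PhantomSpec, str]],
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Render phantoms and write a manifest ready for :func:`run_nsl`.

    ``specs`` is a list of (PhantomSpec, group_label).  When ``seed`` is
    given, each spec's own seed is replaced by a sub-seed derived from it.
    Per-phantom placement failures are recorded and the run continues.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not out_dir.is_dir():
        raise InvalidArgumentError(f"output_dir {out_dir} is not writable")
    seeds = subseeds(seed, len(specs)) if seed is not None else None
    rows, failures = [], []
    from dataclasses import replace

    for i, (spec, group) in enumerate(specs):
        if seeds is not None:
            spec = replace(spec, seed=seeds[i])
        stem = f"phantom_{i:03d}"
        try:
            volume, truth = generate_phantom(spec)
        except OctMorphError as exc:
            log.error("phantom %s failed: %s", stem, exc)
            failures.append({"stem": stem, "error": str(exc)})
            continue
        save_phantom(volume, truth, out_dir, stem)
        rows.append(
            {
                "volume_path": f"{stem}.tiff",
                "mouse_id": stem,
                "group": group,
                "selected_bscans": "",
                "profile_paths": "",
                "voxel_size_um": ";".join(f"{v:g}" for v in spec.voxel_size_um),
            }
        )
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return {"manifest": manifest_path, "n_ok": len(rows), "failures": failures}


def _voxel_size_from_row(row) -> tuple[float, float, float]:
    text = str(row.get("voxel_size_um", "") or "")
    if text.strip():
        parts = [float(t) for t in text.split(";")]
        if len(parts) != 3:
            raise InvalidArgumentError(f"bad voxel_size_um {text!r} in manifest")
        return tuple(parts)  # type: ignore[return-value]
    return (3.0, 3.0, 3.0)


def run_nsl(config: RunConfig) -> dict:
    """Trace (or import) profiles, compute NSL, write per-B-scan + per-mouse tables.

    Entries without ``selected_bscans`` get the equally-spaced protocol
    (``config.n_equally_spaced`` B-scans); explicit index lists are honored.
    Manual profiles take precedence over auto-tracing for their B-scans.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(config.manifest_path)
    bscan_records, mouse_rows, skipped = [], [], []
    for _, row in manifest.iterrows():
        mouse_id, group = row["mouse_id"], row["group"]
        try:
            voxel = _voxel_size_from_row(row)
            volume = read_volume(row["volume_path"], voxel)
            explicit = parse_index_list(str(row.get("selected_bscans", "")))
            if explicit:
                indices = select_bscans(volume, "explicit", explicit)
            else:
                indices = select_bscans(
                    volume, "equally_spaced", config.n_equally_spaced
                )
            manual = parse_profile_map(str(row.get("profile_paths", "")))
            results = []
            for idx in indices:
                if idx in manual:
                    profile = read_profile(
                        manual[idx], "csv", (voxel[2], voxel[1]), bscan_index=idx
                    )
                else:
                    profile = trace_surface(
                        volume.bscan(idx), (voxel[1], voxel[2]),
                        config.tracer, bscan_index=idx,
                    )
                results.append(compute_nsl(profile))
            mouse = aggregate_mouse(results, mouse_id, group)
        except OctMorphError as exc:
            log.error("mouse %s skipped: %s", mouse_id, exc)
            skipped.append({"mouse_id": mouse_id, "error": str(exc)})
            continue
        for r in mouse.per_bscan:
            bscan_records.append(
                {
                    "mouse_id": mouse_id,
                    "group": group,
                    "bscan_index": r.bscan_index,
                    "source": r.source,
                    "n_points": r.n_points,
                    "Ls_um": r.Ls_um,
                    "Lp_um": r.Lp_um,
                    "nsl": r.nsl,
                }
            )
        mouse_rows.append(
            {
                "mouse_id": mouse_id,
                "group": group,
                "n_bscans": len(mouse.per_bscan),
                "mean_nsl": mouse.mean_nsl,
            }
        )
        log.info("mouse %s (%s): mean NSL %.4f over %d B-scans",
                 mouse_id, group, mouse.mean_nsl, len(mouse.per_bscan))
    if not mouse_rows:
        raise OctMorphError("all mice failed NSL processing")
    bscan_path = out_dir / "nsl_per_bscan.csv"
    mouse_path = out_dir / "nsl_per_mouse.csv"
    write_results(bscan_records, bscan_path, kind="nsl")
    pd.DataFrame(mouse_rows, columns=list(MOUSE_COLUMNS)).to_csv(
        mouse_path, index=False, float_format="%.12g"
    )
    return {
        "per_bscan": bscan_path,
        "per_mouse": mouse_path,
        "skipped": skipped,
        "mouse_table": pd.DataFrame(mouse_rows, columns=list(MOUSE_COLUMNS)),
    }


def run_volumes(
    volume: OCTVolume,
    params: SegmentationParams,
    out_path: str | Path | None = None,
    class_tag: str = "",
) -> list:
    """Segment + measure one volume; optionally write the object table."""
    labels = segment_objects(volume, params)
    measurements = measure_objects(labels, volume.voxel_size_um, class_tag)
    if out_path is not None:
        write_results([m.as_record() for m in measurements], out_path, kind="objects")
    return measurements


def run_compare(
    mouse_table: pd.DataFrame | str | Path,
    pair: tuple[str, str],
    alpha: float = 0.05,
    value_column: str = "mean_nsl",
    out_path: str | Path | None = None,
):
    """Compare two groups of per-mouse values from a result table."""
    if not isinstance(mouse_table, pd.DataFrame):
        mouse_table = pd.read_csv(mouse_table)
    if value_column not in mouse_table.columns:
        raise InvalidArgumentError(f"table has no column {value_column!r}")
    values = {
        g: sub[value_column].to_numpy(dtype=float)
        for g, sub in mouse_table.groupby("group")
    }
    comparison = compare_groups(values, pair, alpha=alpha)
    log.info(
        "%s (n=%d) vs %s (n=%d): W=%g, p=%.4g%s",
        comparison.group_a, comparison.n_a, comparison.group_b, comparison.n_b,
        comparison.statistic, comparison.p_value,
        " *" if comparison.significant else "",
    )
    if out_path is not None:
        pd.DataFrame([comparison.as_record()]).to_csv(
            out_path, index=False, float_format="%.12g"
        )
    return comparison


def write_provenance(out_dir: str | Path, config: RunConfig, extra: dict | None = None):
    """Machine-readable record sufficient to reproduce a deterministic run."""
    payload = {
        "package": "octmorph",
        "version": __version__,
        "numpy": np.__version__,
        "config": {
            **{k: v for k, v in asdict(config).items() if k not in ("tracer", "segmentation")},
            "tracer": asdict(config.tracer),
            "segmentation": asdict(config.segmentation),
        },
    }
    if extra:
        payload.update(extra)
    path = Path(out_dir) / "provenance.json"
    path.write_text(json.dumps(payload, indent=2, default=str), encoding="utf-8")
    return path
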