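"""Reading and writing of volumes, surface profiles, manifests and result tables.

Volumes travel as grayscale multi-page TIFF stacks (one page per B-scan);
surface profiles as "x,y" CSV in pixel units (the Fiji-style manual
delineation interchange) or as ImageJ ``.roi`` polylines; cohort manifests and
result tables as RFC-4180 CSV with a header row.  Physical voxel sizes are the
caller's responsibility (manifest/CLI config); TIFF resolution tags are
honored only as a consistency check — on conflict the configured value wins
with a warning, because scale metadata in exported OCT stacks is unreliable.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, InsufficientProfileError, InvalidArgumentError
from .tracing import SurfaceProfile

__all__ = [
    "OCTVolume",
    "read_volume",
    "write_volume",
    "read_profile",
    "write_profile",
    "read_manifest",
    "write_results",
    "read_results",
    "NSL_COLUMNS",
    "OBJECT_COLUMNS",
]


@dataclass
class OCTVolume:
    """A 3D OCT intensity volume with physical voxel sizes.

    Axes are (b_scan, depth, lateral); depth increases downward, matching the
    usual B-scan display with the tissue surface near the top.  ``voxel_size_um``
    is ordered the same way: (B-scan spacing, axial pixel, lateral pixel).
    """

    intensity: np.ndarray
    voxel_size_um: tuple[float, float, float]
    source_id: str = ""

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3 or min(self.intensity.shape) < 1:
            raise InvalidArgumentError(
                f"intensity must be a 3D array, got shape {self.intensity.shape}"
            )
        vs = tuple(float(v) for v in self.voxel_size_um)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise InvalidArgumentError(f"voxel sizes must be 3 positive lengths, got {vs}")
        self.voxel_size_um = vs
        if not np.isfinite(self.intensity).all():
            raise InvalidArgumentError("intensity contains non-finite values")
        if self.intensity.min() < 0:
            raise InvalidArgumentError("intensity must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    @property
    def n_bscans(self) -> int:
        return self.intensity.shape[0]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    def bscan(self, index: int) -> np.ndarray:
        """Return one B-scan as a (depth, lateral) view."""
        return self.intensity[index]


def read_volume(
    path: str | Path,
    voxel_size_um: tuple[float, float, float],
    source_id: str | None = None,
) -> OCTVolume:
    """Read a single- or multi-page grayscale TIFF as an :class:`OCTVolume`.

    A single-page file yields a 1-B-scan volume.  RGB or otherwise
    multi-sample pages are rejected with a :class:`FormatError` naming the
    offending page.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            for i, page in enumerate(tif.pages):
                if page.samplesperpixel != 1:
                    raise FormatError(
                        f"{path}: page {i} has {page.samplesperpixel} samples per "
                        "pixel; grayscale volumes required"
                    )
            data = tif.asarray()
            _check_resolution_tags(tif, voxel_size_um, path)
    except FormatError:
        raise
    except Exception as exc:  # truncated/unreadable file
        raise FormatError(f"{path}: not a readable TIFF volume ({exc})") from exc
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 2D pages, got array of shape {data.shape}")
    return OCTVolume(data, voxel_size_um, source_id or str(path))


def _check_resolution_tags(tif, voxel_size_um, path) -> None:
    # Best effort: compare ImageJ 'spacing' (B-scan axis) if present.
    try:
        meta = tif.imagej_metadata
        if meta and "spacing" in meta and meta.get("unit") in ("um", "micron", "µm"):
            spacing = float(meta["spacing"])
            if spacing > 0 and abs(spacing - voxel_size_um[0]) > 0.01 * voxel_size_um[0]:
                warnings.warn(
                    f"{path}: TIFF metadata spacing {spacing} um conflicts with "
                    f"configured B-scan spacing {voxel_size_um[0]} um; using the "
                    "configured value",
                    stacklevel=3,
                )
    except Exception:
        pass


def write_volume(volume: OCTVolume, path: str | Path) -> None:
    """Write a volume as a multi-page grayscale TIFF (dtype preserved)."""
    path = Path(path)
    try:
        tifffile.imwrite(path, volume.intensity, photometric="minisblack")
    except OSError as exc:
        raise OSError(f"cannot write volume to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# surface profiles
# ---------------------------------------------------------------------------

def read_profile(
    path: str | Path,
    dialect: str = "csv",
    pixel_size_um: float | tuple[float, float] = 1.0,
    bscan_index: int = 0,
) -> SurfaceProfile:
    """Import a manually delineated surface profile.

    Parameters
    ----------
    dialect:
        ``"csv"`` — two-column x,y text (header optional), pixel units;
        ``"imagej_roi"`` — an ImageJ ``.roi`` polyline/polygon file.
    pixel_size_um:
        Scalar or (lateral, axial) pair used to convert pixels to um.

    Points are sorted by ascending x; duplicate x positions are collapsed by
    averaging y.  Fewer than 4 distinct x positions raise
    :class:`InsufficientProfileError` (a cubic baseline is then infeasible).
    """
    path = Path(path)
    if dialect == "csv":
        xy = _read_profile_csv(path)
    elif dialect == "imagej_roi":
        xy = _read_imagej_roi(path)
    else:
        raise InvalidArgumentError(f"unknown profile dialect {dialect!r}")
    if np.isscalar(pixel_size_um):
        sx = sy = float(pixel_size_um)
    else:
        sx, sy = (float(v) for v in pixel_size_um)
    if sx <= 0 or sy <= 0:
        raise InvalidArgumentError("pixel sizes must be positive")
    x = xy[:, 0] * sx
    y = xy[:, 1] * sy
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    ux, inverse = np.unique(x, return_inverse=True)
    if ux.size < 4:
        raise InsufficientProfileError(
            f"{path}: {ux.size} distinct x positions; at least 4 required"
        )
    uy = np.bincount(inverse, weights=y) / np.bincount(inverse)
    return SurfaceProfile(
        points=np.column_stack([ux, uy]), source="manual", bscan_index=bscan_index
    )


def _read_profile_csv(path: Path) -> np.ndarray:
    try:
        raw = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise FormatError(f"{path}: unreadable ({exc})") from exc
    rows = []
    for ln, line in enumerate(raw.splitlines()):
        line = line.strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) < 2:
            raise FormatError(f"{path}: line {ln + 1} has fewer than 2 columns")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            if ln == 0:  # header row
                continue
            raise FormatError(f"{path}: line {ln + 1} is not numeric") from None
    if not rows:
        raise FormatError(f"{path}: no coordinate rows")
    return np.asarray(rows, dtype=float)


# ImageJ ROI type codes (RoiDecoder.java)
_ROI_POLYGON, _ROI_FREELINE, _ROI_POLYLINE, _ROI_FREEHAND = 0, 4, 5, 7
_ROI_LINE_TYPES = {_ROI_POLYGON, _ROI_FREELINE, _ROI_POLYLINE, _ROI_FREEHAND}


def _read_imagej_roi(path: Path) -> np.ndarray:
    """Minimal ImageJ .roi decoder for polyline-style ROIs.

    Handles the classic int16 coordinate layout: "Iout" magic, ROI type at
    byte 6, bounds at bytes 8..15, N at 16..17, coordinates from byte 64 as N
    x-offsets then N y-offsets relative to (left, top).
    """
    data = path.read_bytes()
    if len(data) < 64 + 4 or data[:4] != b"Iout":
        raise FormatError(f"{path}: not an ImageJ ROI file")
    roi_type = data[6]
    if roi_type not in _ROI_LINE_TYPES:
        raise FormatError(
            f"{path}: ROI type {roi_type} is not a polyline/polygon/freeline"
        )
    top, left, _bottom, _right = struct.unpack(">4h", data[8:16])
    n = struct.unpack(">H", data[16:18])[0]
    need = 64 + 4 * n
    if len(data) < need:
        raise FormatError(f"{path}: truncated coordinate block ({n} points)")
    xs = np.frombuffer(data, dtype=">i2", count=n, offset=64).astype(float) + left
    ys = np.frombuffer(data, dtype=">i2", count=n, offset=64 + 2 * n).astype(float) + top
    return np.column_stack([xs, ys])


def write_profile(
    profile: SurfaceProfile,
    path: str | Path,
    pixel_size_um: float | tuple[float, float] = 1.0,
) -> None:
    """Export a profile to the CSV dialect (coordinates back in pixel units)."""
    if np.isscalar(pixel_size_um):
        sx = sy = float(pixel_size_um)
    else:
        sx, sy = (float(v) for v in pixel_size_um)
    df = pd.DataFrame({"x": profile.x / sx, "y": profile.y / sy})
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# cohort manifests
# ---------------------------------------------------------------------------

_MANIFEST_REQUIRED = ("volume_path", "mouse_id", "group")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV.

    Required columns: volume_path, mouse_id, group.  Optional:
    ``selected_bscans`` — semicolon-separated 0-based indices;
    ``profile_paths`` — semicolon-separated ``index=path`` pairs of manual
    profiles.  Relative paths are resolved against the manifest directory.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable manifest ({exc})") from exc
    missing = [c for c in _MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    if len(df) == 0:
        raise FormatError(f"{path}: manifest has no rows")
    for col in ("mouse_id", "group"):
        if (df[col].str.strip() == "").any():
            raise FormatError(f"{path}: empty {col} in manifest")
    base = path.parent
    df["volume_path"] = [str((base / p).resolve()) if not Path(p).is_absolute() else p
                         for p in df["volume_path"]]
    if "profile_paths" in df.columns:
        df["profile_paths"] = [
            _resolve_profile_paths(v, base) for v in df["profile_paths"]
        ]
    return df


def parse_index_list(text: str) -> list[int]:
    """Parse '1;3;5' into [1, 3, 5] (empty string -> empty list)."""
    text = (text or "").strip()
    if not text:
        return []
    try:
        return [int(t) for t in text.split(";") if t.strip() != ""]
    except ValueError as exc:
        raise InvalidArgumentError(f"bad B-scan index list {text!r}") from exc


def parse_profile_map(text: str) -> dict[int, str]:
    """Parse '0=a.csv;2=b.csv' into {0: 'a.csv', 2: 'b.csv'}."""
    out: dict[int, str] = {}
    for item in (text or "").split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise InvalidArgumentError(f"bad profile map entry {item!r}")
        k, v = item.split("=", 1)
        out[int(k)] = v.strip()
    return out


def _resolve_profile_paths(text: str, base: Path) -> str:
    mapping = parse_profile_map(text)
    resolved = {
        k: str((base / v).resolve()) if not Path(v).is_absolute() else v
        for k, v in mapping.items()
    }
    return ";".join(f"{k}={v}" for k, v in sorted(resolved.items()))


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

NSL_COLUMNS = (
    "mouse_id", "group", "bscan_index", "source", "n_points",
    "Ls_um", "Lp_um", "nsl",
)
OBJECT_COLUMNS = (
    "object_id", "class", "voxel_count", "volume_um3",
    "centroid_bscan_um", "centroid_depth_um", "centroid_lateral_um",
)


def _infer_kind(record: Mapping) -> str:
    keys = set(record)
    if "nsl" in keys:
        return "nsl"
    if "voxel_count" in keys:
        return "objects"
    raise InvalidArgumentError(f"cannot infer record kind from keys {sorted(keys)}")


def write_results(
    records: Sequence[Mapping],
    path: str | Path,
    kind: str | None = None,
) -> None:
    """Write per-B-scan NSL or object-measurement records to CSV.

    Column order is stable (:data:`NSL_COLUMNS` / :data:`OBJECT_COLUMNS`) and
    floats are written at 12 significant digits so a read-back reproduces the
    values to ~1e-9 relative.  Mixing NSL and object records in one call is an
    error; an empty record list yields a header-only file of the given
    ``kind`` (default "nsl").
    """
    if kind is not None and kind not in ("nsl", "objects"):
        raise InvalidArgumentError(f"unknown result kind {kind!r}")
    kinds = {_infer_kind(r) for r in records}
    if len(kinds) > 1:
        raise InvalidArgumentError(f"mixed record kinds in one table: {sorted(kinds)}")
    if kinds:
        inferred = kinds.pop()
        if kind is not None and kind != inferred:
            raise InvalidArgumentError(f"records are {inferred!r}, not {kind!r}")
        kind = inferred
    elif kind is None:
        kind = "nsl"
    columns = NSL_COLUMNS if kind == "nsl" else OBJECT_COLUMNS
    df = pd.DataFrame(list(records), columns=list(columns))
    extra = [c for r in records for c in r if c not in columns]
    for c in dict.fromkeys(extra):
        df[c] = [r.get(c) for r in records]
    try:
        df.to_csv(path, index=False, float_format="%.12g")
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a result table written by :func:`write_results`."""
    try:
        return pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable result table ({exc})") from exc
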