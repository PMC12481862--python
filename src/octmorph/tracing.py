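"""Tissue-surface extraction from B-scans and B-scan selection.

The air/tissue boundary in an OCT B-scan is the first depth at which the
backscatter intensity rises above a threshold and stays above it for a few
consecutive pixels (speckle spikes in the background are shorter than that
run).  The traced depth sequence is despiked with a median filter and
optionally smoothed laterally; the result is a single-valued profile y(x) in
physical micrometres, the input to the NSL computation.  Overhanging
structures are flattened to the shallowest crossing per column, since the
cubic-baseline fit presumes a function of x.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import (
    InsufficientProfileError,
    InvalidArgumentError,
    NoSurfaceFoundError,
)

__all__ = ["SurfaceProfile", "TracerParams", "trace_surface", "select_bscans"]

_PROFILE_SOURCES = ("manual", "auto", "synthetic")


@dataclass
class SurfaceProfile:
    """Ordered, single-valued surface polyline for one B-scan.

    ``points`` is an (N, 2) array of (x_um, y_um) with x strictly increasing;
    y is depth below the top of the B-scan (larger y = deeper).
    """

    points: np.ndarray
    source: str = "auto"
    bscan_index: int = 0

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
            raise InvalidArgumentError(
                f"profile needs an (N>=4, 2) point array, got shape {pts.shape}"
            )
        if not np.isfinite(pts).all():
            raise InvalidArgumentError("profile coordinates must be finite")
        if not (np.diff(pts[:, 0]) > 0).all():
            raise InvalidArgumentError("profile x must be strictly increasing")
        if self.source not in _PROFILE_SOURCES:
            raise InvalidArgumentError(
                f"source must be one of {_PROFILE_SOURCES}, got {self.source!r}"
            )
        self.points = pts

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class TracerParams:
    """Parameters of the first-crossing surface tracer.

    threshold / threshold_kind:
        Intensity level; "absolute" uses the value as-is, "percentile"
        resolves it per B-scan (tracing is then invariant to global intensity
        scaling).
    min_run_px:
        Crossings must stay above threshold for this many consecutive axial
        pixels; rejects isolated speckle spikes in the background.
    max_gap_px:
        Lateral runs of columns without a crossing are linearly interpolated
        up to this width; wider gaps (and gaps at the edges) are excluded.
    median_window_px:
        Odd width of the lateral median despike filter.
    subpixel:
        Refine the crossing depth by linear interpolation of intensity
        between the pixel below and above threshold.
    smooth_lateral_um:
        Gaussian sigma of a lateral smoothing pass over the depth profile;
        suppresses per-column speckle jitter that would otherwise inflate the
        polyline length of a smooth surface.  0 disables it.
    """

    threshold: float = 45.0
    threshold_kind: str = "absolute"
    median_window_px: int = 5
    max_gap_px: int = 10
    min_run_px: int = 3
    subpixel: bool = True
    smooth_lateral_um: float = 12.0

    def __post_init__(self):
        if self.threshold_kind not in ("absolute", "percentile"):
            raise InvalidArgumentError(
                f"threshold_kind must be absolute|percentile, got {self.threshold_kind!r}"
            )
        if self.threshold_kind == "percentile" and not 0 <= self.threshold <= 100:
            raise InvalidArgumentError("percentile threshold must lie in [0, 100]")
        if self.median_window_px < 1 or self.median_window_px % 2 == 0:
            raise InvalidArgumentError("median_window_px must be an odd integer >= 1")
        if self.max_gap_px < 0 or self.min_run_px < 1:
            raise InvalidArgumentError("max_gap_px >= 0 and min_run_px >= 1 required")
        if self.smooth_lateral_um < 0:
            raise InvalidArgumentError("smooth_lateral_um must be >= 0")


def trace_surface(
    bscan: np.ndarray,
    pixel_size_um: tuple[float, float],
    params: TracerParams | None = None,
    bscan_index: int = 0,
) -> SurfaceProfile:
    """Trace the air/tissue surface of one B-scan.

    Parameters
    ----------
    bscan:
        (depth, lateral) intensity image.
    pixel_size_um:
        (axial, lateral) pixel sizes in micrometres.

    Returns a :class:`SurfaceProfile` in micrometres, or raises
    :class:`NoSurfaceFoundError` (no column crosses the threshold) /
    :class:`InsufficientProfileError` (fewer than 4 columns survive).
    """
    params = params or TracerParams()
    img = np.asarray(bscan, dtype=float)
    if img.ndim != 2:
        raise InvalidArgumentError(f"B-scan must be 2D, got shape {img.shape}")
    depth_px, n_cols = img.shape
    if n_cols < 4:
        raise InvalidArgumentError("B-scan needs at least 4 lateral columns")
    axial_um, lateral_um = (float(v) for v in pixel_size_um)
    if axial_um <= 0 or lateral_um <= 0:
        raise InvalidArgumentError("pixel sizes must be positive")

    if params.threshold_kind == "percentile":
        if img.max() == img.min():
            raise InvalidArgumentError(
                "percentile threshold unresolvable: B-scan intensities are degenerate"
            )
        thr = float(np.percentile(img, params.threshold))
    else:
        thr = float(params.threshold)

    run = min(params.min_run_px, depth_px)
    above = img >= thr
    ok = above[: depth_px - run + 1].copy()
    for k in range(1, run):
        ok &= above[k : depth_px - run + 1 + k]
    valid = ok.any(axis=0)
    if not valid.any():
        raise NoSurfaceFoundError("no lateral column has a valid threshold crossing")
    idx = np.argmax(ok, axis=0).astype(float)

    if params.subpixel:
        cols = np.nonzero(valid & (np.argmax(ok, axis=0) > 0))[0]
        i = np.argmax(ok, axis=0)[cols]
        below = img[i - 1, cols]
        at = img[i, cols]
        denom = at - below
        safe = (below < thr) & (denom > 0)
        frac = np.ones_like(below)
        frac[safe] = np.clip((thr - below[safe]) / denom[safe], 0.0, 1.0)
        idx[cols] = i - 1 + frac

    depth = np.where(valid, idx, np.nan)
    depth, valid = _fill_gaps(depth, valid, params.max_gap_px)

    # despike + smooth each contiguous valid segment independently
    sigma_cols = params.smooth_lateral_um / lateral_um
    for start, stop in _runs(valid):
        seg = depth[start:stop]
        if params.median_window_px > 1 and seg.size > 1:
            seg = ndimage.median_filter(
                seg, size=min(params.median_window_px, seg.size), mode="nearest"
            )
        if sigma_cols > 0 and seg.size > 1:
            seg = ndimage.gaussian_filter1d(seg, sigma_cols, mode="nearest")
        depth[start:stop] = seg

    cols = np.nonzero(valid)[0]
    if cols.size < 4:
        raise InsufficientProfileError(
            f"only {cols.size} columns with a traceable surface; >= 4 required"
        )
    pts = np.column_stack([cols * lateral_um, depth[cols] * axial_um])
    return SurfaceProfile(points=pts, source="auto", bscan_index=bscan_index)


def _fill_gaps(depth: np.ndarray, valid: np.ndarray, max_gap: int):
    """Linearly interpolate interior invalid runs no wider than max_gap."""
    valid = valid.copy()
    n = depth.size
    for start, stop in _runs(~valid):
        interior = start > 0 and stop < n
        if interior and (stop - start) <= max_gap:
            x = np.arange(start, stop)
            depth[start:stop] = np.interp(
                x, [start - 1, stop], [depth[start - 1], depth[stop]]
            )
            valid[start:stop] = True
    return depth, valid


def _runs(mask: np.ndarray) -> Iterable[tuple[int, int]]:
    """Yield (start, stop) of each maximal True run in a boolean array."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return
    edges = np.flatnonzero(np.diff(m.astype(np.int8)))
    bounds = [0, *(edges + 1), m.size]
    for a, b in zip(bounds[:-1], bounds[1:]):
        if m[a]:
            yield a, b


def select_bscans(
    volume_or_count,
    mode: str = "equally_spaced",
    n_or_indices: int | Sequence[int] = 5,
) -> list[int]:
    """Choose which B-scans enter the NSL protocol.

    ``equally_spaced`` partitions the B-scan axis into n equal intervals and
    returns each interval's center index, floor((k+0.5)*N/n) — the protocol
    used for normal ovaries (n defaults to 5).  ``explicit`` sorts and
    deduplicates a user list — the outgrowth-containing B-scans of tumor
    volumes, chosen by inspection.
    """
    n_total = (
        int(volume_or_count)
        if np.isscalar(volume_or_count)
        else volume_or_count.n_bscans
    )
    if n_total < 1:
        raise InvalidArgumentError("volume has no B-scans")
    if mode == "equally_spaced":
        n = int(n_or_indices)
        if n < 1 or n > n_total:
            raise InvalidArgumentError(
                f"equally_spaced requires 1 <= n <= {n_total}, got {n}"
            )
        return [int((k + 0.5) * n_total // n) for k in range(n)]
    if mode == "explicit":
        indices = sorted({int(i) for i in n_or_indices})
        if not indices:
            raise InvalidArgumentError("explicit selection is empty")
        if indices[0] < 0 or indices[-1] >= n_total:
            raise InvalidArgumentError(
                f"B-scan indices {indices} out of range [0, {n_total})"
            )
        return indices
    raise InvalidArgumentError(f"unknown selection mode {mode!r}")
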