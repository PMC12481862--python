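"""3D segmentation and volume measurement of detached outgrowths and chambers.

Mirrors the two measurement routes used on the in vivo volumes: (1) surface
rendering with an absolute intensity threshold after smoothing at a 5-um
level, here realized as Gaussian smoothing (sigma = 5 um) + thresholding +
connected components, with volume = voxel count x voxel volume; and (2) a
manual per-B-scan region-of-interest route, volume = sum of polygon areas x
B-scan spacing.  Bright polarity segments tissue-intensity objects (detached
outgrowths); dark polarity segments hypointense chambers, restricted to a
tissue mask because chambers are defined inside the tumor tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .errors import InvalidArgumentError
from .io import OCTVolume

__all__ = [
    "SegmentationParams",
    "ObjectMeasurement",
    "smooth_volume",
    "segment_objects",
    "measure_objects",
    "measure_roi_volume",
    "compartment_mask",
]

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}  # neighbor count -> skimage rank


@dataclass
class SegmentationParams:
    """Threshold segmentation parameters.

    ``smoothness_um`` is the Gaussian sigma applied before thresholding (the
    transparent analog of the commercial surface-smoothing level; default
    5 um).  ``polarity`` "bright" keeps intensity >= threshold (detached
    outgrowths), "dark" keeps intensity <= threshold inside a tissue mask
    (fluid-filled chambers).
    """

    threshold: float = 50.0
    smoothness_um: float = 5.0
    polarity: str = "bright"
    min_volume_um3: float = 0.0
    connectivity: int = 26

    def __post_init__(self):
        if self.smoothness_um < 0 or self.min_volume_um3 < 0:
            raise InvalidArgumentError("smoothness_um and min_volume_um3 must be >= 0")
        if self.polarity not in ("bright", "dark"):
            raise InvalidArgumentError(f"polarity must be bright|dark, got {self.polarity!r}")
        if self.connectivity not in _CONNECTIVITY:
            raise InvalidArgumentError("connectivity must be one of 6, 18, 26")


@dataclass
class ObjectMeasurement:
    """One segmented 3D object."""

    object_id: int
    voxel_count: int
    volume_um3: float
    centroid_um: tuple[float, float, float]  # (bscan, depth, lateral)
    bbox: tuple[int, int, int, int, int, int]  # (z0, y0, x0, z1, y1, x1)
    class_tag: str = ""

    def as_record(self) -> dict:
        return {
            "object_id": self.object_id,
            "class": self.class_tag,
            "voxel_count": self.voxel_count,
            "volume_um3": self.volume_um3,
            "centroid_bscan_um": self.centroid_um[0],
            "centroid_depth_um": self.centroid_um[1],
            "centroid_lateral_um": self.centroid_um[2],
        }


def compartment_mask(
    surface_depth_um: np.ndarray,
    shape: tuple[int, int, int],
    voxel_size_um: tuple[float, float, float],
    side: str = "above",
    margin_um: float = 0.0,
) -> np.ndarray:
    """Boolean mask of the region above or below a tissue-surface depth map.

    ``surface_depth_um`` is a (b_scan, lateral) map of surface depth; the mask
    selects voxels whose centers lie above (shallower than) or below the
    surface, offset by ``margin_um`` away from it.  Used to restrict bright
    segmentation to the background compartment (detached outgrowths) or dark
    segmentation to the tissue (chambers) when the surface is known.
    """
    if side not in ("above", "below"):
        raise InvalidArgumentError(f"side must be above|below, got {side!r}")
    nz, ny, nx = shape
    if surface_depth_um.shape != (nz, nx):
        raise InvalidArgumentError(
            f"surface map shape {surface_depth_um.shape} does not match volume "
            f"(b_scan, lateral) = {(nz, nx)}"
        )
    depth = (np.arange(ny) * voxel_size_um[1])[np.newaxis, :, np.newaxis]
    surf = surface_depth_um[:, np.newaxis, :]
    if side == "above":
        return depth < surf - margin_um
    return depth > surf + margin_um


def smooth_volume(volume: OCTVolume, smoothness_um: float) -> OCTVolume:
    """Gaussian-smooth a volume with a physical sigma per axis.

    sigma in voxels = smoothness_um / voxel size for each axis; reflective
    borders, so the total intensity of interior structures is conserved.
    ``smoothness_um`` = 0 returns an identical copy.
    """
    if smoothness_um < 0:
        raise InvalidArgumentError("smoothness_um must be >= 0")
    if smoothness_um == 0:
        return OCTVolume(volume.intensity.copy(), volume.voxel_size_um, volume.source_id)
    sigma = [smoothness_um / v for v in volume.voxel_size_um]
    smoothed = ndimage.gaussian_filter(
        volume.intensity.astype(float), sigma=sigma, mode="reflect"
    )
    return OCTVolume(np.clip(smoothed, 0, None), volume.voxel_size_um, volume.source_id)


def segment_objects(
    volume: OCTVolume,
    params: SegmentationParams | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Threshold + connected-component segmentation.

    Smooths with ``params.smoothness_um``, thresholds (>= for bright, <= for
    dark), labels components under the requested connectivity, drops
    components smaller than ``min_volume_um3``, and returns an int32 label
    volume with labels ordered by descending voxel count (label 1 = largest).

    For dark polarity with no ``mask``, a tissue mask is derived from the
    smoothed volume itself (>= threshold, morphologically closed, holes
    filled) with a warning — chambers only exist inside tissue, and without
    the restriction the whole background would count.
    """
    params = params or SegmentationParams()
    smoothed = smooth_volume(volume, params.smoothness_um).intensity
    if params.polarity == "bright":
        binary = smoothed >= params.threshold
        if mask is not None:
            binary &= np.asarray(mask, dtype=bool)
    else:
        if mask is None:
            warnings.warn(
                "dark-polarity segmentation without a tissue mask: deriving the "
                "mask from the smoothed volume (chambers are defined inside tissue)",
                stacklevel=2,
            )
            tissue = smoothed >= params.threshold
            tissue = ndimage.binary_closing(tissue, structure=np.ones((3, 3, 3)))
            mask = ndimage.binary_fill_holes(tissue)
        binary = (smoothed <= params.threshold) & np.asarray(mask, dtype=bool)
    labels = skmeasure.label(binary, connectivity=_CONNECTIVITY[params.connectivity])
    return _filter_and_order(labels, params, volume.voxel_volume_um3)


def _filter_and_order(labels: np.ndarray, params, voxel_volume: float) -> np.ndarray:
    counts = np.bincount(labels.ravel())
    if counts.size <= 1:
        return np.zeros(labels.shape, dtype=np.int32)
    counts[0] = 0
    keep = np.flatnonzero(counts * voxel_volume >= params.min_volume_um3)
    keep = keep[keep > 0]
    order = keep[np.argsort(-counts[keep], kind="stable")]
    remap = np.zeros(counts.size, dtype=np.int32)
    remap[order] = np.arange(1, order.size + 1, dtype=np.int32)
    return remap[labels]


def measure_objects(
    labels: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    class_tag: str = "",
) -> list[ObjectMeasurement]:
    """Voxel counts, physical volumes, centroids and bboxes per labeled object."""
    labels = np.asarray(labels)
    voxel_volume = float(np.prod(voxel_size_um))
    n = int(labels.max())
    if n == 0:
        return []
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    centroids = ndimage.center_of_mass(np.ones_like(labels), labels, range(1, n + 1))
    slices = ndimage.find_objects(labels)
    out = []
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        bbox = (sl[0].start, sl[1].start, sl[2].start, sl[0].stop, sl[1].stop, sl[2].stop)
        cz, cy, cx = centroids[lab - 1]
        out.append(
            ObjectMeasurement(
                object_id=lab,
                voxel_count=int(counts[lab]),
                volume_um3=float(counts[lab]) * voxel_volume,
                centroid_um=(
                    cz * voxel_size_um[0],
                    cy * voxel_size_um[1],
                    cx * voxel_size_um[2],
                ),
                bbox=bbox,
                class_tag=class_tag,
            )
        )
    return out


def measure_roi_volume(
    per_bscan_rois,
    voxel_size_um: tuple[float, float, float],
) -> float:
    """Manual-ROI volume: sum over B-scans of polygon area x B-scan spacing.

    ``per_bscan_rois`` is a sequence of (bscan_index, vertices) pairs, each
    vertices array an (N, 2) closed simple polygon in micrometres (the
    closing edge is implicit).  Polygon area uses the shoelace formula;
    self-intersecting polygons are rejected.
    """
    spacing = float(voxel_size_um[0])
    total = 0.0
    for bscan_index, verts in per_bscan_rois:
        verts = np.asarray(verts, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise InvalidArgumentError("each ROI needs an (N>=3, 2) vertex array")
        if int(bscan_index) < 0:
            raise InvalidArgumentError(f"negative B-scan index {bscan_index}")
        if _self_intersects(verts):
            raise InvalidArgumentError(
                f"ROI on B-scan {bscan_index} is self-intersecting"
            )
        x, y = verts[:, 0], verts[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        total += area * spacing
    return float(total)


def _self_intersects(verts: np.ndarray) -> bool:
    from shapely.geometry import Polygon

    return not Polygon(verts).is_valid
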