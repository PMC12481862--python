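"""OCT-like ovary/tumor phantom generator with analytic ground truth.

The phantom emulates the first-order statistics of intravital OCT B-scans of
the mouse ovary: a dark background above a speckle-textured tissue block whose
upper boundary is a smooth lateral trend (degree-<=3 polynomial) plus optional
stochastic roughness; attached tumor outgrowths are spherical caps merged into
that surface; detached outgrowths are tissue-intensity balls floating in the
background; fluid-filled chambers are hypointense balls strictly inside the
tissue.  Speckle is multiplicative, gamma-distributed with unit mean (shape =
``speckle_shape``), and depth attenuation is a single exponential.  Voxel
intensity at the tissue boundary follows partial-volume mixing, so sub-pixel
surface estimation is physically meaningful.

Everything is deterministic given the spec (including its seed): the ground
truth records the exact analytic surface and every object's center, radius and
analytic volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidArgumentError, PlacementError
from .io import OCTVolume, write_volume
from .tracing import SurfaceProfile

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "TruthObject",
    "generate_profile",
    "generate_phantom",
    "save_phantom",
    "load_ground_truth",
]


@dataclass
class PhantomSpec:
    """Phantom geometry, scene content, and intensity statistics.

    Lengths are micrometres.  Defaults reflect the imaging scales of the
    study this generator emulates: ~3 um transverse sampling (used for the
    axial sampling too, keeping voxels isotropic) and outgrowths of tens to
    hundreds of micrometres (the smallest resolvable ones are ~88 um across,
    hence the 40-150 um radius range).  Intensity statistics (speckle shape,
    attenuation) are free choices — no measured values exist for the original
    images — documented in the methods note.

    ``baseline_curvature`` holds (linear, quadratic, cubic) coefficients of
    the lateral surface trend about the lateral center.  Roughness is a
    Gaussian random field with RMS amplitude ``roughness_amplitude_um`` and
    correlation FWHM ``roughness_wavelength_um``.
    """

    lateral_extent_um: float = 900.0
    depth_extent_um: float = 600.0
    n_bscans: int = 10
    pixel_size_lateral_um: float = 3.0
    pixel_size_axial_um: float = 3.0
    baseline_depth_um: float = 180.0
    baseline_curvature: tuple[float, float, float] = (0.0, 2e-4, 0.0)
    roughness_amplitude_um: float = 0.0
    roughness_wavelength_um: float = 100.0
    n_outgrowths: int = 0
    outgrowth_radius_range_um: tuple[float, float] = (40.0, 150.0)
    n_detached: int = 0
    n_chambers: int = 0
    chamber_radius_range_um: tuple[float, float] = (20.0, 50.0)
    tissue_mean_intensity: float = 100.0
    background_mean_intensity: float = 5.0
    speckle_shape: float = 4.0
    attenuation_per_um: float = 0.004
    bursa: bool = False
    seed: int = 0
    # explicit radii override random sampling (exact ground-truth control)
    detached_radii_um: tuple[float, ...] | None = None
    chamber_radii_um: tuple[float, ...] | None = None

    def validate(self) -> None:
        pos = {
            "lateral_extent_um": self.lateral_extent_um,
            "depth_extent_um": self.depth_extent_um,
            "pixel_size_lateral_um": self.pixel_size_lateral_um,
            "pixel_size_axial_um": self.pixel_size_axial_um,
            "baseline_depth_um": self.baseline_depth_um,
            "roughness_wavelength_um": self.roughness_wavelength_um,
            "tissue_mean_intensity": self.tissue_mean_intensity,
        }
        for name, v in pos.items():
            if not v > 0:
                raise InvalidArgumentError(f"{name} must be > 0, got {v}")
        if self.n_bscans < 1:
            raise InvalidArgumentError("n_bscans must be >= 1")
        if self.roughness_amplitude_um < 0 or self.attenuation_per_um < 0:
            raise InvalidArgumentError("roughness amplitude and attenuation must be >= 0")
        if not 0 <= self.background_mean_intensity < self.tissue_mean_intensity:
            raise InvalidArgumentError(
                "need 0 <= background_mean_intensity < tissue_mean_intensity "
                "(the phantom must be traceable)"
            )
        if self.speckle_shape <= 0:
            raise InvalidArgumentError("speckle_shape must be > 0")
        for name, (lo, hi) in (
            ("outgrowth_radius_range_um", self.outgrowth_radius_range_um),
            ("chamber_radius_range_um", self.chamber_radius_range_um),
        ):
            if not (0 < lo <= hi):
                raise InvalidArgumentError(f"{name} must satisfy 0 < min <= max")
        for n in (self.n_outgrowths, self.n_detached, self.n_chambers):
            if n < 0:
                raise InvalidArgumentError("object counts must be >= 0")

    @property
    def voxel_size_um(self) -> tuple[float, float, float]:
        # (B-scan spacing, axial, lateral); B-scans sampled at the lateral pitch
        return (
            self.pixel_size_lateral_um,
            self.pixel_size_axial_um,
            self.pixel_size_lateral_um,
        )

    def grid_shape(self) -> tuple[int, int, int]:
        return (
            self.n_bscans,
            int(round(self.depth_extent_um / self.pixel_size_axial_um)),
            int(round(self.lateral_extent_um / self.pixel_size_lateral_um)),
        )

    # -- flat key:value config round trip ----------------------------------
    def to_config(self, path: str | Path) -> None:
        lines = []
        for k, v in asdict(self).items():
            if v is None:
                continue
            if isinstance(v, (tuple, list)):
                v = ",".join(repr(float(t)) for t in v)
            lines.append(f"{k}: {v}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_config(cls, path: str | Path) -> "PhantomSpec":
        kwargs = {}
        fields_ = cls.__dataclass_fields__
        for ln, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise InvalidArgumentError(f"{path}: line {ln + 1} is not 'key: value'")
            k, v = (t.strip() for t in line.split(":", 1))
            if k not in fields_:
                raise InvalidArgumentError(f"{path}: unknown PhantomSpec key {k!r}")
            kwargs[k] = _parse_config_value(k, v)
        spec = cls(**kwargs)
        spec.validate()
        return spec


def _parse_config_value(key: str, text: str):
    if key in ("n_bscans", "n_outgrowths", "n_detached", "n_chambers", "seed"):
        return int(text)
    if key == "bursa":
        return text.lower() in ("1", "true", "yes")
    if "," in text or key in (
        "baseline_curvature",
        "outgrowth_radius_range_um",
        "chamber_radius_range_um",
        "detached_radii_um",
        "chamber_radii_um",
    ):
        return tuple(float(t) for t in text.split(",") if t.strip())
    return float(text)


@dataclass
class TruthObject:
    """One ground-truth scene object (attached bump, detached ball, chamber)."""

    object_id: int
    object_class: str  # outgrowth | detached | chamber
    center_um: tuple[float, float, float]  # (bscan, depth, lateral)
    radius_um: float
    volume_um3: float  # NaN for attached outgrowths (partial caps)


@dataclass
class GroundTruth:
    """Exact analytic surface and object inventory of a phantom."""

    surface_depth_um: np.ndarray  # (n_bscans, n_lateral)
    objects: list[TruthObject]
    spec: PhantomSpec

    def objects_of(self, object_class: str) -> list[TruthObject]:
        return [o for o in self.objects if o.object_class == object_class]


# ---------------------------------------------------------------------------
# 1D profiles
# ---------------------------------------------------------------------------

def generate_profile(
    kind: str,
    params: dict | None = None,
    n_points: int = 200,
    extent_um: float = 1500.0,
    seed: int = 0,
    bscan_index: int = 0,
) -> SurfaceProfile:
    """Generate a synthetic 1D surface profile on a uniform lateral grid.

    kinds and their ``params``:

    - ``flat``: {level} — constant y.
    - ``polynomial``: {coefficients} — ascending-power degree-<=3 coefficients.
    - ``sinusoid``: {baseline, amplitude, wavelength} —
      y = baseline + A*sin(2*pi*x/wavelength).
    - ``bumpy``: {baseline, n_bumps, bump_amplitude, bump_width} — baseline
      plus seeded Gaussian bumps.
    """
    if n_points < 4:
        raise InvalidArgumentError("n_points must be >= 4")
    if extent_um <= 0:
        raise InvalidArgumentError("extent_um must be > 0")
    p = dict(params or {})
    x = np.linspace(0.0, float(extent_um), int(n_points))
    if kind == "flat":
        y = np.full_like(x, float(p.get("level", 500.0)))
    elif kind == "polynomial":
        coeffs = np.asarray(p.get("coefficients", (500.0, 0.0, 0.0, 0.0)), dtype=float)
        if coeffs.ndim != 1 or coeffs.size > 4:
            raise InvalidArgumentError("polynomial coefficients must be degree <= 3")
        y = np.polynomial.polynomial.polyval(x, coeffs)
    elif kind == "sinusoid":
        lam = float(p.get("wavelength", 200.0))
        if lam <= 0:
            raise InvalidArgumentError("sinusoid wavelength must be > 0")
        y = float(p.get("baseline", 500.0)) + float(p.get("amplitude", 30.0)) * np.sin(
            2.0 * np.pi * x / lam
        )
    elif kind == "bumpy":
        rng = np.random.default_rng(seed)
        y = np.full_like(x, float(p.get("baseline", 500.0)))
        width = float(p.get("bump_width", 40.0))
        amp = float(p.get("bump_amplitude", 30.0))
        for _ in range(int(p.get("n_bumps", 5))):
            cx = rng.uniform(0.0, extent_um)
            a = rng.uniform(0.5, 1.0) * amp
            y -= a * np.exp(-0.5 * ((x - cx) / width) ** 2)  # bumps rise (lower depth)
    else:
        raise InvalidArgumentError(f"unknown profile kind {kind!r}")
    return SurfaceProfile(
        points=np.column_stack([x, y]), source="synthetic", bscan_index=bscan_index
    )


# ---------------------------------------------------------------------------
# 3D phantoms
# ---------------------------------------------------------------------------

_PLACEMENT_TRIES = 500
_EDGE_MARGIN_UM = 6.0  # clearance between objects and compartment boundaries


def generate_phantom(spec: PhantomSpec) -> tuple[OCTVolume, GroundTruth]:
    """Render a phantom volume and its exact ground truth.

    Deterministic: identical spec (including seed) gives bit-identical
    output.  Raises :class:`PlacementError` naming the object class if a
    detached spheroid or chamber cannot be placed disjointly within its
    compartment after a bounded number of rejection-sampling attempts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.grid_shape()
    dz, dy, dx = spec.voxel_size_um
    x_um = np.arange(nx) * dx
    z_um = np.arange(nz) * dz
    y_um = np.arange(ny) * dy

    surface = _build_surface(spec, rng, x_um, z_um)
    objects: list[TruthObject] = []
    oid = 0
    for bump in _place_outgrowths(spec, rng, surface, x_um, z_um):
        cz, cd, cx, r = bump
        rho2 = (x_um[np.newaxis, :] - cx) ** 2 + (z_um[:, np.newaxis] - cz) ** 2
        cap = np.sqrt(np.clip(r**2 - rho2, 0.0, None))
        surface = np.minimum(surface, cd - cap + (rho2 >= r**2) * 1e9)
        objects.append(
            TruthObject(oid, "outgrowth", (cz, cd, cx), r, float("nan"))
        )
        oid += 1
    np.clip(surface, dy, spec.depth_extent_um - 4 * dy, out=surface)

    detached = _place_balls(
        spec, rng, surface, x_um, z_um, kind="detached",
        count=spec.n_detached, radii=spec.detached_radii_um,
        radius_range=spec.outgrowth_radius_range_um,
    )
    chambers = _place_balls(
        spec, rng, surface, x_um, z_um, kind="chamber",
        count=spec.n_chambers, radii=spec.chamber_radii_um,
        radius_range=spec.chamber_radius_range_um,
    )

    mean = _mean_intensity_field(spec, surface, y_um, x_um, z_um)
    for cz, cd, cx, r in detached:
        _paint_ball(mean, spec, (cz, cd, cx), r, spec.tissue_mean_intensity)
        objects.append(
            TruthObject(oid, "detached", (cz, cd, cx), r, 4.0 / 3.0 * math.pi * r**3)
        )
        oid += 1
    for cz, cd, cx, r in chambers:
        _paint_ball(mean, spec, (cz, cd, cx), r, spec.background_mean_intensity)
        objects.append(
            TruthObject(oid, "chamber", (cz, cd, cx), r, 4.0 / 3.0 * math.pi * r**3)
        )
        oid += 1

    speckle = rng.gamma(spec.speckle_shape, 1.0 / spec.speckle_shape, size=mean.shape)
    intensity = (mean * speckle).astype(np.float32)
    volume = OCTVolume(intensity, spec.voxel_size_um, source_id=f"phantom-seed{spec.seed}")
    return volume, GroundTruth(surface_depth_um=surface, objects=objects, spec=spec)


def _build_surface(spec, rng, x_um, z_um) -> np.ndarray:
    c1, c2, c3 = spec.baseline_curvature
    xc = x_um - x_um.mean()
    base = spec.baseline_depth_um + c1 * xc + c2 * xc**2 + c3 * xc**3
    surface = np.broadcast_to(base, (z_um.size, x_um.size)).astype(float).copy()
    if spec.roughness_amplitude_um > 0:
        field_ = rng.standard_normal((z_um.size, x_um.size))
        sigma_um = spec.roughness_wavelength_um / 2.355  # FWHM = wavelength
        sig = (sigma_um / spec.voxel_size_um[0], sigma_um / spec.voxel_size_um[2])
        field_ = ndimage.gaussian_filter(field_, sig, mode="wrap")
        sd = field_.std()
        if sd > 0:
            surface += field_ * (spec.roughness_amplitude_um / sd)
    return surface


def _place_outgrowths(spec, rng, surface, x_um, z_um):
    """Attached bumps: caps merged into the surface; may overlap each other."""
    bumps = []
    dy = spec.pixel_size_axial_um
    for _ in range(spec.n_outgrowths):
        lo, hi = spec.outgrowth_radius_range_um
        for _try in range(_PLACEMENT_TRIES):
            r = rng.uniform(lo, hi)
            cx = rng.uniform(x_um[0], x_um[-1])
            cz = rng.uniform(z_um[0], z_um[-1]) if z_um.size > 1 else z_um[0]
            iz = int(np.argmin(np.abs(z_um - cz)))
            ix = int(np.argmin(np.abs(x_um - cx)))
            cd = float(surface[iz, ix])
            if cd - r >= 2 * dy:  # cap apex stays inside the volume
                bumps.append((cz, cd, cx, r))
                break
        else:
            raise PlacementError("outgrowth")
    return bumps


def _place_balls(spec, rng, surface, x_um, z_um, kind, count, radii, radius_range):
    """Disjoint balls either above the surface (detached) or inside tissue."""
    if radii is not None:
        radii = tuple(float(r) for r in radii)
        count = len(radii)
    placed: list[tuple[float, float, float, float]] = []
    margin = _EDGE_MARGIN_UM
    for i in range(count):
        lo, hi = radius_range
        for _try in range(_PLACEMENT_TRIES):
            r = radii[i] if radii is not None else rng.uniform(lo, hi)
            cx = rng.uniform(x_um[0] + r, x_um[-1] - r) if x_um[-1] - x_um[0] > 2 * r else None
            cz = (
                rng.uniform(z_um[0] + r, z_um[-1] - r)
                if z_um[-1] - z_um[0] > 2 * r
                else None
            )
            if cx is None or cz is None:
                continue
            # local surface extremum over the ball footprint
            fx = (np.abs(x_um - cx) <= r)
            fz = (np.abs(z_um - cz) <= r)
            patch = surface[np.ix_(fz, fx)]
            if kind == "detached":
                ceiling = float(patch.min())
                cd_lo, cd_hi = r + margin, ceiling - r - margin
            else:  # chamber, strictly inside tissue
                floor_ = float(patch.max())
                cd_lo = floor_ + r + margin
                cd_hi = spec.depth_extent_um - r - margin
            if cd_hi <= cd_lo:
                continue
            cd = rng.uniform(cd_lo, cd_hi)
            if all(
                math.dist((cz, cd, cx), (pz, pd, px)) > r + pr + margin
                for pz, pd, px, pr in placed
            ):
                placed.append((cz, cd, cx, r))
                break
        else:
            raise PlacementError(kind)
    return placed


def _mean_intensity_field(spec, surface, y_um, x_um, z_um) -> np.ndarray:
    dy = spec.pixel_size_axial_um
    y = y_um[np.newaxis, :, np.newaxis]
    surf = surface[:, np.newaxis, :]
    coverage = np.clip((y - surf) / dy + 0.5, 0.0, 1.0)  # partial-volume edge
    below = np.clip(y - surf, 0.0, None)
    tissue = spec.tissue_mean_intensity * np.exp(-spec.attenuation_per_um * below)
    mean = spec.background_mean_intensity * (1.0 - coverage) + tissue * coverage
    if spec.bursa:
        # thin elevated-intensity sheet 30 um above the surface, 15 um thick
        sheet = (y >= surf - 45.0) & (y < surf - 30.0)
        mean[sheet] = np.maximum(mean[sheet], 1.2 * spec.tissue_mean_intensity)
    return mean


def _paint_ball(mean, spec, center_um, radius_um, intensity) -> None:
    cz, cd, cx = center_um
    dz, dy, dx = spec.voxel_size_um
    nz, ny, nx = mean.shape
    z = np.arange(nz) * dz
    y = np.arange(ny) * dy
    x = np.arange(nx) * dx
    dist = np.sqrt(
        (z[:, None, None] - cz) ** 2
        + (y[None, :, None] - cd) ** 2
        + (x[None, None, :] - cx) ** 2
    )
    cov = np.clip((radius_um - dist) / dy + 0.5, 0.0, 1.0)
    np.copyto(mean, mean * (1.0 - cov) + intensity * cov)


# ---------------------------------------------------------------------------
# on-disk form: TIFF volume + CSV sidecars
# ---------------------------------------------------------------------------

def save_phantom(
    volume: OCTVolume, truth: GroundTruth, out_dir: str | Path, stem: str
) -> dict[str, Path]:
    """Write volume (multi-page TIFF), object table and surface map (CSV).

    Object sidecar columns: id, class, cx, cy, cz, radius_um, volume_um3 with
    cx = lateral, cy = depth, cz = B-scan position, all in micrometres.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "volume": out_dir / f"{stem}.tiff",
        "objects": out_dir / f"{stem}_objects.csv",
        "surface": out_dir / f"{stem}_surface.csv",
        "spec": out_dir / f"{stem}_spec.cfg",
    }
    write_volume(volume, paths["volume"])
    rows = [
        {
            "id": o.object_id,
            "class": o.object_class,
            "cx": o.center_um[2],
            "cy": o.center_um[1],
            "cz": o.center_um[0],
            "radius_um": o.radius_um,
            "volume_um3": o.volume_um3,
        }
        for o in truth.objects
    ]
    pd.DataFrame(rows, columns=["id", "class", "cx", "cy", "cz", "radius_um",
                                "volume_um3"]).to_csv(
        paths["objects"], index=False, float_format="%.12g"
    )
    np.savetxt(paths["surface"], truth.surface_depth_um, delimiter=",", fmt="%.6f")
    truth.spec.to_config(paths["spec"])
    return paths


def load_ground_truth(out_dir: str | Path, stem: str) -> GroundTruth:
    """Read back the sidecars written by :func:`save_phantom`."""
    out_dir = Path(out_dir)
    spec = PhantomSpec.from_config(out_dir / f"{stem}_spec.cfg")
    surface = np.loadtxt(out_dir / f"{stem}_surface.csv", delimiter=",", ndmin=2)
    df = pd.read_csv(out_dir / f"{stem}_objects.csv")
    objects = [
        TruthObject(
            int(r["id"]), str(r["class"]),
            (float(r["cz"]), float(r["cy"]), float(r["cx"])),
            float(r["radius_um"]), float(r["volume_um3"]),
        )
        for _, r in df.iterrows()
    ]
    return GroundTruth(surface_depth_um=surface, objects=objects, spec=spec)
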