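"""Normalized surface length (NSL) of a traced tissue surface.

NSL = Ls / Lp, where Ls is the polyline length of the surface profile and Lp
the length of its least-squares third-degree polynomial baseline — a
gyrification-index-style roughness ratio: a smooth ovary surface gives NSL
close to 1, a surface folded by tumor outgrowths gives larger values.

The baseline cubic is evaluated at the profile's own x samples and its length
taken as a polyline, i.e. with the same discretization as Ls, so the ratio is
free of discretization bias.  All lengths are in physical micrometres.  The
OLS cubic is not the shortest admissible baseline, so NSL can in principle
dip below 1 for pathological profiles; such values are reported as-is with a
warning, never clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial

from .errors import InsufficientProfileError, InvalidArgumentError
from .tracing import SurfaceProfile

__all__ = [
    "PolynomialFit",
    "NSLResult",
    "MouseNSL",
    "fit_cubic",
    "polyline_length",
    "compute_nsl",
    "aggregate_mouse",
]


@dataclass
class PolynomialFit:
    """OLS cubic baseline of a surface profile.

    ``coefficients`` are ascending powers in the original micrometre
    coordinates (the fit itself runs on a centered/scaled abscissa for
    conditioning).
    """

    coefficients: np.ndarray  # (4,) ascending powers, original coordinates
    x_range_um: tuple[float, float]
    rmse_um: float
    degree: int = 3

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (4,) or not np.isfinite(self.coefficients).all():
            raise InvalidArgumentError("cubic fit needs 4 finite coefficients")
        lo, hi = self.x_range_um
        if not lo < hi:
            raise InvalidArgumentError("x_range_um must satisfy min < max")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, dtype=float),
                                                self.coefficients)


@dataclass
class NSLResult:
    """Ls, Lp and their ratio for one B-scan profile."""

    Ls_um: float
    Lp_um: float
    nsl: float
    bscan_index: int = 0
    n_points: int = 0
    source: str = "auto"

    def __post_init__(self):
        if not (self.Ls_um > 0 and self.Lp_um > 0 and self.nsl > 0):
            raise InvalidArgumentError("Ls, Lp and nsl must all be positive")


@dataclass
class MouseNSL:
    """Per-mouse aggregate: the mean of the per-B-scan NSL values."""

    mouse_id: str
    group: str
    per_bscan: list[NSLResult]
    mean_nsl: float


def fit_cubic(profile: SurfaceProfile) -> PolynomialFit:
    """Ordinary least-squares cubic of y on x over the profile's points."""
    x, y = profile.x, profile.y
    if np.unique(x).size < 4:
        raise InsufficientProfileError(
            "cubic fit needs at least 4 distinct x positions"
        )
    try:
        fitted = Polynomial.fit(x, y, deg=3)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise InsufficientProfileError(f"rank-deficient cubic design: {exc}") from exc
    coeffs = fitted.convert().coef
    coeffs = np.pad(coeffs, (0, 4 - coeffs.size))  # trailing zeros if degenerate
    resid = y - fitted(x)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return PolynomialFit(
        coefficients=coeffs,
        x_range_um=(float(x.min()), float(x.max())),
        rmse_um=rmse,
    )


def polyline_length(points) -> float:
    """Sum of Euclidean segment lengths of an ordered (x, y) sequence, in um."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise InvalidArgumentError(
            f"polyline needs an (N>=2, 2) point array, got shape {pts.shape}"
        )
    if not np.isfinite(pts).all():
        raise InvalidArgumentError("polyline coordinates must be finite")
    return float(np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1])).sum())


def compute_nsl(profile: SurfaceProfile) -> NSLResult:
    """Compute Ls, Lp and NSL = Ls/Lp for one profile.

    Lp is the polyline length of the fitted cubic sampled at the profile's
    own x positions (same discretization as Ls by design).
    """
    fit = fit_cubic(profile)
    ls = polyline_length(profile.points)
    baseline = np.column_stack([profile.x, fit(profile.x)])
    lp = polyline_length(baseline)
    nsl = ls / lp
    if nsl < 1.0 - 1e-9:
        warnings.warn(
            f"NSL = {nsl:.6f} < 1: the OLS cubic baseline is longer than the "
            "profile; reporting the value as-is",
            stacklevel=2,
        )
    return NSLResult(
        Ls_um=ls,
        Lp_um=lp,
        nsl=nsl,
        bscan_index=profile.bscan_index,
        n_points=profile.n_points,
        source=profile.source,
    )


def aggregate_mouse(results, mouse_id: str, group: str) -> MouseNSL:
    """Average per-B-scan NSL values into one value representing the mouse."""
    results = list(results)
    if not results:
        raise InvalidArgumentError("cannot aggregate an empty result list")
    mean = float(np.mean([r.nsl for r in results]))
    return MouseNSL(mouse_id=mouse_id, group=group, per_bscan=results, mean_nsl=mean)
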