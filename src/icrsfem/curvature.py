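"""Sagittal-curvature and best-fit-sphere post-processing.

Sagittal (axial) power at a radial station x is computed from the axial
radius: the distance from the surface point along the local surface normal
to the apex axis.  For a surface height profile y(x) this is

    r_ax = |x| * sqrt(1 + y'^2) / |y'|          (mm)
    P    = (n - 1) * 1000 / r_ax                (dioptres)

which for a circular arc of radius R reduces to P = (n-1)*1000/R at every
station.  The keratometric index defaults to the clinical 1.3375.  At the
apex the limit |y'|/x -> |y''| is used.  Surfaces are smoothed with a fixed-
parameter smoothing spline before differentiation; flattening (radius
increase) gives a negative power change.

The plane-strain model loses the apex symmetry that stabilizes the axial
radius near x = 0, so the central zone (|x| < 1 mm) of its power profile is
replaced by a smooth polynomial interpolation across the gap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import least_squares

__all__ = [
    "SurfaceProfile",
    "CurvatureProfile",
    "sagittal_power",
    "central_interpolation",
    "best_fit_sphere",
    "curvature_change",
    "KERATOMETRIC_INDEX",
]

KERATOMETRIC_INDEX = 1.3375
#: fixed smoothing-spline parameter (mm^3): light smoothing that removes
#: inter-element wiggle of the quadratic FE surface without biasing the
#: curvature of analytic test circles
SPLINE_LAM = 1e-7
GRID_SPACING = 0.025  # mm
#: the spline derivative is ill-conditioned at the very edge of the data
#: support; the evaluation grid stays this far inside it
EDGE_INSET = 0.1  # mm


@dataclass(frozen=True)
class SurfaceProfile:
    """Single-valued anterior surface y(x), points ordered by x (mm)."""

    points: np.ndarray          # (M, 2)
    zone: float = 10.0          # mm, diameter of interest

    def __post_init__(self) -> None:
        x = self.points[:, 0]
        if np.any(np.diff(x) <= 0):
            raise ValueError("profile x must be strictly increasing")

    @classmethod
    def from_points(cls, pts: np.ndarray, zone: float = 10.0,
                    mirror: bool = False) -> "SurfaceProfile":
        """Sort, dedupe and optionally mirror (axisymmetric half-profile)."""
        pts = np.asarray(pts, dtype=float)
        if mirror:
            neg = pts[pts[:, 0] > 1e-12].copy()
            neg[:, 0] *= -1.0
            pts = np.vstack([neg, pts])
        order = np.argsort(pts[:, 0])
        pts = pts[order]
        keep = np.concatenate([[True], np.diff(pts[:, 0]) > 1e-10])
        return cls(points=pts[keep], zone=zone)

    def spline(self, lam: float = SPLINE_LAM):
        x, y = self.points[:, 0], self.points[:, 1]
        return make_smoothing_spline(x, y, lam=lam)


@dataclass(frozen=True)
class CurvatureProfile:
    radial_position: np.ndarray      # mm
    sagittal_power: np.ndarray       # dioptres
    keratometric_index: float = KERATOMETRIC_INDEX


def sagittal_power(profile: SurfaceProfile, n: float = KERATOMETRIC_INDEX,
                   grid: np.ndarray | None = None) -> CurvatureProfile:
    """Sagittal power versus radial position on a uniform 25 μm grid."""
    spl = profile.spline()
    x_data = profile.points[:, 0]
    if grid is None:
        half = profile.zone / 2.0
        lo = max(-half, x_data.min() + EDGE_INSET)
        hi = min(half, x_data.max() - EDGE_INSET)
        grid = np.arange(np.ceil(lo / GRID_SPACING), np.floor(hi / GRID_SPACING) + 1) * GRID_SPACING
    yp = spl.derivative(1)(grid)
    k = (n - 1.0) * 1000.0
    with np.errstate(divide="ignore", invalid="ignore"):
        power = k * np.abs(yp) / (np.abs(grid) * np.sqrt(1.0 + yp**2))
    at_apex = np.abs(grid) < 1e-12
    if at_apex.any():
        ypp = spl.derivative(2)(grid[at_apex])
        power[at_apex] = k * np.abs(ypp)
    return CurvatureProfile(radial_position=grid, sagittal_power=power,
                            keratometric_index=n)


def central_interpolation(cp: CurvatureProfile, inner_radius: float = 1.0,
                          support: float = 2.0, degree: int = 1) -> CurvatureProfile:
    """Replace the central |x| < inner_radius zone by polynomial interpolation.

    The polynomial is fitted to the finite values in the supporting annulus
    inner_radius <= |x| <= inner_radius + support on both sides of the gap,
    so polynomials up to the fit degree are reproduced exactly.  The default
    degree 1 cannot overshoot the supporting data across the wide gap.
    """
    x, p = cp.radial_position, cp.sagittal_power.copy()
    inside = np.abs(x) < inner_radius
    sup = (~inside) & (np.abs(x) <= inner_radius + support) & np.isfinite(p)
    if sup.sum() < degree + 1 or not (x[sup].min() < 0 < x[sup].max()):
        raise ValueError("insufficient support on both sides of the central gap")
    coef = np.polyfit(x[sup], p[sup], deg=degree)
    p[inside] = np.polyval(coef, x[inside])
    return replace(cp, sagittal_power=p)


def best_fit_sphere(profile: SurfaceProfile, zone_diameter: float = 10.0,
                    n: float = KERATOMETRIC_INDEX) -> tuple[float, float]:
    """Least-squares circle (meridional section of the best-fit sphere).

    Returns (radius mm, power D) for the points with |x| <= zone/2.
    """
    pts = profile.points
    sel = np.abs(pts[:, 0]) <= zone_diameter / 2.0
    x, y = pts[sel, 0], pts[sel, 1]
    if len(x) < 3:
        raise ValueError("not enough points in the fitting zone")
    # collinearity check
    v1 = np.array([x[-1] - x[0], y[-1] - y[0]])
    dev = np.abs((x - x[0]) * v1[1] - (y - y[0]) * v1[0])
    if dev.max() <= 1e-12 * max(1.0, np.abs(v1).max()):
        raise ValueError("degenerate (collinear) surface points")
    # Kasa algebraic fit, then geometric refinement
    A = np.stack([2 * x, 2 * y, np.ones_like(x)], axis=1)
    sol, *_ = np.linalg.lstsq(A, x * x + y * y, rcond=None)
    a, b, c = sol
    r0 = np.sqrt(max(c + a * a + b * b, 1e-30))

    def resid(q):
        return np.hypot(x - q[0], y - q[1]) - q[2]

    fit = least_squares(resid, x0=[a, b, r0], method="lm")
    radius = float(fit.x[2])
    power = (n - 1.0) * 1000.0 / radius
    return radius, power


def curvature_change(pre: CurvatureProfile, post: CurvatureProfile) -> CurvatureProfile:
    """Pointwise power change post - pre (negative = flattening)."""
    if (len(pre.radial_position) != len(post.radial_position)
            or not np.allclose(pre.radial_position, post.radial_position)):
        raise ValueError("curvature profiles are on different grids")
    return CurvatureProfile(radial_position=pre.radial_position,
                            sagittal_power=post.sagittal_power - pre.sagittal_power,
                            keratometric_index=pre.keratometric_index)


# ---------------------------------------------------------------------------
# summaries of a change profile


def central_value(cp: CurvatureProfile) -> float:
    """Power change at the apex (x = 0)."""
    i = int(np.argmin(np.abs(cp.radial_position)))
    return float(cp.sagittal_power[i])


def peripheral_extreme(cp: CurvatureProfile, band: tuple[float, float] = (1.0, 5.0),
                       side: str = "both") -> float:
    """Most negative power change in the peripheral band (signed)."""
    x = cp.radial_position
    if side == "positive":
        sel = (x >= band[0]) & (x <= band[1])
    elif side == "negative":
        sel = (x <= -band[0]) & (x >= -band[1])
    else:
        sel = (np.abs(x) >= band[0]) & (np.abs(x) <= band[1])
    vals = cp.sagittal_power[sel]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no finite values in the peripheral band")
    return float(vals.min())


def zone_mean(cp: CurvatureProfile, diameter: float = 4.0) -> float:
    """Mean power change over the central zone of the given diameter."""
    sel = np.abs(cp.radial_position) <= diameter / 2.0
    vals = cp.sagittal_power[sel]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no finite values in the central zone")
    return float(vals.mean())
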