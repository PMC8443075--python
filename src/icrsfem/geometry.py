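"""Parametric meridional cross-section of the layered cornea.

The cornea is modelled as the band between two circular arcs whose centers
lie on the apex axis (the y-axis): an anterior arc of radius ``r_anterior``
and a posterior arc of radius ``r_posterior``, separated by the central
corneal thickness at the apex.  The apex of the anterior surface sits at the
origin, the eye interior extends toward negative y.

A meridional station is addressed by the angle ``theta`` subtended at the
anterior arc center, measured from the apex axis; the through-thickness
direction at a station is the anterior surface normal (the ray from the
anterior arc center), along which depth is measured.

Three tissue layers are carved out of the band: epithelium (fixed absolute
thickness from the anterior surface), anterior stroma and posterior stroma
(fractional split of the remaining stromal thickness).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CorneaGeometry",
    "TunnelSpec",
    "build_cornea_geometry",
    "thickness_at",
]

UM_PER_MM = 1000.0


@dataclass(frozen=True)
class CorneaGeometry:
    """Layered two-arc corneal cross-section.

    Lengths follow clinical convention: radii and chord in mm, thicknesses
    in μm.
    """

    r_anterior: float = 7.8        # mm
    r_posterior: float = 6.4       # mm
    cct: float = 550.0             # μm, apex thickness
    t_epi: float = 50.0            # μm, epithelium
    f_anterior_stroma: float = 0.4  # anterior share of stromal thickness
    half_chord: float = 5.8        # mm, radial half-extent at the limbus
    apex_axis: str = "y"

    # -- derived, all in mm -------------------------------------------------
    @property
    def cct_mm(self) -> float:
        return self.cct / UM_PER_MM

    @property
    def t_epi_mm(self) -> float:
        return self.t_epi / UM_PER_MM

    @property
    def anterior_center(self) -> np.ndarray:
        return np.array([0.0, -self.r_anterior])

    @property
    def posterior_center(self) -> np.ndarray:
        return np.array([0.0, -(self.cct_mm + self.r_posterior)])

    @property
    def center_offset(self) -> float:
        """Distance between arc centers along the apex axis (mm)."""
        return self.r_anterior - self.cct_mm - self.r_posterior

    @property
    def theta_max(self) -> float:
        """Meridional angle of the limbus (rad)."""
        return float(np.arcsin(self.half_chord / self.r_anterior))

    def __post_init__(self) -> None:
        if not (self.r_anterior > self.r_posterior > 0):
            raise ValueError(
                "require r_anterior > r_posterior > 0, got "
                f"{self.r_anterior!r}, {self.r_posterior!r}"
            )
        if not (self.cct > self.t_epi > 0):
            raise ValueError(f"require cct > t_epi > 0, got cct={self.cct}, t_epi={self.t_epi}")
        if not (0.0 < self.f_anterior_stroma < 1.0):
            raise ValueError("f_anterior_stroma must lie strictly in (0, 1)")
        if not (0.0 < self.half_chord < self.r_anterior):
            raise ValueError("half_chord must lie in (0, r_anterior)")
        # The two arcs must not touch inside the half-chord.
        th = np.linspace(0.0, self.theta_max, 257)
        t = self.thickness_profile(th)
        if not np.all(np.isfinite(t)) or np.any(t <= 0.0):
            raise ValueError("anterior and posterior arcs intersect within the half-chord")

    # -- surface maps --------------------------------------------------------
    def radial_unit(self, theta):
        """Outward surface normal(s) at meridional angle(s) theta."""
        theta = np.asarray(theta, dtype=float)
        return np.stack([np.sin(theta), np.cos(theta)], axis=-1)

    def anterior_point(self, theta):
        return self.anterior_center + self.r_anterior * self.radial_unit(theta)

    def thickness_profile(self, theta):
        """Corneal thickness (mm) along the surface normal at theta.

        The normal through the anterior arc center hits the posterior arc at
        distance ``s`` from that center; the thickness is ``r_anterior - s``.
        """
        theta = np.asarray(theta, dtype=float)
        d = self.center_offset
        disc = self.r_posterior**2 - d**2 * np.sin(theta) ** 2
        with np.errstate(invalid="ignore"):
            s = d * np.cos(theta) + np.sqrt(disc)
        return self.r_anterior - s

    def posterior_point(self, theta):
        return self.anterior_point(theta) - self.thickness_profile(theta)[..., None] * self.radial_unit(theta)

    def point_at(self, theta, depth_mm):
        """Point at meridional angle theta and normal depth below the anterior surface."""
        return self.anterior_center + (self.r_anterior - np.asarray(depth_mm)[..., None]) * self.radial_unit(theta)

    def layer_depths(self, theta):
        """Depths (mm) of the layer interfaces [0, epi, ant/post stroma, posterior]."""
        t = self.thickness_profile(theta)
        epi = np.full_like(t, self.t_epi_mm)
        ant = epi + self.f_anterior_stroma * (t - epi)
        return np.stack([np.zeros_like(t), epi, ant, t], axis=-1)

    def surface_polyline(self, n: int = 200) -> np.ndarray:
        """Both surfaces as an (2n, 2) closed polyline in mm (for CSV export)."""
        th = np.linspace(0.0, self.theta_max, n)
        ant = self.anterior_point(th)
        post = self.posterior_point(th[::-1])
        return np.vstack([ant, post])


@dataclass(frozen=True)
class TunnelSpec:
    """Stromal tunnel footprint: an 800 x 30 μm band at 70% corneal depth.

    ``width`` runs along the surface direction, ``height`` through the
    thickness; ``depth_fraction`` locates the band mid-height as a fraction
    of local thickness measured along the surface normal from the anterior
    surface.  ``center_radial_position`` is the distance of the tunnel
    center from the apex axis.
    """

    width: float = 800.0                 # μm
    height: float = 30.0                 # μm
    depth_fraction: float = 0.70
    center_radial_position: float = 3.0  # mm

    def __post_init__(self) -> None:
        if not (0.0 < self.depth_fraction < 1.0):
            raise ValueError("depth_fraction must lie in (0, 1)")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("tunnel width and height must be positive")

    def theta_center(self, geom: CorneaGeometry) -> float:
        return float(np.arcsin(self.center_radial_position / geom.r_anterior))

    def depth_band(self, geom: CorneaGeometry, theta) -> np.ndarray:
        """(top, bottom) normal depths in mm of the tunnel at angle(s) theta."""
        t = geom.thickness_profile(theta)
        mid = self.depth_fraction * t
        h = self.height / UM_PER_MM
        return np.stack([mid - h / 2.0, mid + h / 2.0], axis=-1)

    def theta_halfwidth(self, geom: CorneaGeometry) -> float:
        """Half the angular extent of the tunnel footprint."""
        thc = self.theta_center(geom)
        depth_mid = self.depth_fraction * float(geom.thickness_profile(thc))
        r_mid = geom.r_anterior - depth_mid
        return 0.5 * (self.width / UM_PER_MM) / r_mid

    def corners(self, geom: CorneaGeometry) -> np.ndarray:
        """The four footprint corners in global (x, y) mm."""
        thc = self.theta_center(geom)
        dth = self.theta_halfwidth(geom)
        pts = []
        for th in (thc - dth, thc + dth):
            top, bot = self.depth_band(geom, th)
            pts.append(geom.point_at(th, top))
            pts.append(geom.point_at(th, bot))
        return np.asarray(pts)

    def validate_inside_posterior_stroma(self, geom: CorneaGeometry) -> None:
        thc = self.theta_center(geom)
        dth = self.theta_halfwidth(geom)
        for th in (thc - dth, thc, thc + dth):
            depths = geom.layer_depths(th)
            ant_stroma_bottom, post = depths[2], depths[3]
            top, bot = self.depth_band(geom, th)
            if not (ant_stroma_bottom < top and bot < post):
                raise ValueError(
                    "tunnel band leaves the posterior stroma at theta="
                    f"{np.degrees(th):.1f} deg (depths {top:.4f}-{bot:.4f} mm, "
                    f"posterior stroma {ant_stroma_bottom:.4f}-{post:.4f} mm)"
                )


def build_cornea_geometry(**params) -> CorneaGeometry:
    """Construct a :class:`CorneaGeometry`, defaulting to the standard eye.

    Presets: ``build_cornea_geometry()`` gives the standard 550 μm cornea;
    ``build_cornea_geometry(cct=450)`` the thin (keratoconus-like) variant.
    """
    return CorneaGeometry(**params)


def thin_cornea_geometry(**params) -> CorneaGeometry:
    """The 450 μm thin-cornea preset, all else default."""
    params.setdefault("cct", 450.0)
    return CorneaGeometry(**params)


def thickness_at(geometry: CorneaGeometry, x: float) -> float:
    """Corneal thickness in μm at radial station ``x`` (mm) from the apex axis.

    Measured along the anterior surface normal at the station; equals the
    central corneal thickness at x = 0.
    """
    if abs(x) > geometry.half_chord:
        raise ValueError(f"station x={x} mm outside half-chord {geometry.half_chord} mm")
    theta = np.arcsin(abs(x) / geometry.r_anterior)
    return float(geometry.thickness_profile(theta)) * UM_PER_MM


def band_coords(geometry: CorneaGeometry, points) -> tuple[np.ndarray, np.ndarray]:
    """Inverse surface map: (meridional angle, normal depth) of global points."""
    p = np.atleast_2d(points) - geometry.anterior_center
    theta = np.arctan2(p[:, 0], p[:, 1])
    depth = geometry.r_anterior - np.linalg.norm(p, axis=1)
    return theta, depth


def with_updates(geom: CorneaGeometry, **kw) -> CorneaGeometry:
    """Functional update helper (frozen dataclass)."""
    return replace(geom, **kw)
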