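"""ICRS parameterization and the in-silico implantation procedure.

A ring design is a pair of linear profiles (thickness and base width versus
arc angle) for a triangular cross-section.  Implantation at one angular
station proceeds in stages: the pre-operative cornea is solved with IOP and
pre-strain on the uncarved mesh; the tunnel elements are then removed and
the tunnel-boundary nodes are displaced onto the triangle outline of the
ring cross-section (base on the tunnel floor, apex pointing anteriorly);
the displaced boundary is bound into a rigid body (the implant is orders of
magnitude stiffer than stroma); finally the rigid master's axial (y)
translation is left free so the ring settles into equilibrium under IOP and
pre-strain, and the post-operative state is solved.

When the ring base is wider than the tunnel footprint the extra width is
taken up entirely on the inner (axis-facing) edge, where the radially
tensile load would open the tunnel during surgery.  A cross-section small
enough to fit inside the 30 μm tunnel cavity makes no contact and imposes
no displacement; a fully zero-size cross-section degenerates to "no
surgery" and the post-operative state equals the pre-operative one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import CorneaGeometry, TunnelSpec, UM_PER_MM
from .materials import default_prestrain, table1
from .mesh import Mesh, MeshDensity, carve_tunnel, generate_mesh
from .solver import (
    LoadCase,
    RigidBody,
    SolutionField,
    TissueModel,
    solve_incremental,
)

__all__ = [
    "RingDesign",
    "CrossSection",
    "ring_cross_section",
    "impose_ring",
    "simulate_implantation",
    "ImplantContext",
]


@dataclass(frozen=True)
class RingDesign:
    """Triangular-section ring: thickness and base width linear in arc angle.

    The default is the asymmetric 160° segment whose thickness grows from
    150 to 300 μm and base width from 600 to 800 μm between its two ends.
    Fixing one profile (both end values equal) gives the hypothetical
    thickness-only / base-only variants; fixing both gives a symmetric ring.
    """

    name: str = "asymmetric"
    arc_length: float = 160.0                      # degrees
    thickness_ends: tuple[float, float] = (150.0, 300.0)   # μm
    base_ends: tuple[float, float] = (600.0, 800.0)        # μm
    shape: str = "triangular"

    def __post_init__(self) -> None:
        if self.arc_length <= 0:
            raise ValueError("arc_length must be positive")
        if min(*self.thickness_ends, *self.base_ends) < 0:
            raise ValueError("profiles must be non-negative")

    def thickness_profile(self, angle: float) -> float:
        self._check(angle)
        t0, t1 = self.thickness_ends
        return t0 + (t1 - t0) * angle / self.arc_length

    def base_profile(self, angle: float) -> float:
        self._check(angle)
        b0, b1 = self.base_ends
        return b0 + (b1 - b0) * angle / self.arc_length

    def _check(self, angle: float) -> None:
        if not (0.0 <= angle <= self.arc_length):
            raise ValueError(f"angle {angle} outside arc [0, {self.arc_length}]")

    # -- the study's designs -------------------------------------------------
    @classmethod
    def asymmetric(cls) -> "RingDesign":
        return cls()

    @classmethod
    def thickness_only(cls, base: float = 700.0) -> "RingDesign":
        return cls(name="thickness_only", base_ends=(base, base))

    @classmethod
    def base_only(cls, thickness: float = 225.0) -> "RingDesign":
        return cls(name="base_only", thickness_ends=(thickness, thickness))

    @classmethod
    def symmetric(cls, thickness: float = 225.0, base: float = 600.0) -> "RingDesign":
        return cls(name="symmetric", thickness_ends=(thickness, thickness),
                   base_ends=(base, base))


@dataclass(frozen=True)
class CrossSection:
    """Isoceles triangle in local tunnel coordinates (mm): base on the
    tunnel floor (eta = 0), apex pointing anteriorly (+eta)."""

    thickness: float     # μm
    base: float          # μm

    @property
    def thickness_mm(self) -> float:
        return self.thickness / UM_PER_MM

    @property
    def base_mm(self) -> float:
        return self.base / UM_PER_MM

    @property
    def area_mm2(self) -> float:
        return 0.5 * self.base_mm * self.thickness_mm

    def outline(self, base_span: tuple[float, float] | None = None) -> np.ndarray:
        """Closed triangle polyline; ``base_span`` overrides the xi extent."""
        if base_span is None:
            base_span = (-self.base_mm / 2.0, self.base_mm / 2.0)
        xl, xr = base_span
        if not (xr > xl) or self.thickness <= 0:
            raise ValueError("degenerate cross-section outline")
        apex = (0.5 * (xl + xr), self.thickness_mm)
        return np.array([(xl, 0.0), (xr, 0.0), apex, (xl, 0.0)])


def ring_cross_section(design: RingDesign, angle: float) -> CrossSection:
    """Cross-section at an angular station, by linear interpolation."""
    return CrossSection(thickness=design.thickness_profile(angle),
                        base=design.base_profile(angle))


def tunnel_band_coords(mesh: Mesh, points) -> np.ndarray:
    """(xi, h) tunnel coordinates of global points: arc length along the
    tunnel floor from its center, and height above the local floor depth."""
    geom, tun = mesh.geometry, mesh.tunnel
    thc = tun.theta_center(geom)
    r_floor = geom.r_anterior - float(tun.depth_band(geom, thc)[1])
    from .geometry import band_coords

    theta, depth = band_coords(geom, points)
    xi = (theta - thc) * r_floor
    h = tun.depth_band(geom, theta)[..., 1] - depth
    return np.column_stack([xi, h])


def _tunnel_frame(mesh: Mesh):
    """Origin (floor center) and (tangent, normal) axes of the tunnel."""
    geom, tun = mesh.geometry, mesh.tunnel
    thc = tun.theta_center(geom)
    d_floor = float(tun.depth_band(geom, thc)[1])
    origin = geom.point_at(thc, d_floor)
    normal = geom.radial_unit(thc)
    tangent = np.array([normal[1], -normal[0]])
    return origin, tangent, normal


def impose_ring(carved_mesh: Mesh, cs: CrossSection, tunnel: TunnelSpec | None = None):
    """Map the tunnel-boundary nodes onto the ring's triangle outline.

    Contact-style imposition: the triangle base is centered on the tunnel
    floor when it fits; when the base is wider than the footprint the
    overhang is taken up entirely on the inner (axis-facing) edge, where the
    radially tensile load would open the tunnel during surgery.  Floor
    nodes under the base rest in place (they carry the base), roof nodes are
    projected along the surface normal onto the slants wherever the triangle
    pokes above the 30 μm cavity, and inner-end nodes are pushed inward when
    the base overhangs.  Nodes the ring does not touch are left free.

    Returns ``(nodes, offsets)`` for the contacted nodes only: the ring's
    outer border (to be bound rigid) and its imposed displacements in mm.
    """
    mesh = carved_mesh
    tunnel = tunnel or mesh.tunnel
    geom = mesh.geometry
    boundary = mesh.node_sets["tunnel_boundary"]
    if len(boundary) == 0:
        raise ValueError("mesh has no tunnel boundary")

    # curvilinear tunnel coordinates: arc length along the floor, height
    # above it (so the triangle follows the curved stromal band exactly)
    thc = tunnel.theta_center(geom)
    r_floor = geom.r_anterior - float(tunnel.depth_band(geom, thc)[1])
    local = tunnel_band_coords(mesh, mesh.nodes[boundary])
    xi, height = local[:, 0], local[:, 1]

    h = tunnel.height / UM_PER_MM
    w = tunnel.width / UM_PER_MM
    tau = cs.thickness_mm
    b = cs.base_mm
    if tau <= h and b <= w:
        # implant fits inside the cavity: no contact, nothing imposed
        return boundary[:0], np.zeros((0, 2))

    # base span on the floor: centered if it fits, otherwise the overhang
    # goes entirely to the inner (-xi) edge
    if b <= w:
        xl, xr = -b / 2.0, b / 2.0
    else:
        xl, xr = w / 2.0 - b, w / 2.0
    xa = 0.5 * (xl + xr)         # apex abscissa

    def slant_height(x):
        if x <= xl or x >= xr:
            return -np.inf
        if x <= xa:
            return tau * (x - xl) / (xa - xl)
        return tau * (xr - x) / (xr - xa)

    def left_slant_x(z):
        return xl + (xa - xl) * z / tau

    def to_global(x, z):
        theta = thc + x / r_floor
        d_floor = float(tunnel.depth_band(geom, theta)[1])
        return geom.point_at(theta, d_floor - z)

    floor = set(mesh.node_sets["tunnel_floor"])
    roof = set(mesh.node_sets["tunnel_roof"])
    inner = set(mesh.node_sets["tunnel_end_inner"])

    tol = 1e-9
    contact_nodes, offsets = [], []
    for k, n in enumerate(boundary):
        x, z = xi[k], height[k]
        target = None
        if n in floor:
            if x >= xl - tol:
                target = (x, z)          # rests under the base
        elif n in roof:
            s = slant_height(x)
            if s > z:
                target = (x, s)          # lifted onto the slant
        elif n in inner and xl < -w / 2.0:
            target = (min(left_slant_x(z), x), z)   # inner-edge expansion
        if target is not None:
            contact_nodes.append(int(n))
            offsets.append(to_global(*target) - mesh.nodes[n])
    return np.asarray(contact_nodes, dtype=int), np.asarray(offsets)


@dataclass
class ImplantContext:
    """Reusable per-(geometry, mode) state: mesh, material model, pre-op solve."""

    geometry: CorneaGeometry
    mode: str
    mesh: Mesh
    model: TissueModel
    preop: SolutionField
    loadcase: LoadCase = field(default_factory=LoadCase.iop)
    n_steps: int = 12


def make_context(geometry: CorneaGeometry | None = None,
                 mode: str = "axisymmetric",
                 tunnel: TunnelSpec | None = None,
                 density: MeshDensity | None = None,
                 iop_mmhg: float = 15.0,
                 materials: dict | None = None,
                 prestrain=None,
                 n_steps: int = 12) -> ImplantContext:
    """Mesh the cornea and solve the pre-operative state once.

    Pre- and post-operative states are both computed with the incremental
    driver (``n_steps`` increments) so that their difference is free of
    discretization-of-path artifacts.
    """
    geometry = geometry or CorneaGeometry()
    tunnel = tunnel or TunnelSpec()
    domain = "half" if mode == "axisymmetric" else "full"
    mesh = generate_mesh(geometry, tunnel, density, domain=domain)
    model = TissueModel(materials or table1(), center=geometry.anterior_center,
                        prestrain=default_prestrain() if prestrain is None else prestrain)
    lc = LoadCase.iop(iop_mmhg)
    preop = solve_incremental(mesh, model, lc, mode=mode, n_steps=n_steps)
    return ImplantContext(geometry=geometry, mode=mode, mesh=mesh,
                          model=model, preop=preop, loadcase=lc, n_steps=n_steps)


def implant(context: ImplantContext, cs: CrossSection) -> SolutionField:
    """Carve the tunnel, impose the ring, release axially, re-solve."""
    if cs.thickness <= 0.0 or cs.base <= 0.0:
        return context.preop          # degenerate design: no surgery
    carved = carve_tunnel(context.mesh)
    nodes, offsets = impose_ring(carved, cs)
    if len(nodes) == 0:               # ring floats in the cavity, no contact
        return solve_incremental(carved, context.model, context.loadcase,
                                 mode=context.mode, n_steps=context.n_steps)
    master = carved.nodes[nodes].mean(axis=0)
    rb = RigidBody(nodes=np.asarray(nodes, dtype=int), master_xy=master,
                   offsets=offsets, fix={"ux": 0.0, "rot": 0.0})
    return solve_incremental(carved, context.model, context.loadcase,
                             rigid_bodies=[rb], mode=context.mode,
                             n_steps=context.n_steps)


def simulate_implantation(geometry: CorneaGeometry | None = None,
                          design: RingDesign | None = None,
                          angle: float = 0.0,
                          mode: str = "axisymmetric",
                          context: ImplantContext | None = None,
                          **context_kw):
    """Full pipeline at one angular station; returns (preop, postop)."""
    design = design or RingDesign.asymmetric()
    if context is None:
        context = make_context(geometry, mode, **context_kw)
    cs = ring_cross_section(design, angle)
    postop = implant(context, cs)
    return context.preop, postop
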