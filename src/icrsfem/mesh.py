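"""Structured quad-8 mesh of the corneal cross-section.

The mesh is a tensor grid in (meridional angle, normal depth): element
columns follow the surface, element rows follow the layer structure.  A thin
through-thickness band at the tunnel depth runs across the whole meridian so
that the 800 x 30 μm tunnel footprint is resolved by a dedicated block of
elements; outside the tunnel's angular extent that band is ordinary
posterior stroma.  Midside nodes are generated by the same surface map as
the corners, so element edges on the anterior and posterior surfaces are
curved and lie on the true arcs.

``domain="half"`` meshes one half-meridian (axisymmetric mode, apex axis on
the left edge); ``domain="full"`` meshes the whole meridian (plane-strain
mode) with the tunnel on the +x side only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import quad

from . import quad8
from .geometry import CorneaGeometry, TunnelSpec

__all__ = ["MeshDensity", "Mesh", "generate_mesh", "carve_tunnel",
           "annular_sector_mesh", "analytic_band_area"]


@dataclass(frozen=True)
class MeshDensity:
    """Through-thickness element counts per band and along-surface budget.

    The defaults put 7 element rows through the thickness and 55 columns
    across a half-meridian, i.e. 385 elements in the axisymmetric mesh.
    """

    n_epi: int = 1
    n_ant: int = 2
    n_post_above: int = 2
    n_tunnel: int = 1
    n_post_below: int = 1
    n_surface: int = 55

    def refine(self, k: int = 2) -> "MeshDensity":
        return MeshDensity(
            n_epi=self.n_epi * k, n_ant=self.n_ant * k,
            n_post_above=self.n_post_above * k, n_tunnel=self.n_tunnel * k,
            n_post_below=self.n_post_below * k, n_surface=self.n_surface * k,
        )

    @property
    def n_rows(self) -> int:
        return (self.n_epi + self.n_ant + self.n_post_above
                + self.n_tunnel + self.n_post_below)


@dataclass(frozen=True)
class Mesh:
    nodes: np.ndarray                 # (N, 2) mm
    elements: np.ndarray              # (E, 8) quad-8 connectivity
    element_sets: dict[str, np.ndarray]
    node_sets: dict[str, np.ndarray]
    active: np.ndarray                # (E,) bool
    node_theta: np.ndarray            # (N,) meridional angle
    node_depth: np.ndarray            # (N,) normal depth, mm
    geometry: CorneaGeometry | None
    tunnel: TunnelSpec | None
    density: MeshDensity | None
    domain: str
    n_cols: int
    n_rows: int
    tunnel_cols: tuple[int, int]      # [c0, c1) element-column range
    tunnel_rows: tuple[int, int]      # [r0, r1) element-row range
    elem_grid: np.ndarray = field(repr=False, default=None)  # (E, 2) (col, row)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def element_coords(self, e: int) -> np.ndarray:
        return self.nodes[self.elements[e]]

    def element_layer(self, e: int) -> str:
        """Material layer of element e (tunnel elements are stromal pre-op)."""
        lab = self._layer_labels[e]
        return "posterior_stroma" if lab == "tunnel" else lab

    @property
    def _layer_labels(self) -> np.ndarray:
        labels = np.empty(self.n_elements, dtype=object)
        for name, idx in self.element_sets.items():
            labels[idx] = name
        return labels

    def meshed_area(self, active_only: bool = False) -> float:
        """Plane cross-section area by quadrature, mm^2."""
        pts, wts = quad8.GAUSS3
        total = 0.0
        for e in range(self.n_elements):
            if active_only and not self.active[e]:
                continue
            coords = self.element_coords(e)
            for (xi, eta), w in zip(pts, wts):
                total += w * quad8.jacobian(coords, xi, eta)[1]
        return total


def _column_edges(geometry: CorneaGeometry, tunnel: TunnelSpec,
                  density: MeshDensity, domain: str):
    """Angular breakpoints of element columns, conforming to the tunnel."""
    th_max = geometry.theta_max
    thc = tunnel.theta_center(geometry)
    dth = tunnel.theta_halfwidth(geometry)
    th1, th2 = thc - dth, thc + dth
    if not (0.0 < th1 < th2 < th_max):
        raise ValueError("tunnel footprint does not fit inside the half-meridian")

    if domain == "half":
        regions = [(0.0, th1), (th1, th2), (th2, th_max)]
        tunnel_region = 1
        n_target = density.n_surface
        span = th_max
    elif domain == "full":
        regions = [(-th_max, 0.0), (0.0, th1), (th1, th2), (th2, th_max)]
        tunnel_region = 2
        n_target = 2 * density.n_surface
        span = 2 * th_max
    else:
        raise ValueError(f"unknown domain {domain!r}")

    avg = span / n_target
    edges = []
    tunnel_span = (0, 0)
    for k, (lo, hi) in enumerate(regions):
        n = max(2 if k == tunnel_region else 1, int(round((hi - lo) / avg)))
        seg = np.linspace(lo, hi, n + 1)
        if k == tunnel_region:
            tunnel_span = (len(edges), len(edges) + n)
        edges.extend(seg[:-1] if k < len(regions) - 1 else seg)
    return np.asarray(edges), tunnel_span


def _row_depths(geometry: CorneaGeometry, tunnel: TunnelSpec,
                density: MeshDensity, theta: float) -> np.ndarray:
    """Depths (mm) of the element-row boundaries at one meridional angle."""
    T = float(geometry.thickness_profile(theta))
    d_epi = geometry.t_epi_mm
    d_as = d_epi + geometry.f_anterior_stroma * (T - d_epi)
    h = tunnel.height / 1000.0
    d_tt = tunnel.depth_fraction * T - h / 2.0
    d_tb = tunnel.depth_fraction * T + h / 2.0
    if not (d_epi < d_as < d_tt < d_tb < T):
        raise ValueError(f"tunnel band collides with layer interfaces at theta={theta}")
    bands = [(0.0, d_epi, density.n_epi),
             (d_epi, d_as, density.n_ant),
             (d_as, d_tt, density.n_post_above),
             (d_tt, d_tb, density.n_tunnel),
             (d_tb, T, density.n_post_below)]
    depths = [0.0]
    for lo, hi, n in bands:
        depths.extend(np.linspace(lo, hi, n + 1)[1:])
    return np.asarray(depths)


def generate_mesh(geometry: CorneaGeometry, tunnel: TunnelSpec | None = None,
                  density: MeshDensity | None = None,
                  domain: str = "half") -> Mesh:
    """Generate the structured quad-8 mesh with named element and node sets.

    Raises if any element has a non-positive Jacobian or the tunnel block
    cannot be embedded at the requested density.
    """
    tunnel = tunnel or TunnelSpec()
    density = density or MeshDensity()
    tunnel.validate_inside_posterior_stroma(geometry)

    edges, (c_t0, c_t1) = _column_edges(geometry, tunnel, density, domain)
    C = len(edges) - 1
    R = density.n_rows
    r_t0 = density.n_epi + density.n_ant + density.n_post_above
    r_t1 = r_t0 + density.n_tunnel

    I, J = 2 * C + 1, 2 * R + 1
    # theta of every node station
    th_sta = np.empty(I)
    th_sta[0::2] = edges
    th_sta[1::2] = 0.5 * (edges[:-1] + edges[1:])

    node_id = -np.ones((I, J), dtype=int)
    xs, ths, dps, ijs = [], [], [], []
    for i in range(I):
        rb = _row_depths(geometry, tunnel, density, th_sta[i])
        d_sta = np.empty(J)
        d_sta[0::2] = rb
        d_sta[1::2] = 0.5 * (rb[:-1] + rb[1:])
        for j in range(J):
            if i % 2 == 1 and j % 2 == 1:
                continue  # serendipity: no element-center nodes
            node_id[i, j] = len(xs)
            xs.append(geometry.point_at(th_sta[i], d_sta[j]))
            ths.append(th_sta[i])
            dps.append(d_sta[j])
            ijs.append((i, j))
    nodes = np.asarray(xs)
    node_theta = np.asarray(ths)
    node_depth = np.asarray(dps)

    # connectivity: corners CCW (deep-left, deep-right, shallow-right,
    # shallow-left), then midsides
    elements, grid = [], []
    layer_of_row = (["epithelium"] * density.n_epi
                    + ["anterior_stroma"] * density.n_ant
                    + ["posterior_stroma"] * density.n_post_above
                    + ["tunnel_band"] * density.n_tunnel
                    + ["posterior_stroma"] * density.n_post_below)
    sets: dict[str, list[int]] = {k: [] for k in
                                  ("epithelium", "anterior_stroma", "posterior_stroma", "tunnel")}
    for r in range(R):
        for c in range(C):
            i0, j0 = 2 * c, 2 * r
            conn = [node_id[i0, j0 + 2], node_id[i0 + 2, j0 + 2],
                    node_id[i0 + 2, j0], node_id[i0, j0],
                    node_id[i0 + 1, j0 + 2], node_id[i0 + 2, j0 + 1],
                    node_id[i0 + 1, j0], node_id[i0, j0 + 1]]
            e = len(elements)
            elements.append(conn)
            grid.append((c, r))
            lab = layer_of_row[r]
            if lab == "tunnel_band":
                lab = "tunnel" if c_t0 <= c < c_t1 else "posterior_stroma"
            sets[lab].append(e)
    elements = np.asarray(elements)
    elem_grid = np.asarray(grid)

    for e in range(len(elements)):
        if quad8.min_jacobian(nodes[elements[e]]) <= 0.0:
            raise ValueError(f"inverted element {e} in generated mesh")

    ij = np.asarray(ijs)
    i_idx, j_idx = ij[:, 0], ij[:, 1]
    node_sets: dict[str, np.ndarray] = {
        "anterior_surface": np.where(j_idx == 0)[0],
        "posterior_surface": np.where(j_idx == 2 * R)[0],
    }
    if domain == "half":
        node_sets["limbus"] = np.where(i_idx == 2 * C)[0]
        node_sets["apex_axis"] = np.where(i_idx == 0)[0]
    else:
        node_sets["limbus"] = np.where((i_idx == 0) | (i_idx == 2 * C))[0]
        k0 = int(np.argmin(np.abs(edges)))
        node_sets["apex_axis"] = np.where(i_idx == 2 * k0)[0]

    ti0, ti1 = 2 * c_t0, 2 * c_t1
    tj0, tj1 = 2 * r_t0, 2 * r_t1
    in_block = (i_idx >= ti0) & (i_idx <= ti1) & (j_idx >= tj0) & (j_idx <= tj1)
    on_perim = in_block & ((i_idx == ti0) | (i_idx == ti1) | (j_idx == tj0) | (j_idx == tj1))
    node_sets["tunnel_boundary"] = np.where(on_perim)[0]
    node_sets["tunnel_roof"] = np.where(in_block & (j_idx == tj0))[0]
    node_sets["tunnel_floor"] = np.where(in_block & (j_idx == tj1))[0]
    node_sets["tunnel_end_inner"] = np.where(
        in_block & (i_idx == ti0) & (j_idx > tj0) & (j_idx < tj1))[0]
    node_sets["tunnel_end_outer"] = np.where(
        in_block & (i_idx == ti1) & (j_idx > tj0) & (j_idx < tj1))[0]

    return Mesh(
        nodes=nodes, elements=elements,
        element_sets={k: np.asarray(v, dtype=int) for k, v in sets.items()},
        node_sets=node_sets, active=np.ones(len(elements), dtype=bool),
        node_theta=node_theta, node_depth=node_depth,
        geometry=geometry, tunnel=tunnel, density=density, domain=domain,
        n_cols=C, n_rows=R, tunnel_cols=(c_t0, c_t1), tunnel_rows=(r_t0, r_t1),
        elem_grid=elem_grid,
    )


def carve_tunnel(mesh: Mesh) -> Mesh:
    """Deactivate the tunnel elements (pre-op mesh keeps them stromal).

    Carving an already-carved mesh warns and returns it unchanged.
    """
    tun = mesh.element_sets["tunnel"]
    if len(tun) == 0:
        raise ValueError("mesh has no tunnel element set")
    if not mesh.active[tun].any():
        warnings.warn("tunnel already carved; no-op", stacklevel=2)
        return mesh
    active = mesh.active.copy()
    active[tun] = False
    return replace(mesh, active=active)


def annular_sector_mesh(r_in: float, r_out: float, n_r: int, n_t: int,
                        theta_lo: float = 0.0, theta_hi: float = np.pi / 2,
                        ) -> Mesh:
    """Quad-8 mesh of an annular sector, for closed-form verification.

    Angles are measured from the +y axis (as in the cornea convention);
    node sets: ``inner``, ``outer`` (arcs), ``axis`` (theta_lo edge),
    ``equator`` (theta_hi edge).  Element set: ``body``.
    """
    th = np.linspace(theta_lo, theta_hi, 2 * n_t + 1)
    rr = np.linspace(r_in, r_out, 2 * n_r + 1)
    nid = -np.ones((2 * n_t + 1, 2 * n_r + 1), dtype=int)
    pts, ths, dps = [], [], []
    for i in range(2 * n_t + 1):
        for j in range(2 * n_r + 1):
            if i % 2 == 1 and j % 2 == 1:
                continue
            nid[i, j] = len(pts)
            pts.append([rr[j] * np.sin(th[i]), rr[j] * np.cos(th[i])])
            ths.append(th[i])
            dps.append(r_out - rr[j])
    els = []
    for c in range(n_t):
        for r in range(n_r):
            i0, j0 = 2 * c, 2 * r
            els.append([nid[i0, j0], nid[i0 + 2, j0], nid[i0 + 2, j0 + 2],
                        nid[i0, j0 + 2], nid[i0 + 1, j0], nid[i0 + 2, j0 + 1],
                        nid[i0 + 1, j0 + 2], nid[i0, j0 + 1]])
    pts = np.asarray(pts)
    els = np.asarray(els)
    for e in range(len(els)):
        if quad8.min_jacobian(pts[els[e]]) <= 0.0:  # pragma: no cover
            raise ValueError("inverted element in annular sector mesh")
    rad = np.hypot(pts[:, 0], pts[:, 1])
    node_sets = {
        "inner": np.where(np.isclose(rad, r_in))[0],
        "outer": np.where(np.isclose(rad, r_out))[0],
        "axis": np.where(np.isclose(np.asarray(ths), theta_lo))[0],
        "equator": np.where(np.isclose(np.asarray(ths), theta_hi))[0],
    }
    return Mesh(nodes=pts, elements=els,
                element_sets={"body": np.arange(len(els))},
                node_sets=node_sets, active=np.ones(len(els), dtype=bool),
                node_theta=np.asarray(ths), node_depth=np.asarray(dps),
                geometry=None, tunnel=None, density=None, domain="sector",
                n_cols=n_t, n_rows=n_r, tunnel_cols=(0, 0), tunnel_rows=(0, 0))


def analytic_band_area(geometry: CorneaGeometry, theta_lo: float, theta_hi: float) -> float:
    """Exact plane area (mm^2) of the corneal band between two angles.

    The map (theta, depth) -> (x, y) has Jacobian (r_anterior - depth), so
    the area is the integral of ``R_a*T - T^2/2`` over theta.
    """
    Ra = geometry.r_anterior

    def integrand(th):
        T = float(geometry.thickness_profile(th))
        return Ra * T - 0.5 * T * T

    val, _ = quad(integrand, theta_lo, theta_hi, limit=200)
    return val
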