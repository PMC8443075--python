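"""Static FEM on quad-8 meshes, axisymmetric or plane strain.

The same 4-component Voigt machinery (xx, yy, hoop, xy) serves both modes:
in the axisymmetric mode the hoop strain row of B is ``u_x/x`` and volume
integration carries the ``2*pi*x`` weight (x = distance to the apex axis);
in plane strain the hoop strain row is zero and the depth is unit.  Material
anisotropy is evaluated in local (circumferential, radial) axes at every
quadrature point and rotated to global axes.

Two drivers are provided.  ``solve_static`` is the small-strain linear
operator: one assembly, one sparse direct solve; it satisfies superposition
exactly and is used for the pre-operative state and for all closed-form
verification problems.  ``solve_incremental`` is an updated-Lagrangian
Euler driver for the implantation stage, where imposed boundary
displacements of several hundred μm rotate the corneal meridian far enough
that membrane straightening (an arc-length effect, quadratic in rotation)
dominates the central response: loads and imposed displacements are ramped
in equal increments and the nodal coordinates are updated after each linear
step, so finite-rotation kinematics accumulate along the path.

Constraints (prescribed displacements and rigid-body couplings) are applied
by elimination: u = T q + g, and the reduced system ``T'KT q = T'(f - Kg)``
is solved with a sparse direct factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from . import quad8
from .materials import (
    InitialStrainField,
    MaterialSpec,
    rotation_voigt,
)
from .mesh import Mesh

__all__ = [
    "TissueModel",
    "LoadCase",
    "RigidBody",
    "SolutionField",
    "element_stiffness",
    "solve_static",
    "solve_incremental",
    "rigid_body_constraint",
    "von_mises",
    "MMHG_TO_PA",
]

MMHG_TO_PA = 133.322

_DOF = 2  # ux, uy per node


class TissueModel:
    """Material field: layer specs + local axes about a curvature center.

    ``center=None`` means the local axes coincide with the global axes
    everywhere (used by patch tests); otherwise the radial axis points from
    ``center`` through the evaluation point.
    """

    def __init__(self, specs: dict[str, MaterialSpec], center=None,
                 prestrain: list[InitialStrainField] | None = None):
        self.specs = specs
        self.center = None if center is None else np.asarray(center, dtype=float)
        self.prestrain = {f.layer: f for f in (prestrain or [])}
        self._Dloc = {k: np.linalg.inv(v.compliance4()) for k, v in specs.items()}

    def axes(self, point) -> np.ndarray:
        """Rows: local circumferential (tangent) and radial axes at a point."""
        if self.center is None:
            return np.eye(2)
        p = np.asarray(point, dtype=float) - self.center
        r = np.hypot(p[0], p[1])
        u = p / r
        return np.array([[u[1], -u[0]], [u[0], u[1]]])

    def axes_batch(self, points: np.ndarray) -> np.ndarray:
        """(n, 2, 2) local axes for an array of points."""
        n = len(points)
        if self.center is None:
            return np.broadcast_to(np.eye(2), (n, 2, 2)).copy()
        v = points - self.center
        u = v / np.linalg.norm(v, axis=1, keepdims=True)
        a = np.empty((n, 2, 2))
        a[:, 0, 0] = u[:, 1]
        a[:, 0, 1] = -u[:, 0]
        a[:, 1, 0] = u[:, 0]
        a[:, 1, 1] = u[:, 1]
        return a

    def D_global(self, point, layer: str) -> np.ndarray:
        T = rotation_voigt(self.axes(point))
        return T.T @ self._Dloc[layer] @ T

    def eps_pre_global(self, point, layer: str) -> np.ndarray | None:
        f = self.prestrain.get(layer)
        if f is None:
            return None
        Tinv = rotation_voigt(self.axes(point).T)
        return Tinv @ f.local_vector()

    def eps_pre_local(self, layer: str) -> np.ndarray:
        f = self.prestrain.get(layer)
        return f.local_vector() if f is not None else np.zeros(4)


@dataclass
class LoadCase:
    """Loads: surface pressure (Pa) on a boundary node set, plus pre-strain.

    The pressure traction acts along the surface normal oriented away from
    the tissue's curvature center, i.e. an intraocular pressure on the
    posterior surface pushes the cornea anteriorly.
    """

    pressure: float = 0.0
    pressure_set: str = "posterior_surface"
    prescribed: list[tuple[int, int, float]] = field(default_factory=list)

    @classmethod
    def iop(cls, mmhg: float = 15.0) -> "LoadCase":
        return cls(pressure=mmhg * MMHG_TO_PA)


@dataclass
class RigidBody:
    """Multi-point constraint: slave nodes follow one rigid master.

    ``offsets`` are imposed slave displacements relative to the rigid
    motion (the in-silico ring imposition); ``fix`` pins selected master
    dofs ("ux", "uy", "rot") to values, the rest equilibrate freely.
    """

    nodes: np.ndarray
    master_xy: np.ndarray
    offsets: np.ndarray | None = None      # (n, 2) or None
    fix: dict[str, float] = field(default_factory=dict)


def rigid_body_constraint(node_set, coords, master_xy=None, offsets=None,
                          fix=None) -> RigidBody:
    """Tie the nodes of ``node_set`` (with coordinates ``coords``) rigidly.

    The master defaults to the centroid of the constrained nodes.
    """
    node_set = np.asarray(node_set, dtype=int)
    if len(node_set) < 2:
        raise ValueError("a rigid body needs at least two nodes")
    if master_xy is None:
        master_xy = coords.mean(axis=0)
    return RigidBody(nodes=node_set, master_xy=np.asarray(master_xy, float),
                     offsets=offsets, fix=dict(fix or {}))


# ---------------------------------------------------------------------------
# single-element operations (scalar path, used by verification tests)


def _B_matrix(dN_xy: np.ndarray, N: np.ndarray, x: float, mode: str) -> np.ndarray:
    """Strain-displacement matrix, 4 x 16, Voigt (xx, yy, hoop, xy)."""
    B = np.zeros((4, 16))
    B[0, 0::2] = dN_xy[:, 0]
    B[1, 1::2] = dN_xy[:, 1]
    if mode == "axisymmetric":
        B[2, 0::2] = N / x
    B[3, 0::2] = dN_xy[:, 1]
    B[3, 1::2] = dN_xy[:, 0]
    return B


def _vol_weight(w: float, detJ: float, x: float, mode: str) -> float:
    if mode == "axisymmetric":
        return w * detJ * 2.0 * np.pi * x
    return w * detJ


def element_stiffness(coords: np.ndarray, D_of_point, mode: str) -> np.ndarray:
    """16x16 element stiffness; ``D_of_point(point) -> 4x4`` global stiffness.

    A constant 4x4 array may be passed instead of a callable.
    """
    if not callable(D_of_point):
        Dc = np.asarray(D_of_point)
        D_of_point = lambda p: Dc  # noqa: E731
    pts, wts = quad8.GAUSS3
    K = np.zeros((16, 16))
    for (xi, eta), w in zip(pts, wts):
        N = quad8.shape(xi, eta)
        _, detJ, dN_xy = quad8.jacobian(coords, xi, eta)
        if detJ <= 0.0:
            raise ValueError("singular or inverted element Jacobian")
        p = N @ coords
        x = p[0]
        if mode == "axisymmetric" and x <= 0.0:
            raise ValueError("axisymmetric element with non-positive radius")
        B = _B_matrix(dN_xy, N, x, mode)
        D = D_of_point(p)
        K += _vol_weight(w, detJ, x, mode) * (B.T @ D @ B)
    return 0.5 * (K + K.T)


# ---------------------------------------------------------------------------
# vectorized assembly over all active elements


def _layer_labels(mesh: Mesh) -> np.ndarray:
    labels = np.empty(mesh.n_elements, dtype=object)
    for name, idx in mesh.element_sets.items():
        labels[idx] = "posterior_stroma" if name == "tunnel" else name
    return labels


def _layer_index(mesh: Mesh, model: TissueModel):
    """Integer layer id per element + stacked local D and pre-strain."""
    labels = _layer_labels(mesh)
    names = list(model.specs.keys())
    lut = {n: i for i, n in enumerate(names)}
    try:
        idx = np.array([lut[l] for l in labels], dtype=int)
    except KeyError as err:
        raise KeyError(f"unknown layer label {err.args[0]!r}") from None
    Dloc = np.stack([model._Dloc[n] for n in names])
    eps0 = np.stack([model.eps_pre_local(n) for n in names])
    return idx, Dloc, eps0


def _rotation_voigt_batch(a: np.ndarray) -> np.ndarray:
    """(n, 4, 4) Voigt strain transforms for (n, 2, 2) axis matrices."""
    n = len(a)
    T = np.zeros((n, 4, 4))
    a11, a12 = a[:, 0, 0], a[:, 0, 1]
    a21, a22 = a[:, 1, 0], a[:, 1, 1]
    T[:, 0, 0] = a11 * a11
    T[:, 0, 1] = a12 * a12
    T[:, 0, 3] = a11 * a12
    T[:, 1, 0] = a21 * a21
    T[:, 1, 1] = a22 * a22
    T[:, 1, 3] = a21 * a22
    T[:, 2, 2] = 1.0
    T[:, 3, 0] = 2 * a11 * a21
    T[:, 3, 1] = 2 * a12 * a22
    T[:, 3, 3] = a11 * a22 + a12 * a21
    return T


def _gp_batch(coords: np.ndarray, xi: float, eta: float, mode: str):
    """Per-element B matrices, gp positions and |J| at one Gauss point."""
    E = len(coords)
    N = quad8.shape(xi, eta)
    dN = quad8.shape_grad(xi, eta)
    J = np.einsum("ak,eaj->ekj", dN, coords)          # (E,2,2), rows d/dxi
    detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    if np.any(detJ <= 0.0):
        raise ValueError("singular or inverted element Jacobian")
    inv = np.empty_like(J)                             # inv(J)
    inv[:, 0, 0] = J[:, 1, 1]
    inv[:, 0, 1] = -J[:, 0, 1]
    inv[:, 1, 0] = -J[:, 1, 0]
    inv[:, 1, 1] = J[:, 0, 0]
    inv /= detJ[:, None, None]
    dN_xy = np.einsum("ak,ejk->eaj", dN, inv)          # dN @ inv(J).T
    p = np.einsum("a,eaj->ej", N, coords)
    B = np.zeros((E, 4, 16))
    B[:, 0, 0::2] = dN_xy[:, :, 0]
    B[:, 1, 1::2] = dN_xy[:, :, 1]
    if mode == "axisymmetric":
        if np.any(p[:, 0] <= 0.0):
            raise ValueError("axisymmetric element with non-positive radius")
        B[:, 2, 0::2] = N / p[:, 0:1]
    B[:, 3, 0::2] = dN_xy[:, :, 1]
    B[:, 3, 1::2] = dN_xy[:, :, 0]
    return B, p, detJ, dN_xy, N


def _assemble(mesh: Mesh, model: TissueModel, mode: str,
              with_prestrain: bool, coords_override=None):
    """Stiffness and (optionally) pre-strain load in one vectorized pass."""
    act = np.where(mesh.active)[0]
    conn = mesh.elements[act]
    nodes = mesh.nodes if coords_override is None else coords_override
    coords = nodes[conn]
    lidx, DlocL, eps0L = _layer_index(mesh, model)
    Dloc = DlocL[lidx[act]]
    eps0 = eps0L[lidx[act]]
    has_pre = np.abs(eps0).max(axis=1) > 0

    pts, wts = quad8.GAUSS3
    E = len(act)
    Ke = np.zeros((E, 16, 16))
    fe = np.zeros((E, 16))
    for (xi, eta), w in zip(pts, wts):
        B, p, detJ, _, _ = _gp_batch(coords, xi, eta, mode)
        a = model.axes_batch(p)
        T = _rotation_voigt_batch(a)
        D = np.einsum("eji,ejk,ekl->eil", T, Dloc, T)
        vol = w * detJ * (2.0 * np.pi * p[:, 0] if mode == "axisymmetric" else 1.0)
        Ke += vol[:, None, None] * np.einsum("eji,ejk,ekl->eil", B, D, B)
        if with_prestrain and has_pre.any():
            Tinv = _rotation_voigt_batch(np.transpose(a, (0, 2, 1)))
            e0g = np.einsum("eij,ej->ei", Tinv, eps0)
            fe -= vol[:, None] * np.einsum("eji,ejk,ek->ei", B, D, e0g)

    dofs = np.empty((E, 16), dtype=int)
    dofs[:, 0::2] = 2 * conn
    dofs[:, 1::2] = 2 * conn + 1
    rows = np.repeat(dofs, 16, axis=1).ravel()
    cols = np.tile(dofs, (1, 16)).ravel()
    n = _DOF * mesh.n_nodes
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    f = np.zeros(n)
    np.add.at(f, dofs.ravel(), fe.ravel())
    return K, f


def assemble_stiffness(mesh: Mesh, model: TissueModel, mode: str) -> sp.csr_matrix:
    return _assemble(mesh, model, mode, with_prestrain=False)[0]


def assemble_prestrain_load(mesh: Mesh, model: TissueModel,
                            fields=None, mode: str = "axisymmetric") -> np.ndarray:
    """RHS contribution of the layer pre-strain.

    With the elastic-pre-strain convention sigma = D (eps + eps_pre), the
    equilibrium RHS picks up ``-int B' D eps_pre dV`` over every element.
    """
    if fields is not None:
        model = TissueModel(model.specs, center=model.center, prestrain=list(fields))
    return _assemble(mesh, model, mode, with_prestrain=True)[1]


_EDGES = [(0, 1, 4), (1, 2, 5), (2, 3, 6), (3, 0, 7)]


def assemble_pressure_load(mesh: Mesh, model: TissueModel, pressure: float,
                           node_set: str, mode: str,
                           coords_override=None) -> np.ndarray:
    """Consistent load of a pressure on boundary edges within ``node_set``.

    Traction = pressure * n with n the surface normal pointing away from the
    model's curvature center (outward through the tissue).
    """
    nodes = mesh.nodes if coords_override is None else coords_override
    f = np.zeros(_DOF * mesh.n_nodes)
    if pressure == 0.0:
        return f
    members = np.zeros(mesh.n_nodes, dtype=bool)
    members[mesh.node_sets[node_set]] = True
    center = model.center if model.center is not None else np.zeros(2)
    sg, wg = quad8.edge_gauss(3)
    for e in range(mesh.n_elements):
        if not mesh.active[e]:
            continue
        conn = mesh.elements[e]
        for (a, b, m) in _EDGES:
            tri = conn[[a, b, m]]
            if not members[tri].all():
                continue
            coords = nodes[tri]
            fe = np.zeros((3, 2))
            for s, w in zip(sg, wg):
                N = quad8.edge_shape(s)
                dN = quad8.edge_shape_grad(s)
                p = N @ coords
                tangent = dN @ coords
                normal = np.array([tangent[1], -tangent[0]])
                if normal @ (p - center) < 0:
                    normal = -normal
                # |tangent| ds is the edge measure; normal carries that length
                wt = w * (2.0 * np.pi * p[0] if mode == "axisymmetric" else 1.0)
                fe += wt * pressure * np.outer(N, normal)
            dofs = np.empty(6, dtype=int)
            dofs[0::2] = 2 * tri
            dofs[1::2] = 2 * tri + 1
            np.add.at(f, dofs, fe.ravel())
    return f


def default_bcs(mesh: Mesh, mode: str) -> list[tuple[int, int, float]]:
    """Limbal pin (both translations fixed) + symmetry on the apex axis."""
    bcs = []
    for n in mesh.node_sets["limbus"]:
        bcs.append((int(n), 0, 0.0))
        bcs.append((int(n), 1, 0.0))
    if mode == "axisymmetric":
        for n in mesh.node_sets["apex_axis"]:
            bcs.append((int(n), 0, 0.0))
    return bcs


@dataclass
class SolutionField:
    """Nodal displacements plus quadrature-point stresses in local axes."""

    mesh: Mesh
    mode: str
    displacements: np.ndarray            # (N, 2) mm
    stress_local: np.ndarray             # (E, ngp, 4): (cc, rr, hh, cr), Pa
    von_mises: np.ndarray                # (E,) max over gp, Pa
    strain_local: np.ndarray             # (E, ngp, 4) incl. pre-strain
    residual_rel: float
    reactions: np.ndarray                # (2N,) K u - f
    master_dofs: dict = field(default_factory=dict)

    @property
    def deformed_nodes(self) -> np.ndarray:
        return self.mesh.nodes + self.displacements

    def anterior_surface_points(self, deformed: bool = True) -> np.ndarray:
        idx = self.mesh.node_sets["anterior_surface"]
        pts = self.deformed_nodes[idx] if deformed else self.mesh.nodes[idx]
        order = np.argsort(self.mesh.node_theta[idx])
        return pts[order]


def von_mises(stress4) -> float:
    """Standard 3D von Mises from (s11, s22, s33, s12) with s13 = s23 = 0."""
    s = np.asarray(stress4, dtype=float)
    s11, s22, s33, s12 = s[..., 0], s[..., 1], s[..., 2], s[..., 3]
    return np.sqrt(0.5 * ((s11 - s22) ** 2 + (s22 - s33) ** 2 + (s33 - s11) ** 2)
                   + 3.0 * s12 ** 2)


def _auto_pin_unattached(mesh: Mesh, fixed: dict[int, float], rigid_bodies):
    """Pin dofs of nodes attached to no active element (carved interiors)."""
    attached = np.zeros(mesh.n_nodes, dtype=bool)
    attached[mesh.elements[mesh.active].ravel()] = True
    in_rigid = set()
    for rb in rigid_bodies:
        in_rigid.update(int(n) for n in rb.nodes)
    for n in np.where(~attached)[0]:
        if int(n) in in_rigid:
            continue
        fixed.setdefault(2 * int(n), 0.0)
        fixed.setdefault(2 * int(n) + 1, 0.0)


def _build_transform(mesh: Mesh, fixed: dict[int, float],
                     rigid_bodies: list[RigidBody], coords_override=None):
    """u = T q + g elimination operators for fixed dofs and rigid couplings."""
    nodes = mesh.nodes if coords_override is None else coords_override
    n = _DOF * mesh.n_nodes
    g = np.zeros(n)
    slave = np.zeros(n, dtype=bool)
    for dof, val in fixed.items():
        slave[dof] = True
        g[dof] = val

    rows, cols, vals = [], [], []
    master_cols: list[dict[str, int]] = []

    for rb in rigid_bodies:
        for k, node in enumerate(rb.nodes):
            off = rb.offsets[k] if rb.offsets is not None else (0.0, 0.0)
            for d in range(2):
                dof = 2 * int(node) + d
                if slave[dof]:
                    raise ValueError("node in a rigid body is also constrained directly")
                slave[dof] = True
                g[dof] = off[d]

    free_dofs = np.where(~slave)[0]
    col_of = {int(d): i for i, d in enumerate(free_dofs)}
    ncol = len(free_dofs)
    for d in free_dofs:
        rows.append(int(d)); cols.append(col_of[int(d)]); vals.append(1.0)

    for rb in rigid_bodies:
        cols_rb: dict[str, int] = {}
        for name in ("ux", "uy", "rot"):
            if name in rb.fix:
                continue
            cols_rb[name] = ncol
            ncol += 1
        master_cols.append(cols_rb)
        for node in rb.nodes:
            dx = nodes[int(node)] - rb.master_xy
            # ux_s = ux_m - rot*dy ; uy_s = uy_m + rot*dx
            terms = {
                2 * int(node): (("ux", 1.0), ("rot", -dx[1])),
                2 * int(node) + 1: (("uy", 1.0), ("rot", dx[0])),
            }
            for dof, tt in terms.items():
                for name, coef in tt:
                    if name in rb.fix:
                        g[dof] += coef * rb.fix[name]
                    else:
                        rows.append(dof); cols.append(cols_rb[name]); vals.append(coef)

    T = sp.coo_matrix((vals, (rows, cols)), shape=(n, ncol)).tocsr()
    return T, g, master_cols


def _linear_step(mesh, model, mode, fixed, rigid_bodies, K, f, coords_override=None):
    T, g, master_cols = _build_transform(mesh, fixed, rigid_bodies, coords_override)
    Kq = (T.T @ K @ T).tocsc()
    fq = T.T @ (f - K @ g)
    q = spsolve(Kq, fq) if Kq.shape[0] else np.zeros(0)
    if not np.all(np.isfinite(q)):
        raise RuntimeError("singular constrained system (unconstrained rigid modes?)")
    U = T @ q + g
    r = K @ U - f
    scale = max(np.abs(f).max(), np.abs(K @ U).max(), 1e-30)
    res = np.abs(T.T @ r)
    residual_rel = float(res.max() / scale) if res.size else 0.0
    masters = [{name: float(q[c]) for name, c in cols.items()} for cols in master_cols]
    return U, r, residual_rel, masters


def solve_static(mesh: Mesh, model: TissueModel, loadcase: LoadCase,
                 constraints=None, rigid_bodies=(), mode: str = "axisymmetric",
                 ) -> SolutionField:
    """Assemble and solve one linear static case; recover stresses.

    ``constraints`` is a list of (node, dof, value) prescriptions; ``None``
    applies the cornea defaults (pinned limbus, symmetry axis).
    """
    if constraints is None:
        constraints = default_bcs(mesh, mode)
    fixed: dict[int, float] = {}
    for node, d, val in list(constraints) + list(loadcase.prescribed):
        fixed[2 * int(node) + d] = float(val)
    rigid_bodies = list(rigid_bodies)
    _auto_pin_unattached(mesh, fixed, rigid_bodies)

    K, f_pre = _assemble(mesh, model, mode, with_prestrain=True)
    f = f_pre + assemble_pressure_load(mesh, model, loadcase.pressure,
                                       loadcase.pressure_set, mode)
    U, r, residual_rel, masters = _linear_step(mesh, model, mode, fixed,
                                               rigid_bodies, K, f)
    disp = U.reshape(-1, 2)
    stress, strain, vm = _recover_stresses(mesh, model, disp, mode)
    return SolutionField(mesh=mesh, mode=mode, displacements=disp,
                         stress_local=stress, von_mises=vm, strain_local=strain,
                         residual_rel=residual_rel, reactions=r,
                         master_dofs=dict(enumerate(masters)))


def _assemble_nl(mesh: Mesh, model: TissueModel, mode: str, coords: np.ndarray,
                 sig_el: np.ndarray, sig_pre: np.ndarray, lam: float):
    """Tangent (material + geometric) stiffness and internal force.

    ``sig_el`` is the tracked elastic stress from the displacement history,
    ``sig_pre`` the pre-stress field, both in global Voigt components at the
    3x3 Gauss points of the active elements; the total stress
    ``sig_el + lam*sig_pre`` enters both the internal force and the
    initial-stress (geometric) stiffness, which carries the membrane-tension
    coupling between in-plane stress and transverse deflection.
    """
    act = np.where(mesh.active)[0]
    conn = mesh.elements[act]
    ecoords = coords[conn]
    lidx, DlocL, _ = _layer_index(mesh, model)
    Dloc = DlocL[lidx[act]]

    pts, wts = quad8.GAUSS3
    E = len(act)
    Ke = np.zeros((E, 16, 16))
    fe = np.zeros((E, 16))
    Bs, Ds = [], []
    ix = np.arange(0, 16, 2)
    eidx = np.arange(E)
    for i, ((xi, eta), w) in enumerate(zip(pts, wts)):
        B, p, detJ, dN_xy, N = _gp_batch(ecoords, xi, eta, mode)
        a = model.axes_batch(p)
        T = _rotation_voigt_batch(a)
        D = np.einsum("eji,ejk,ekl->eil", T, Dloc, T)
        vol = w * detJ * (2.0 * np.pi * p[:, 0] if mode == "axisymmetric" else 1.0)
        Ke += vol[:, None, None] * np.einsum("eji,ejk,ekl->eil", B, D, B)
        sig = sig_el[:, i, :] + lam * sig_pre[:, i, :]
        fe += vol[:, None] * np.einsum("eji,ej->ei", B, sig)
        # geometric stiffness: grad(N)' [[sxx,sxy],[sxy,syy]] grad(N) on both
        # displacement components, plus the axisymmetric hoop term
        s2 = np.empty((E, 2, 2))
        s2[:, 0, 0] = sig[:, 0]
        s2[:, 1, 1] = sig[:, 1]
        s2[:, 0, 1] = s2[:, 1, 0] = sig[:, 3]
        Kg8 = vol[:, None, None] * np.einsum("eak,ekl,ebl->eab", dN_xy, s2, dN_xy)
        Ke[np.ix_(eidx, ix, ix)] += Kg8
        Ke[np.ix_(eidx, ix + 1, ix + 1)] += Kg8
        if mode == "axisymmetric":
            hoop = (vol * sig[:, 2] / p[:, 0] ** 2)[:, None, None] * np.outer(N, N)
            Ke[np.ix_(eidx, ix, ix)] += hoop
        Bs.append(B)
        Ds.append(D)

    dofs = np.empty((E, 16), dtype=int)
    dofs[:, 0::2] = 2 * conn
    dofs[:, 1::2] = 2 * conn + 1
    rows = np.repeat(dofs, 16, axis=1).ravel()
    cols = np.tile(dofs, (1, 16)).ravel()
    n = _DOF * mesh.n_nodes
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    f_int = np.zeros(n)
    np.add.at(f_int, dofs.ravel(), fe.ravel())
    return K, f_int, Bs, Ds, dofs


def _prestress_field(mesh: Mesh, model: TissueModel, mode: str) -> np.ndarray:
    """Pre-stress (global Voigt) at the 3x3 Gauss points of active elements."""
    act = np.where(mesh.active)[0]
    conn = mesh.elements[act]
    ecoords = mesh.nodes[conn]
    lidx, DlocL, eps0L = _layer_index(mesh, model)
    Dloc = DlocL[lidx[act]]
    eps0 = eps0L[lidx[act]]
    pts, _ = quad8.GAUSS3
    sig = np.zeros((len(act), len(pts), 4))
    if np.abs(eps0).max() == 0.0:
        return sig
    for i, (xi, eta) in enumerate(pts):
        _, p, _, _, _ = _gp_batch(ecoords, xi, eta, mode)
        T = _rotation_voigt_batch(model.axes_batch(p))
        # sig_glob = T' Dloc T (T^-1 eps0_loc) = T' (Dloc eps0_loc)
        sig[:, i, :] = np.einsum("eji,ej->ei",
                                 T, np.einsum("eij,ej->ei", Dloc, eps0))
    return sig


def solve_incremental(mesh: Mesh, model: TissueModel, loadcase: LoadCase,
                      constraints=None, rigid_bodies=(), mode: str = "axisymmetric",
                      n_steps: int = 12, max_iter: int = 25,
                      tol: float = 1e-7) -> SolutionField:
    """Incremental Newton solve with stress tracking and geometric stiffness.

    Pressure, pre-stress and imposed displacements are ramped in equal load
    steps; within each step full Newton iterations equilibrate the internal
    force against the external load on the current (updated) configuration.
    The tracked stress provides the initial-stress stiffness, so the pre-
    tensioned corneal membrane responds to the ring's lift with the
    arc-length (drumhead) coupling that a single linear solve cannot
    represent.
    """
    if constraints is None:
        constraints = default_bcs(mesh, mode)
    fixed_total: dict[int, float] = {}
    for node, d, val in list(constraints) + list(loadcase.prescribed):
        fixed_total[2 * int(node) + d] = float(val)
    rigid_bodies = list(rigid_bodies)
    _auto_pin_unattached(mesh, fixed_total, rigid_bodies)

    act = np.where(mesh.active)[0]
    sig_pre = _prestress_field(mesh, model, mode)
    sig_el = np.zeros_like(sig_pre)
    coords = mesh.nodes.copy()
    n = _DOF * mesh.n_nodes
    U = np.zeros(n)
    # track all three master dofs per rigid body (free ones accumulate
    # Newton increments, fixed ones their ramped imposed values)
    masters_total: list[dict[str, float]] = [
        {k: 0.0 for k in ("ux", "uy", "rot")} for rb in rigid_bodies]
    residual_rel = np.inf
    reactions = np.zeros(n)

    for k in range(1, n_steps + 1):
        lam = k / n_steps
        f_ext = lam * assemble_pressure_load(
            mesh, model, loadcase.pressure, loadcase.pressure_set, mode,
            coords_override=coords)
        for it in range(max_iter):
            K, f_int, Bs, Ds, dofs = _assemble_nl(mesh, model, mode, coords,
                                                  sig_el, sig_pre, lam)
            r = f_ext - f_int
            # constraint mismatches (nonzero only on the first iterate)
            fixed_it = {dof: lam * val - U[dof] for dof, val in fixed_total.items()}
            rbs_it = []
            fix_incs = []
            for rb, mt in zip(rigid_bodies, masters_total):
                um = np.array([mt["ux"], mt["uy"]])
                rot = mt["rot"]
                off = np.zeros((len(rb.nodes), 2))
                for j, node in enumerate(rb.nodes):
                    tgt = lam * (rb.offsets[j] if rb.offsets is not None else 0.0)
                    arm = mesh.nodes[int(node)] - rb.master_xy
                    exp = um + rot * np.array([-arm[1], arm[0]])
                    cur = U[2 * int(node):2 * int(node) + 2] - exp
                    off[j] = tgt - cur
                fix_it = {name: lam * v - mt[name] for name, v in rb.fix.items()}
                fix_incs.append(fix_it)
                rbs_it.append(replace(rb, offsets=off, fix=fix_it))
            T, g, master_cols = _build_transform(mesh, fixed_it, rbs_it, coords)
            scale = max(np.abs(f_ext).max(), np.abs(f_int).max(), 1e-30)
            residual_rel = float(np.abs(T.T @ r).max() / scale)
            gmax = np.abs(g).max() if len(g) else 0.0
            if residual_rel < tol and gmax < 1e-12 and it > 0:
                break
            Kq = (T.T @ K @ T).tocsc()
            rq = T.T @ (r - K @ g)
            dq = spsolve(Kq, rq)
            if not np.all(np.isfinite(dq)):
                raise RuntimeError("singular tangent system")
            dU = T @ dq + g
            # stress update with the operators of the configuration just solved
            due = dU[dofs]
            for i in range(len(Bs)):
                deps = np.einsum("eij,ej->ei", Bs[i], due)
                sig_el[:, i, :] += np.einsum("eij,ej->ei", Ds[i], deps)
            U += dU
            coords = coords + dU.reshape(-1, 2)
            for mt, cols_rb, fix_it in zip(masters_total, master_cols, fix_incs):
                for name, c in cols_rb.items():
                    mt[name] += float(dq[c])
                for name, v in fix_it.items():
                    mt[name] += v
            reactions = K @ dU - r
        else:
            import warnings
            warnings.warn(f"Newton did not reach tol={tol:g} at load step {k} "
                          f"(residual {residual_rel:.2e})", stacklevel=2)

    disp = U.reshape(-1, 2)
    # report the tracked (equilibrium) stress, rotated into local axes at
    # the final configuration
    pts, _ = quad8.GAUSS3
    stress = np.full((mesh.n_elements, len(pts), 4), np.nan)
    strain = np.full((mesh.n_elements, len(pts), 4), np.nan)
    conn = mesh.elements[act]
    ecoords = coords[conn]
    lidx, DlocL, _ = _layer_index(mesh, model)
    Sloc = np.stack([np.linalg.inv(D) for D in DlocL])[lidx[act]]
    for i, (xi, eta) in enumerate(pts):
        _, p, _, _, _ = _gp_batch(ecoords, xi, eta, mode)
        Tv = _rotation_voigt_batch(model.axes_batch(p))
        sig_tot = sig_el[:, i, :] + sig_pre[:, i, :]
        # stresses map with the inverse-transpose of the strain transform
        TinvT = np.transpose(_rotation_voigt_batch(
            np.transpose(model.axes_batch(p), (0, 2, 1))), (0, 2, 1))
        sl = np.einsum("eji,ej->ei", TinvT, sig_tot)
        stress[act, i] = sl
        strain[act, i] = np.einsum("eij,ej->ei", Sloc, sl)
    vm = np.full(mesh.n_elements, np.nan)
    vm[act] = np.nanmax(von_mises(stress[act]), axis=1)
    return SolutionField(mesh=mesh, mode=mode, displacements=disp,
                         stress_local=stress, von_mises=vm, strain_local=strain,
                         residual_rel=residual_rel, reactions=reactions,
                         master_dofs=dict(enumerate(masters_total)))


def _recover_stresses(mesh: Mesh, model: TissueModel, disp: np.ndarray, mode: str):
    act = np.where(mesh.active)[0]
    conn = mesh.elements[act]
    coords = mesh.nodes[conn]
    lidx, DlocL, eps0L = _layer_index(mesh, model)
    Dloc = DlocL[lidx[act]]
    eps0 = eps0L[lidx[act]]
    ue = np.empty((len(act), 16))
    ue[:, 0::2] = disp[conn, 0]
    ue[:, 1::2] = disp[conn, 1]

    pts, _ = quad8.GAUSS2
    ngp = len(pts)
    stress = np.full((mesh.n_elements, ngp, 4), np.nan)
    strain = np.full((mesh.n_elements, ngp, 4), np.nan)
    for k, (xi, eta) in enumerate(pts):
        B, p, _, _, _ = _gp_batch(coords, xi, eta, mode)
        eps_g = np.einsum("eij,ej->ei", B, ue)
        T = _rotation_voigt_batch(model.axes_batch(p))
        eps_l = np.einsum("eij,ej->ei", T, eps_g) + eps0
        strain[act, k] = eps_l
        stress[act, k] = np.einsum("eij,ej->ei", Dloc, eps_l)
    vm = np.full(mesh.n_elements, np.nan)
    vm[act] = np.nanmax(von_mises(stress[act]), axis=1)
    return stress, strain, vm
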