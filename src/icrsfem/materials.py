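"""Constitutive model: transversely isotropic elasticity in local corneal axes.

The stroma is stiffer along the collagen lamellae (circumferential, i.e.
tangent to the surface and out-of-plane hoop) than across them (radial,
through the thickness).  The plane of isotropy is therefore spanned by the
two circumferential directions and the symmetry axis is the local surface
normal.  The epithelium is a soft isotropic layer.

Voigt ordering used throughout, with engineering shear:

* local  axes: ``(cc, rr, hh, cr)``  — tangent, normal, hoop, in-plane shear
* global axes: ``(xx, yy, hh, xy)``

The hoop component is shared between the two frames (rotation about the
hoop axis only mixes the in-plane components), which lets one 4x4 operator
serve both the axisymmetric mode (hoop strain = u_x/x) and the plane-strain
mode (hoop strain identically zero).

Pre-strain is stored with its physical sign (anterior stroma: radial
compressive, circumferential tensile; posterior stroma: both tensile) and
enters the stress as existing elastic strain, sigma = D (eps + eps_pre), so
the reference (imaged) geometry already carries the tensile circumferential
pre-stress that the intraocular pressure maintains in vivo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CorneaGeometry

__all__ = [
    "MaterialSpec",
    "InitialStrainField",
    "TABLE1",
    "compliance_matrix",
    "stiffness_matrix",
    "local_material_axes",
    "rotation_voigt",
    "default_prestrain",
    "prestrain_load",
]

MMHG_TO_PA = 133.322


@dataclass(frozen=True)
class MaterialSpec:
    """Transversely isotropic elastic constants (Pa) plus density (kg/m^3).

    ``nu_rc`` is the Poisson ratio coupling the radial (symmetry) axis to the
    circumferential plane, defined by the radial-loading experiment
    (nu_rc = -eps_c/eps_r under sigma_r); the reciprocal ratio nu_cr is
    derived from symmetry of the compliance, nu_cr/E_c = nu_rc/E_r.
    ``nu_cc`` acts within the circumferential plane of isotropy.
    """

    name: str
    E_r: float
    E_c: float
    G_rc: float
    nu_cc: float
    nu_rc: float
    rho: float = 1062.0

    def __post_init__(self) -> None:
        if min(self.E_r, self.E_c, self.G_rc) <= 0.0:
            raise ValueError(f"{self.name}: all moduli must be positive")
        w = np.linalg.eigvalsh(self.stiffness4())
        if w[0] <= 0.0:
            raise ValueError(
                f"{self.name}: stiffness not positive definite "
                f"(smallest eigenvalue {w[0]:.3e} Pa)"
            )

    @classmethod
    def isotropic(cls, name: str, E: float, nu: float, rho: float = 1000.0) -> "MaterialSpec":
        return cls(name, E_r=E, E_c=E, G_rc=E / (2.0 * (1.0 + nu)),
                   nu_cc=nu, nu_rc=nu, rho=rho)

    @property
    def isotropic_flag(self) -> bool:
        return (
            np.isclose(self.E_r, self.E_c)
            and np.isclose(self.nu_rc, self.nu_cc)
            and np.isclose(self.G_rc, self.E_c / (2.0 * (1.0 + self.nu_cc)))
        )

    @property
    def nu_cr(self) -> float:
        """Reciprocal ratio, from compliance symmetry."""
        return self.nu_rc * self.E_c / self.E_r

    def compliance4(self) -> np.ndarray:
        """4x4 local compliance in order (cc, rr, hh, cr), 1/Pa."""
        S = np.zeros((4, 4))
        S[0, 0] = 1.0 / self.E_c
        S[1, 1] = 1.0 / self.E_r
        S[2, 2] = 1.0 / self.E_c
        S[0, 1] = S[1, 0] = -self.nu_rc / self.E_r
        S[1, 2] = S[2, 1] = -self.nu_rc / self.E_r
        S[0, 2] = S[2, 0] = -self.nu_cc / self.E_c
        S[3, 3] = 1.0 / self.G_rc
        return S

    def stiffness4(self) -> np.ndarray:
        # bypass __post_init__ recursion: compute directly from compliance
        return np.linalg.inv(self.compliance4())


#: Material constants of the three corneal layers (the published profile).
#: The posterior stroma's radial-circumferential Poisson ratio is positive
#: here; pass ``posterior_nu_rc=-0.34`` to ``TABLE1`` for the literal
#: (physically unmotivated) negative variant used in sensitivity checks.
def table1(posterior_nu_rc: float = 0.34) -> dict[str, MaterialSpec]:
    return {
        "epithelium": MaterialSpec.isotropic("epithelium", E=100.0, nu=0.4, rho=1000.0),
        "anterior_stroma": MaterialSpec(
            "anterior_stroma", E_r=500e3, E_c=1e6, G_rc=20e3,
            nu_cc=0.34, nu_rc=0.34, rho=1062.0,
        ),
        "posterior_stroma": MaterialSpec(
            "posterior_stroma", E_r=400e3, E_c=800e3, G_rc=16e3,
            nu_cc=0.34, nu_rc=posterior_nu_rc, rho=1062.0,
        ),
    }


TABLE1 = table1()


def compliance_matrix(spec: MaterialSpec, mode: str) -> np.ndarray:
    """Reduced compliance operator for the given 2D mode.

    ``axisymmetric``: the full 4x4 (cc, rr, hh, cr) compliance.
    ``plane_strain``: the 3x3 in-plane compliance with the hoop direction
    condensed out (hoop strain constrained to zero).
    """
    S4 = spec.compliance4()
    if mode == "axisymmetric":
        return S4
    if mode == "plane_strain":
        D4 = np.linalg.inv(S4)
        keep = [0, 1, 3]
        D3 = D4[np.ix_(keep, keep)]
        return np.linalg.inv(D3)
    raise ValueError(f"unknown mode {mode!r}")


def stiffness_matrix(spec: MaterialSpec, mode: str) -> np.ndarray:
    return np.linalg.inv(compliance_matrix(spec, mode))


def local_material_axes(point, geometry: CorneaGeometry) -> np.ndarray:
    """Rotation matrix ``a`` (rows = local axes in global components).

    Local axis 1 is circumferential (surface tangent, sense of increasing
    meridional angle), axis 2 radial (outward surface normal through the
    anterior arc center).  At the apex the radial axis coincides with the
    apex axis (y), the tangent with x.
    """
    p = np.asarray(point, dtype=float) - geometry.anterior_center
    r = np.linalg.norm(p)
    if r == 0.0:
        raise ValueError("point coincides with the anterior arc center")
    u = p / r                       # radial
    t = np.array([u[1], -u[0]])     # tangent; at apex t = +x
    return np.array([t, u])


def rotation_voigt(a: np.ndarray) -> np.ndarray:
    """Voigt strain-transformation T for the 4-vector (11, 22, hh, 12-eng).

    ``eps_local = T @ eps_global``; stresses map as ``sig_global = T.T @
    sig_local``; hence ``D_global = T.T @ D_local @ T``.  The hoop component
    is unaffected by the in-plane rotation.
    """
    (a11, a12), (a21, a22) = a
    return np.array([
        [a11 * a11, a12 * a12, 0.0, a11 * a12],
        [a21 * a21, a22 * a22, 0.0, a21 * a22],
        [0.0, 0.0, 1.0, 0.0],
        [2 * a11 * a21, 2 * a12 * a22, 0.0, a11 * a22 + a12 * a21],
    ])


@dataclass(frozen=True)
class InitialStrainField:
    """Layer-wise pre-strain with physical signs.

    Anterior stroma: radial compressive (<= 0), circumferential tensile
    (>= 0).  Posterior stroma: both tensile.  The circumferential value is
    applied to both circumferential directions (tangent and hoop).
    """

    layer: str
    eps_radial: float
    eps_circumferential: float

    def __post_init__(self) -> None:
        if self.layer == "anterior_stroma":
            if self.eps_radial > 0 or self.eps_circumferential < 0:
                raise ValueError(
                    "anterior stroma pre-strain must be radially compressive "
                    "and circumferentially tensile"
                )
        elif self.layer == "posterior_stroma":
            if self.eps_radial < 0 or self.eps_circumferential < 0:
                raise ValueError("posterior stroma pre-strain must be tensile")

    def local_vector(self) -> np.ndarray:
        """Pre-strain in local Voigt order (cc, rr, hh, cr)."""
        return np.array([
            self.eps_circumferential,
            self.eps_radial,
            self.eps_circumferential,
            0.0,
        ])


def default_prestrain() -> list[InitialStrainField]:
    """The published IOP-equilibrium pre-strain field (epithelium strain-free)."""
    return [
        InitialStrainField("anterior_stroma", eps_radial=-0.015, eps_circumferential=0.015),
        InitialStrainField("posterior_stroma", eps_radial=0.010, eps_circumferential=0.010),
    ]


def prestrain_load(fields, mesh, materials, mode: str = "axisymmetric") -> np.ndarray:
    """Consistent nodal load equivalent to the layer pre-strain.

    Delegates to the assembly routine: the load is the integral of
    ``B^T D eps_pre`` over each element, with the pre-strain rotated into
    global axes at every quadrature point.
    """
    from .solver import assemble_prestrain_load

    return assemble_prestrain_load(mesh, materials, fields, mode)
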