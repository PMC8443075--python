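"""8-node serendipity quadrilateral: shape functions and quadrature.

Node ordering: corners 1-4 counterclockwise, then midsides 5-8 between
(1,2), (2,3), (3,4), (4,1).  Reference coordinates (xi, eta) in [-1, 1]^2.
"""

from __future__ import annotations

import numpy as np

# reference coordinates of the 8 nodes
XI = np.array([-1.0, 1.0, 1.0, -1.0, 0.0, 1.0, 0.0, -1.0])
ETA = np.array([-1.0, -1.0, 1.0, 1.0, -1.0, 0.0, 1.0, 0.0])


def shape(xi: float, eta: float) -> np.ndarray:
    """Shape function values N_i(xi, eta), shape (8,)."""
    N = np.empty(8)
    for i in range(4):
        xi_i, eta_i = XI[i], ETA[i]
        N[i] = 0.25 * (1 + xi * xi_i) * (1 + eta * eta_i) * (xi * xi_i + eta * eta_i - 1)
    N[4] = 0.5 * (1 - xi * xi) * (1 - eta)
    N[5] = 0.5 * (1 + xi) * (1 - eta * eta)
    N[6] = 0.5 * (1 - xi * xi) * (1 + eta)
    N[7] = 0.5 * (1 - xi) * (1 - eta * eta)
    return N


def shape_grad(xi: float, eta: float) -> np.ndarray:
    """Reference-coordinate gradients dN_i/d(xi, eta), shape (8, 2)."""
    dN = np.empty((8, 2))
    for i in range(4):
        a, b = XI[i], ETA[i]
        dN[i, 0] = 0.25 * a * (1 + b * eta) * (2 * a * xi + b * eta)
        dN[i, 1] = 0.25 * b * (1 + a * xi) * (a * xi + 2 * b * eta)
    dN[4] = [-xi * (1 - eta), -0.5 * (1 - xi * xi)]
    dN[5] = [0.5 * (1 - eta * eta), -(1 + xi) * eta]
    dN[6] = [-xi * (1 + eta), 0.5 * (1 - xi * xi)]
    dN[7] = [-0.5 * (1 - eta * eta), -(1 - xi) * eta]
    return dN


def gauss_rule(n: int):
    """Tensor-product Gauss-Legendre points and weights on [-1, 1]^2."""
    p, w = np.polynomial.legendre.leggauss(n)
    pts, wts = [], []
    for i in range(n):
        for j in range(n):
            pts.append((p[i], p[j]))
            wts.append(w[i] * w[j])
    return np.array(pts), np.array(wts)


GAUSS3 = gauss_rule(3)   # stiffness integration
GAUSS2 = gauss_rule(2)   # stress recovery


def edge_gauss(n: int = 3):
    """1D Gauss rule for edge (pressure) integration."""
    return np.polynomial.legendre.leggauss(n)


# quadratic edge shape functions on [-1, 1]: nodes at -1, +1, 0
def edge_shape(s: float) -> np.ndarray:
    return np.array([0.5 * s * (s - 1), 0.5 * s * (s + 1), 1 - s * s])


def edge_shape_grad(s: float) -> np.ndarray:
    return np.array([s - 0.5, s + 0.5, -2 * s])


def jacobian(coords: np.ndarray, xi: float, eta: float):
    """Jacobian matrix, its determinant and cartesian shape gradients.

    ``coords`` is (8, 2) nodal coordinates; returns (J, detJ, dN_xy) where
    dN_xy is (8, 2) gradients with respect to (x, y).
    """
    dN = shape_grad(xi, eta)
    J = dN.T @ coords              # (2,2): d(x,y)/d(xi,eta) transposed
    detJ = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    dN_xy = dN @ np.linalg.inv(J).T
    return J, detJ, dN_xy


def min_jacobian(coords: np.ndarray, rule=GAUSS3) -> float:
    """Smallest Jacobian determinant over the quadrature points."""
    pts, _ = rule
    return min(jacobian(coords, xi, eta)[1] for xi, eta in pts)
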