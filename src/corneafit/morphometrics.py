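"""Canonical ellipsoid form and clinical morpho-geometric parameters.

A fitted quadric that is a real ellipsoid can be rotated/translated into
x'^2/a^2 + y'^2/b^2 + z'^2/c^2 = 1. With c the semi-axis along the optical
(z) axis, the clinically used parameters are the apical radii of curvature

    Rx = a^2 / c,   Ry = b^2 / c        (mm)

and the asphericities (conic constants)

    Qx = (a/c)^2 - 1,   Qy = (b/c)^2 - 1.

Healthy corneas are prolate (c > a, b), giving Q ~ -0.3; Q drifts toward -1
in advanced keratoconus. A fit whose second-order terms vanish or whose
eigenvalue signature is not ellipsoidal is a quadric-order failure (fq = 1):
a mathematically valid minimiser that is not the accepted model of a corneal
cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NotAnEllipsoidError
from .quadric import QuadricCoefficients, coefficients_from_blocks


@dataclass(frozen=True)
class CanonicalEllipsoid:
    """Semi-axes (a, b, c) mm with c along the optical axis, plus pose."""

    semi_axes: tuple[float, float, float]
    rotation: np.ndarray    # 3x3, columns = canonical x, y, z axes in data frame
    center: np.ndarray      # mm

    def to_coefficients(self) -> QuadricCoefficients:
        """Implicit quadric of this ellipsoid (unit-norm, canonical sign)."""
        a, b, c = self.semi_axes
        D = np.diag([1.0 / a**2, 1.0 / b**2, 1.0 / c**2])
        R = self.rotation
        A = R @ D @ R.T
        t = np.asarray(self.center, dtype=float)
        bb = -2.0 * A @ t
        k = float(t @ A @ t) - 1.0
        return QuadricCoefficients(coefficients_from_blocks(A, bb, k))


@dataclass(frozen=True)
class MorphoGeometry:
    """Apical curvature radii (mm) and asphericities along x and y."""

    rx: float
    ry: float
    qx: float
    qy: float

    def to_dict(self) -> dict:
        return {"rx": self.rx, "ry": self.ry, "qx": self.qx, "qy": self.qy}


def _ellipsoid_parts(c: QuadricCoefficients):
    """(eigvals, eigvecs, center, centered constant) or NotAnEllipsoidError."""
    A = c.quadratic_form()
    b = c.linear_part()
    w, V = np.linalg.eigh(A)
    if np.any(w == 0.0) or not (np.all(w > 0) or np.all(w < 0)):
        raise NotAnEllipsoidError("quadratic form is not definite")
    x0 = np.linalg.solve(A, -0.5 * b)
    k_c = c.constant() + 0.5 * float(b @ x0)   # Q(x0 + u) = u^T A u + k_c
    if np.any(-k_c / w <= 0.0):
        raise NotAnEllipsoidError("no real ellipsoid (constant has wrong sign)")
    return w, V, x0, k_c


def to_canonical_ellipsoid(c: QuadricCoefficients) -> CanonicalEllipsoid:
    """Eigen-decompose the quadric into canonical ellipsoid form.

    The canonical c-axis is the principal direction with the largest |z|
    component (the optical axis); of the remaining two, x gets the larger |x|
    component. The rotation is assembled right-handed with non-negative
    leading components, making the pose deterministic.
    """
    w, V, x0, k_c = _ellipsoid_parts(c)
    semi = np.sqrt(-k_c / w)

    iz = int(np.argmax(np.abs(V[2, :])))
    rest = [i for i in range(3) if i != iz]
    ix = rest[int(np.argmax(np.abs(V[0, rest])))]
    iy = [i for i in rest if i != ix][0]

    ex, ey, ez = V[:, ix].copy(), V[:, iy].copy(), V[:, iz].copy()
    if ex[0] < 0:
        ex = -ex
    if ez[2] < 0:
        ez = -ez
    ey = np.cross(ez, ex)  # right-handed, det +1
    R = np.column_stack([ex, ey, ez])
    return CanonicalEllipsoid(
        semi_axes=(float(semi[ix]), float(semi[iy]), float(semi[iz])),
        rotation=R, center=x0)


def morpho_parameters(e: CanonicalEllipsoid) -> MorphoGeometry:
    """Rx = a^2/c, Ry = b^2/c, Qx = (a/c)^2 - 1, Qy = (b/c)^2 - 1."""
    a, b, c = e.semi_axes
    return MorphoGeometry(rx=a * a / c, ry=b * b / c,
                          qx=(a / c) ** 2 - 1.0, qy=(b / c) ** 2 - 1.0)


def check_quadric_order(c: QuadricCoefficients, tol: float = 1e-6) -> int:
    """Quadric-order failure flag fq: 0 for a valid ellipsoid, else 1.

    fq = 1 when the second-order coefficient block has norm below tol (the
    surface degenerated toward a plane) or when the eigenvalue signature is
    not ellipsoidal (paraboloid, hyperboloid, imaginary ellipsoid).
    """
    if c.second_order_norm() < tol:
        return 1
    try:
        _ellipsoid_parts(c)
    except NotAnEllipsoidError:
        return 1
    return 0
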