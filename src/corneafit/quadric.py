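"""The implicit quadric surface model and its goodness-of-fit measures.

The corneal surface is modelled as the zero set of a general second-order
polynomial in three variables,

    Q(x, y, z) = a11 x^2 + a12 xy + a13 xz + a10 x
               + a22 y^2 + a23 yz + a20 y
               + a33 z^2 + a30 z + a00 = 0,

with coordinates in mm. The ten coefficients are stored in the fixed order
(a11, a12, a13, a10, a22, a23, a20, a33, a30, a00) and kept on the unit
Euclidean sphere: Q is homogeneous of degree one in its coefficients, so the
all-zero vector would be a trivial global minimiser of any algebraic residual
and a scale must be fixed. The sign is canonicalised so that a33 >= 0 (first
nonzero second-order coefficient positive if a33 = 0).

Two distinct error measures appear throughout the package and must not be
conflated:

* the *algebraic fitness* (1/N) sum Q(P_s)^2 -- the objective every fitter
  minimises;
* the *elevation MSE* (1/N') sum (z_hat - z)^2 in mm^2 -- the reported
  goodness of fit, where z_hat is the quadric's elevation at the node's
  (x, y), solved from the quadratic in z and taking the root nearer the
  measured elevation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import EmptyCloudError, SurfaceMissError
from .grid import PointCloud

#: index of each coefficient in the canonical storage order
COEFF_NAMES = ("a11", "a12", "a13", "a10", "a22", "a23", "a20", "a33", "a30", "a00")
#: indices of the second-order block {a11, a12, a13, a22, a23, a33}
SECOND_ORDER_IDX = (0, 1, 2, 4, 5, 7)
_A33 = 7

# |a33| below this (on unit-norm coefficients) is treated as a linear z-equation
_Z_QUAD_TINY = 1e-12


def normalize_coefficients(vec: np.ndarray) -> np.ndarray:
    """Project a raw 10-vector to the unit sphere with canonical sign."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (10,):
        raise ValueError("coefficient vector must have exactly 10 entries")
    n = np.linalg.norm(vec)
    if n == 0.0:
        raise ValueError("the all-zero coefficient vector is not a valid quadric")
    vec = vec / n
    if vec[_A33] != 0.0:
        if vec[_A33] < 0.0:
            vec = -vec
    else:
        for k in SECOND_ORDER_IDX:
            if vec[k] != 0.0:
                if vec[k] < 0.0:
                    vec = -vec
                break
    return vec


@dataclass(frozen=True)
class QuadricCoefficients:
    """Unit-norm, sign-canonical coefficients of the implicit quadric."""

    array: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "array", normalize_coefficients(self.array))

    @classmethod
    def from_values(cls, a11, a12, a13, a10, a22, a23, a20, a33, a30, a00):
        return cls(np.array([a11, a12, a13, a10, a22, a23, a20, a33, a30, a00],
                            dtype=float))

    def __getattr__(self, name):
        if name in COEFF_NAMES:
            return float(self.array[COEFF_NAMES.index(name)])
        raise AttributeError(name)

    def quadratic_form(self) -> np.ndarray:
        """Symmetric 3x3 matrix A with x^T A x equal to the second-order part."""
        a11, a12, a13, _, a22, a23, _, a33, _, _ = self.array
        return np.array([[a11, a12 / 2, a13 / 2],
                         [a12 / 2, a22, a23 / 2],
                         [a13 / 2, a23 / 2, a33]])

    def linear_part(self) -> np.ndarray:
        return self.array[[3, 6, 8]].copy()

    def constant(self) -> float:
        return float(self.array[9])

    def second_order_norm(self) -> float:
        return float(np.linalg.norm(self.array[list(SECOND_ORDER_IDX)]))

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in zip(COEFF_NAMES, self.array)}

    @classmethod
    def from_dict(cls, d: dict) -> "QuadricCoefficients":
        return cls(np.array([d[k] for k in COEFF_NAMES], dtype=float))


def coefficients_from_blocks(A: np.ndarray, b: np.ndarray, k: float,
                             normalize: bool = True) -> np.ndarray:
    """Assemble the 10-vector from x^T A x + b^T x + k (A symmetric)."""
    vec = np.array([A[0, 0], 2 * A[0, 1], 2 * A[0, 2], b[0],
                    A[1, 1], 2 * A[1, 2], b[1],
                    A[2, 2], b[2], k])
    return normalize_coefficients(vec) if normalize else vec


def transform_to_original(vec: np.ndarray, center: np.ndarray, scale: float) -> np.ndarray:
    """Map coefficients fitted in preconditioned coordinates x = (X - t)/s back to X.

    Returns a unit-norm canonical 10-vector in the original mm frame.
    """
    q = QuadricCoefficients(vec)
    A, b, k = q.quadratic_form(), q.linear_part(), q.constant()
    t = np.asarray(center, dtype=float)
    s = float(scale)
    A2 = A / s**2
    b2 = b / s - 2.0 * (A @ t) / s**2
    k2 = float(t @ A @ t) / s**2 - float(b @ t) / s + k
    return coefficients_from_blocks(A2, b2, k2)


def design_matrix(points: np.ndarray) -> np.ndarray:
    """N x 10 matrix of quadric monomials (x^2, xy, xz, x, y^2, yz, y, z^2, z, 1)."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    x, y, z = p[:, 0], p[:, 1], p[:, 2]
    one = np.ones_like(x)
    return np.column_stack([x * x, x * y, x * z, x, y * y, y * z, y, z * z, z, one])


def evaluate_quadric(c: QuadricCoefficients, points: np.ndarray) -> np.ndarray:
    """Q(x, y, z) at one point (3-vector) or many (N x 3); scalar for one."""
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    vals = design_matrix(p) @ c.array
    return float(vals[0]) if single else vals


def algebraic_fitness(c: QuadricCoefficients, cloud: PointCloud | np.ndarray) -> float:
    """Mean squared algebraic residual (1/N) sum_s Q(P_s)^2 -- the fit objective."""
    pts = cloud.points if isinstance(cloud, PointCloud) else np.atleast_2d(cloud)
    if len(pts) == 0:
        raise EmptyCloudError("cannot evaluate fitness on an empty cloud")
    r = design_matrix(pts) @ c.array
    return float(np.mean(r * r))


def solve_elevation(c: QuadricCoefficients, x, y, z_ref) -> np.ndarray:
    """Elevation(s) z with Q(x, y, z) = 0, taking the root nearer z_ref.

    Solves a33 z^2 + (a13 x + a23 y + a30) z + (a11 x^2 + a12 xy + a10 x +
    a22 y^2 + a20 y + a00) = 0 per node; degrades to the linear case when
    a33 ~ 0. Nodes with no real root are returned as NaN.

    Accepts scalars or equal-length arrays; returns an array (0-d for scalars).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z_ref = np.broadcast_to(np.asarray(z_ref, dtype=float), x.shape)
    a11, a12, a13, a10, a22, a23, a20, a33, a30, a00 = c.array

    B = a13 * x + a23 * y + a30
    C = a11 * x * x + a12 * x * y + a10 * x + a22 * y * y + a20 * y + a00

    out = np.full(x.shape, np.nan, dtype=float)
    if abs(a33) > _Z_QUAD_TINY:
        disc = B * B - 4.0 * a33 * C
        ok = disc >= 0.0
        sq = np.sqrt(np.where(ok, disc, 0.0))
        z1 = (-B + sq) / (2.0 * a33)
        z2 = (-B - sq) / (2.0 * a33)
        pick1 = np.abs(z1 - z_ref) <= np.abs(z2 - z_ref)
        out = np.where(ok, np.where(pick1, z1, z2), np.nan)
    else:
        lin = np.abs(B) > _Z_QUAD_TINY
        out = np.where(lin, -C / np.where(lin, B, 1.0), np.nan)
    return out


def elevation_mse(c: QuadricCoefficients, cloud: PointCloud) -> tuple[float, int]:
    """Elevation mean squared error (mm^2) and the count of unresolved nodes.

    Re-evaluates the fitted surface at the nodes where elevations were
    collected (root nearer the measured elevation) and averages the squared
    differences over the nodes with a real root. Raises SurfaceMissError if
    the surface misses the entire cloud.
    """
    pts = cloud.points
    if len(pts) == 0:
        raise EmptyCloudError("cannot evaluate MSE on an empty cloud")
    z_hat = solve_elevation(c, pts[:, 0], pts[:, 1], z_ref=pts[:, 2])
    ok = np.isfinite(z_hat)
    n_ok = int(ok.sum())
    if n_ok == 0:
        raise SurfaceMissError("fitted quadric has no real elevation at any node")
    d = z_hat[ok] - pts[ok, 2]
    return float(np.mean(d * d)), len(pts) - n_ok


@dataclass(frozen=True)
class Preconditioner:
    """Centering/scaling applied to clouds before fitting.

    Quadric scatter matrices in raw mm units are badly conditioned; fitting is
    done with the centroid at the origin and the maximum radius scaled to 1,
    and coefficients are mapped back analytically afterwards.
    """

    center: np.ndarray
    scale: float

    @classmethod
    def fit(cls, points: np.ndarray) -> "Preconditioner":
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        t = pts.mean(axis=0)
        s = float(np.max(np.linalg.norm(pts - t, axis=1)))
        if s == 0.0:
            s = 1.0
        return cls(center=t, scale=s)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(points, dtype=float)) - self.center) / self.scale

    def restore_coefficients(self, vec: np.ndarray) -> QuadricCoefficients:
        return QuadricCoefficients(transform_to_original(vec, self.center, self.scale))


@dataclass
class FitResult:
    """Outcome of one surface fit, whatever the method."""

    coefficients: QuadricCoefficients
    mse: float                       # elevation MSE, mm^2
    n_points: int
    method_tag: str                  # GA | LSQ | SQP | DIRECT
    generations: int = 0             # generations (GA) or iterations (others)
    converged: bool = True
    fq: int = 0                      # 1 = quadric-order failure
    unresolved_nodes: int = 0
    seed: Optional[int] = None
    fitness: float = field(default=float("nan"))  # final algebraic fitness

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.to_dict(),
            "mse": self.mse,
            "n_points": self.n_points,
            "method_tag": self.method_tag,
            "generations": self.generations,
            "converged": bool(self.converged),
            "fq": int(self.fq),
            "unresolved_nodes": int(self.unresolved_nodes),
            "seed": self.seed,
            "fitness": self.fitness,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(coefficients=QuadricCoefficients.from_dict(d["coefficients"]),
                   mse=d["mse"], n_points=d["n_points"], method_tag=d["method_tag"],
                   generations=d.get("generations", 0),
                   converged=d.get("converged", True), fq=d.get("fq", 0),
                   unresolved_nodes=d.get("unresolved_nodes", 0),
                   seed=d.get("seed"), fitness=d.get("fitness", float("nan")))
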