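"""Classical quadric fitters: direct linear (SVD), trust-region least squares, SQP.

``fit_direct_linear`` is the closed-form reference: the unit-norm minimiser of
the algebraic residual is the right singular vector of the monomial design
matrix with the smallest singular value. It is deterministic and globally
optimal for the norm-constrained problem, which makes it the oracle the other
fitters are measured against.

``fit_lsq_trra`` is weighted least squares solved iteratively with scipy's
trust-region reflective algorithm, from a neutral sphere initialisation
(radius 7.8 mm, a typical anterior cornea). ``fit_sqp`` minimises the same
objective under the unit-norm equality constraint with a sequential quadratic
programming solver (SLSQP); as a local method it may land in poor minima on
deformed or incomplete clouds, which is reported (non-convergence / fq flags),
not patched.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import optimize

from .errors import DegenerateCloudError, InsufficientDataError
from .grid import PointCloud
from .morphometrics import check_quadric_order
from .quadric import (FitResult, Preconditioner, QuadricCoefficients,
                      algebraic_fitness, design_matrix, elevation_mse,
                      normalize_coefficients)

_MIN_POINTS = 10
_RANK_RTOL = 1e-10
_DEFAULT_SPHERE_RADIUS_MM = 7.8


def _require_points(cloud: PointCloud) -> np.ndarray:
    pts = cloud.points
    if len(pts) < _MIN_POINTS:
        raise InsufficientDataError(
            f"need at least {_MIN_POINTS} points, got {len(pts)}")
    return pts


def _result(vec_pre: np.ndarray, pre: Preconditioner, cloud: PointCloud,
            tag: str, iterations: int, converged: bool) -> FitResult:
    coeffs = pre.restore_coefficients(vec_pre)
    mse, unresolved = elevation_mse(coeffs, cloud)
    return FitResult(coefficients=coeffs, mse=mse, n_points=len(cloud.points),
                     method_tag=tag, generations=iterations, converged=converged,
                     fq=check_quadric_order(coeffs), unresolved_nodes=unresolved,
                     fitness=algebraic_fitness(coeffs, cloud))


def fit_direct_linear(cloud: PointCloud) -> FitResult:
    """Exact unit-norm minimiser of the algebraic residual (SVD null vector).

    Raises DegenerateCloudError when the cloud leaves a 2+-dimensional
    near-null space (e.g. coplanar points), i.e. the minimiser is not unique.
    """
    pts = _require_points(cloud)
    pre = Preconditioner.fit(pts)
    M = design_matrix(pre.apply(pts))
    _, sv, Vt = np.linalg.svd(M, full_matrices=False)
    # the smallest singular value may legitimately be ~0 (noiseless data);
    # degeneracy means the *second* smallest also vanishes
    if sv[-2] <= _RANK_RTOL * sv[0]:
        raise DegenerateCloudError(
            "design matrix rank < 10: quadric is not uniquely determined")
    return _result(Vt[-1], pre, cloud, "DIRECT", iterations=0, converged=True)


def _sphere_init(scaled_points: np.ndarray, pre: Preconditioner) -> np.ndarray:
    """Unit-norm coefficients of a 7.8 mm sphere tangent to the cloud apex."""
    r = _DEFAULT_SPHERE_RADIUS_MM / pre.scale
    z0 = float(scaled_points[:, 2].max()) - r
    vec = np.array([1.0, 0, 0, 0, 1.0, 0, 0, 1.0, -2.0 * z0, z0 * z0 - r * r])
    return normalize_coefficients(vec)


def fit_lsq_trra(cloud: PointCloud, weights: Optional[np.ndarray] = None,
                 constrain_a11: bool = False) -> FitResult:
    """Weighted least squares via the trust-region reflective algorithm.

    With ``constrain_a11`` the trivial solution is excluded by pinning
    a11 = 1 (9 free coefficients); otherwise the residuals are divided by the
    coefficient norm, which makes the objective scale-invariant (the continuous
    analogue of unit-norm projection). Optional per-point weights model the
    higher uncertainty of peripheral samples.
    """
    pts = _require_points(cloud)
    if weights is None:
        w = np.ones(len(pts))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(pts),) or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative, not all zero")
    sw = np.sqrt(w)

    pre = Preconditioner.fit(pts)
    scaled = pre.apply(pts)
    M = design_matrix(scaled)
    sv = np.linalg.svd(M, compute_uv=False)
    if sv[-2] <= _RANK_RTOL * sv[0]:
        raise DegenerateCloudError(
            "design matrix rank < 10: quadric is not uniquely determined")
    x0 = _sphere_init(scaled, pre)

    if constrain_a11:
        def residuals(p):
            c = np.concatenate([[1.0], p])
            return sw * (M @ c)
        sol = optimize.least_squares(residuals, x0[1:] / x0[0], method="trf",
                                     xtol=1e-15, ftol=1e-15, gtol=1e-15)
        vec = np.concatenate([[1.0], sol.x])
    else:
        def residuals(c):
            return sw * (M @ c) / np.linalg.norm(c)
        sol = optimize.least_squares(residuals, x0, method="trf",
                                     xtol=1e-15, ftol=1e-15, gtol=1e-15)
        vec = sol.x
    return _result(normalize_coefficients(vec), pre, cloud, "LSQ",
                   iterations=int(sol.nfev), converged=bool(sol.success))


def radial_weights(cloud: PointCloud) -> np.ndarray:
    """Down-weight peripheral samples: w = 1 / (1 + (r/r_max)^2)."""
    r = np.hypot(cloud.points[:, 0], cloud.points[:, 1])
    rmax = r.max() if r.max() > 0 else 1.0
    return 1.0 / (1.0 + (r / rmax) ** 2)


def fit_sqp(cloud: PointCloud,
            init: Optional[QuadricCoefficients] = None) -> FitResult:
    """Algebraic fit under the unit-norm equality constraint via SLSQP.

    Solver failure is surfaced as converged=False on the returned result,
    never as an exception; local-minimum artefacts on deformed clouds are
    expected behaviour of this baseline.
    """
    pts = _require_points(cloud)
    pre = Preconditioner.fit(pts)
    scaled = pre.apply(pts)
    M = design_matrix(scaled)
    S = (M.T @ M) / len(M)
    x0 = init.array if init is not None else _sphere_init(scaled, pre)

    def objective(c):
        return float(c @ S @ c)

    def grad(c):
        return 2.0 * (S @ c)

    cons = {"type": "eq",
            "fun": lambda c: float(c @ c) - 1.0,
            "jac": lambda c: 2.0 * c}
    sol = optimize.minimize(objective, x0, jac=grad, method="SLSQP",
                            constraints=[cons],
                            options={"maxiter": 500, "ftol": 1e-18})
    vec = sol.x
    if not np.all(np.isfinite(vec)) or np.linalg.norm(vec) == 0.0:
        vec = x0
    return _result(normalize_coefficients(vec), pre, cloud, "SQP",
                   iterations=int(sol.nit), converged=bool(sol.success))
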