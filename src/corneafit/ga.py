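"""Elitist real-coded genetic algorithm for the quadric coefficients.

The fitter minimises the mean squared algebraic residual of the implicit
quadric over the point cloud (plus a penalty for surfaces that have no real
elevation above data nodes), evolving unit-norm 10-gene vectors in
preconditioned (centred, radius-scaled) coordinates. The configuration
mirrors the settings that work well for this problem class: a population of
100 individuals per variable (1000 total), crossover rate 0.8, cloning
(survival/elite) rate 0.2, mutation rate 0, and a function tolerance of
1e-50 paired with a stall window so runs terminate.

Operator design. Selection is size-2 tournament; crossover is blend (BLX-
alpha, alpha = 0.5). Axis-aligned BLX with zero mutation collapses the
population before it reaches the global valley of this strongly anisotropic
quadratic landscape, so the default crossover works in the population's
principal-axes frame (rotation-invariant blend), with two safeguards:

* a *rank guard* flooring each principal direction's blend interval at a
  small fraction of the parent distance, so search directions that drift to
  zero variance can be regenerated;
* a *stall burst* that temporarily widens the blend intervals when the best
  fitness stops improving, letting a collapsed population re-expand around
  its elites.

Two independent restarts are pooled and polished by a short refinement phase
whose fitness is the exact mean squared residual in the original millimetre
frame -- the quantity reported and compared across methods. Axis-aligned
blend remains available via ``crossover="blend_alpha"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from typing import Optional

import numpy as np
import yaml

from .errors import InsufficientDataError
from .grid import PointCloud
from .morphometrics import check_quadric_order
from .quadric import (FitResult, Preconditioner, algebraic_fitness,
                      design_matrix, elevation_mse)

_MIN_POINTS = 10


@dataclass
class GAConfig:
    """Genetic-algorithm settings; the defaults are the study configuration."""

    pop_per_variable: int = 100
    n_variables: int = 10
    crossover_rate: float = 0.8
    survival_rate: float = 0.2
    mutation_rate: float = 0.0
    function_tolerance: float = 1e-50
    constraint_tolerance: float = 1e-50
    max_generations: int = 500
    stall_generations: int = 50
    gene_bounds: tuple[float, float] = (-1.0, 1.0)
    seed: Optional[int] = None
    selection: str = "tournament_k2"
    crossover: str = "blend_alpha_rotated"
    blend_alpha: float = 0.5
    # exploration safeguards (see module docstring)
    rank_guard: float = 1e-2
    stall_boost: float = 1.5
    stall_boost_window: int = 40
    stall_boost_ratio: float = 0.05
    restarts: int = 2
    # exact-residual refinement phase
    refine_generations: int = 120
    refine_population: int = 250
    # unresolved-node penalty subsample size
    penalty_nodes: int = 128

    def __post_init__(self) -> None:
        if self.crossover_rate + self.survival_rate > 1.0 + 1e-12:
            raise ValueError("crossover_rate + survival_rate must be <= 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.selection != "tournament_k2" and not self.selection.startswith("tournament_k"):
            raise ValueError(f"unknown selection {self.selection!r}")
        if self.crossover not in ("blend_alpha", "blend_alpha_rotated"):
            raise ValueError(f"unknown crossover {self.crossover!r}")

    @property
    def population_size(self) -> int:
        return self.pop_per_variable * self.n_variables

    @property
    def tournament_size(self) -> int:
        return int(self.selection.removeprefix("tournament_k"))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gene_bounds"] = list(self.gene_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GAConfig":
        d = dict(d)
        if "gene_bounds" in d:
            d["gene_bounds"] = tuple(d["gene_bounds"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GAConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def stopping_check(history, config: GAConfig) -> tuple[bool, Optional[str]]:
    """Whether the run should stop: tolerance/stall or generation cap.

    history is the best fitness per generation so far. Stops with reason
    "tolerance" when the improvement over the last stall_generations is below
    function_tolerance, or "max_generations" at the cap.
    """
    n = len(history)
    if n == 0:
        return False, None
    if n > config.stall_generations:
        improvement = history[-1 - config.stall_generations] - history[-1]
        if improvement < config.function_tolerance:
            return True, "tolerance"
    if n >= config.max_generations:
        return True, "max_generations"
    return False, None


def _normalize_rows(C: np.ndarray) -> np.ndarray:
    return C / np.linalg.norm(C, axis=1, keepdims=True)


def blend_crossover(pa: np.ndarray, pb: np.ndarray, alpha: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Axis-aligned BLX-alpha: per-gene uniform in [lo - a*d, hi + a*d].

    With alpha = 0 every offspring gene lies inside the parents' per-gene
    interval. Operates on raw gene vectors (no norm projection).
    """
    lo, hi = np.minimum(pa, pb), np.maximum(pa, pb)
    d = hi - lo
    return rng.uniform(lo - alpha * d, hi + alpha * d)


def _tournament(fitnesses: np.ndarray, n_winners: int, k: int, rng) -> np.ndarray:
    cand = rng.integers(0, len(fitnesses), size=(n_winners, k))
    return cand[np.arange(n_winners), np.argmin(fitnesses[cand], axis=1)]


def evolve_generation(population: np.ndarray, fitnesses: np.ndarray,
                      config: GAConfig, rng: np.random.Generator,
                      spread_boost: float = 1.0) -> np.ndarray:
    """One generation: elites + blend-crossover offspring + tournament clones.

    The population is an (P, 10) array of unit-norm gene vectors. The top
    ceil(survival_rate * P) individuals are cloned unchanged (elitism), then
    ceil(crossover_rate * P) offspring are produced by blend crossover of
    tournament-selected parents, and any remainder is filled with tournament-
    selected clones. Every output row is re-projected to unit norm.
    """
    P = len(population)
    if fitnesses.shape != (P,):
        raise ValueError("fitnesses must match population size")
    n_el = min(P, math.ceil(config.survival_rate * P))
    n_cx = min(P - n_el, math.ceil(config.crossover_rate * P))
    n_cl = P - n_el - n_cx

    order = np.argsort(fitnesses, kind="stable")
    elites = population[order[:n_el]]

    parts = [elites]
    k = config.tournament_size
    if n_cx > 0:
        win = _tournament(fitnesses, 2 * n_cx, k, rng)
        pa, pb = population[win[:n_cx]], population[win[n_cx:]]
        alpha = config.blend_alpha
        if config.crossover == "blend_alpha_rotated":
            mu = population.mean(axis=0)
            _, _, Vt = np.linalg.svd(population - mu, full_matrices=False)
            E = Vt.T
            qa, qb = pa @ E, pb @ E
            lo, hi = np.minimum(qa, qb), np.maximum(qa, qb)
            d = hi - lo
            pair_dist = np.linalg.norm(qa - qb, axis=1, keepdims=True)
            d = np.maximum(d, config.rank_guard * pair_dist) * spread_boost
            off = rng.uniform(lo - alpha * d, hi + alpha * d) @ E.T
        else:
            if spread_boost != 1.0:
                mid = 0.5 * (pa + pb)
                pa = mid + (pa - mid) * spread_boost
                pb = mid + (pb - mid) * spread_boost
            off = blend_crossover(pa, pb, alpha, rng)
        if config.mutation_rate > 0.0:
            hit = rng.random(n_cx) < config.mutation_rate
            if np.any(hit):
                scale = population.std(axis=0, keepdims=True)
                off[hit] += rng.standard_normal((int(hit.sum()), off.shape[1])) * scale
        # only offspring need re-projection: elites and clones are untouched
        # copies of already unit-norm rows (renormalising them would perturb
        # the elite fitness at the ulp level and break strict elitism)
        parts.append(_normalize_rows(off))
    if n_cl > 0:
        parts.append(population[_tournament(fitnesses, n_cl, k, rng)])

    return np.vstack(parts)


class _PenaltyEvaluator:
    """Additive fitness penalty for nodes where a candidate has no real z.

    The elevation MSE presumes a real root above every node; candidates that
    miss part of the data column are steered away by adding
    (fraction of unresolved nodes) * (2 * z_range)^2 to their fitness. The
    fraction is measured on a fixed stride subsample of the nodes for speed;
    it vanishes near any surface that covers the cloud, so optima of the
    penalised and plain objectives coincide there.
    """

    def __init__(self, points: np.ndarray, max_nodes: int):
        stride = max(1, len(points) // max(1, max_nodes))
        sub = points[::stride]
        x, y = sub[:, 0], sub[:, 1]
        one = np.ones_like(x)
        self._lin = np.column_stack([x, y, one])                      # a13, a23, a30
        self._quad = np.column_stack([x * x, x * y, x, y * y, y, one])  # a11,a12,a10,a22,a20,a00
        z = points[:, 2]
        self._weight = (2.0 * float(z.max() - z.min())) ** 2

    def __call__(self, C: np.ndarray) -> np.ndarray:
        B = self._lin @ C[:, [2, 5, 8]].T        # (n_sub, P)
        Cq = self._quad @ C[:, [0, 1, 3, 4, 6, 9]].T
        a33 = C[:, 7][None, :]
        disc = B * B - 4.0 * a33 * Cq
        tiny = 1e-12
        unresolved = (disc < 0.0) | ((np.abs(a33) < tiny) & (np.abs(B) < tiny))
        return unresolved.mean(axis=0) * self._weight


def _transform_matrix(center: np.ndarray, scale: float) -> np.ndarray:
    """10x10 linear map from preconditioned to original-frame coefficients."""
    L = np.empty((10, 10))
    for k in range(10):
        e = np.zeros(10)
        e[k] = 1.0
        # transform_to_original is linear before normalization; recover columns
        q = _raw_transform(e, center, scale)
        L[:, k] = q
    return L


def _raw_transform(vec: np.ndarray, center: np.ndarray, scale: float) -> np.ndarray:
    a11, a12, a13, a10, a22, a23, a20, a33, a30, a00 = vec
    A = np.array([[a11, a12 / 2, a13 / 2], [a12 / 2, a22, a23 / 2],
                  [a13 / 2, a23 / 2, a33]])
    b = np.array([a10, a20, a30])
    t, s = np.asarray(center, float), float(scale)
    A2 = A / s**2
    b2 = b / s - 2.0 * (A @ t) / s**2
    k2 = float(t @ A @ t) / s**2 - float(b @ t) / s + a00
    return np.array([A2[0, 0], 2 * A2[0, 1], 2 * A2[0, 2], b2[0],
                     A2[1, 1], 2 * A2[1, 2], b2[1], A2[2, 2], b2[2], k2])


def _init_population(config: GAConfig, rng) -> np.ndarray:
    lo, hi = config.gene_bounds
    C = rng.uniform(lo, hi, size=(config.population_size, config.n_variables))
    return _normalize_rows(C)


def _coarse_phase(Rq: np.ndarray, n_points: int, penalty: _PenaltyEvaluator,
                  config: GAConfig, rng) -> tuple[np.ndarray, np.ndarray, int, str]:
    """One restart of the coarse GA; returns (population, fitness, gens, reason)."""
    C = _init_population(config, rng)
    history: list[float] = []
    reason = "max_generations"
    for g in range(config.max_generations):
        Y = C @ Rq.T
        f = (Y * Y).sum(axis=1) / n_points + penalty(C)
        fb = float(f.min())
        history.append(fb)
        stop, why = stopping_check(history, config)
        if stop:
            reason = why
            break
        # step-size control: while the best fitness improves slowly, widen the
        # blend intervals every generation; the population spread then
        # self-regulates to the scale of the remaining distance to the optimum
        # instead of collapsing prematurely (elites keep the boost harmless
        # once truly converged)
        boost = 1.0
        if (g >= config.stall_boost_window
                and history[-config.stall_boost_window] > 0
                and fb > config.stall_boost_ratio * history[-config.stall_boost_window]):
            boost = config.stall_boost
        C = evolve_generation(C, f, config, rng, spread_boost=boost)
    Y = C @ Rq.T
    f = (Y * Y).sum(axis=1) / n_points + penalty(C)
    return C, f, len(history), reason


def _refine_phase(C0: np.ndarray, f0: np.ndarray, M_orig: np.ndarray,
                  L: np.ndarray, penalty: _PenaltyEvaluator,
                  config: GAConfig, rng) -> tuple[np.ndarray, int, str]:
    """Polish pooled candidates against the exact original-frame residual."""
    P = min(config.refine_population, len(C0))
    C = C0[np.argsort(f0, kind="stable")[:P]]
    n = len(M_orig)
    local = replace(config, max_generations=config.refine_generations)

    def fitness(C):
        W = C @ L.T
        R = W @ M_orig.T
        return (R * R).sum(axis=1) / (n * (W * W).sum(axis=1)) + penalty(C)

    history: list[float] = []
    reason = "max_generations"
    f = fitness(C)
    for _ in range(config.refine_generations):
        history.append(float(f.min()))
        stop, why = stopping_check(history, local)
        if stop:
            reason = why
            break
        C = evolve_generation(C, f, config, rng)
        f = fitness(C)
    return C, len(history), reason


def fit_ga(cloud: PointCloud, config: Optional[GAConfig] = None,
           seed: Optional[int] = None) -> FitResult:
    """Fit the implicit quadric to a point cloud with the genetic algorithm.

    ``seed`` overrides ``config.seed``; with a fixed seed the result is
    bit-reproducible. Raises InsufficientDataError for clouds with fewer than
    10 points.
    """
    config = config or GAConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    pts = cloud.points
    if len(pts) < _MIN_POINTS:
        raise InsufficientDataError(
            f"need at least {_MIN_POINTS} points, got {len(pts)}")

    rng = np.random.default_rng(config.seed)
    pre = Preconditioner.fit(pts)
    scaled = pre.apply(pts)
    M = design_matrix(scaled)
    Rq = np.linalg.qr(M, mode="r")
    penalty = _PenaltyEvaluator(scaled, config.penalty_nodes)
    L = _transform_matrix(pre.center, pre.scale)
    M_orig = design_matrix(pts)

    pools, fits, total_gens, reasons = [], [], 0, []
    for _ in range(max(1, config.restarts)):
        C, f, gens, reason = _coarse_phase(Rq, len(pts), penalty, config, rng)
        pools.append(C)
        fits.append(f)
        total_gens += gens
        reasons.append(reason)

    final_pop, refine_gens, refine_reason = _refine_phase(
        np.vstack(pools), np.concatenate(fits), M_orig, L, penalty, config, rng)
    total_gens += refine_gens
    reasons.append(refine_reason)

    # final selection through the exact reporting pipeline (back-transform,
    # normalisation, mean squared residual + penalty), so the returned fit
    # minimises precisely the quantity that is reported and compared
    candidates = [pre.restore_coefficients(v) for v in final_pop]
    V = np.stack([c.array for c in candidates])
    R = V @ M_orig.T
    scores = (R * R).mean(axis=1) + penalty(final_pop)
    coeffs = candidates[int(np.argmin(scores))]
    mse, unresolved = elevation_mse(coeffs, cloud)
    return FitResult(
        coefficients=coeffs,
        mse=mse,
        n_points=len(pts),
        method_tag="GA",
        generations=total_gens,
        converged=any(r == "tolerance" for r in reasons),
        fq=check_quadric_order(coeffs),
        unresolved_nodes=unresolved,
        seed=config.seed,
        fitness=algebraic_fitness(coeffs, cloud),
    )
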