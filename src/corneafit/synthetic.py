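"""Synthetic corneal elevation grids with exact ground truth.

Real Sirius-style exports are not redistributable, so test data are emulated:
an ellipsoidal cornea with prescribed apical radii (Rx, Ry) and asphericities
(Qx, Qy) is sampled on the tomographer's 24 x 256 polar grid, Gaussian
elevation noise is added, and acquisition dropouts are coded with the -1000
sentinel. A Gaussian bump emulates the local protrusion of keratoconus, so
graded cohorts (control / KC grades) can be generated with known truth.

The prescribed parameters are inverted through the canonical relations
a^2 = Rx * c and (a/c)^2 = 1 + Qx, giving c = Rx / (1 + Qx) and
a = Rx / sqrt(1 + Qx) (likewise for b from Ry, Qy). A single shared c-axis is
used -- a true ellipsoid, inside the fitted model family -- so recovery tests
are exact; if the x- and y-derived c differ, their geometric mean is used and
the recorded truth is recomputed from the realised axes. Cone deformation
supplies the out-of-family stress test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .grid import (SENTINEL, PolarElevationGrid, default_meridian_angles,
                   default_ring_radii)
from .morphometrics import (CanonicalEllipsoid, MorphoGeometry,
                            morpho_parameters)
from .quadric import QuadricCoefficients, solve_elevation


@dataclass(frozen=True)
class ConeSpec:
    """Keratoconus-like Gaussian protrusion added to the elevations."""

    amplitude_mm: float
    width_mm: float
    center_xy_mm: tuple[float, float]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic cornea (defaults: healthy anterior surface)."""

    rx: float = 7.8
    ry: float = 7.8
    qx: float = -0.3
    qy: float = -0.3
    apex_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tilt_deg: float = 0.0
    noise_sigma: float = 0.0            # mm
    dropout_fraction: float = 0.0
    dropout_mode: str = "random"        # random | wedge | ring
    cone: Optional[ConeSpec] = None
    seed: Optional[int] = None
    n_rings: int = 24
    n_meridians: int = 256

    def __post_init__(self) -> None:
        if self.rx <= 0 or self.ry <= 0:
            raise ValueError("radii must be positive")
        if 1.0 + self.qx <= 0 or 1.0 + self.qy <= 0:
            raise ValueError("asphericities must satisfy 1 + Q > 0 (ellipsoidal regime)")
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise ValueError("dropout_fraction must be in [0, 1)")
        if self.dropout_mode not in ("random", "wedge", "ring"):
            raise ValueError(f"unknown dropout_mode {self.dropout_mode!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Exact surface the grid was sampled from."""

    coefficients: QuadricCoefficients
    ellipsoid: CanonicalEllipsoid
    morphometry: MorphoGeometry
    n_footprint_sentinels: int = 0


def _realized_ellipsoid(spec: SyntheticSpec) -> CanonicalEllipsoid:
    cx = spec.rx / (1.0 + spec.qx)
    cy = spec.ry / (1.0 + spec.qy)
    c = math.sqrt(cx * cy)
    a = math.sqrt(spec.rx * c)
    b = math.sqrt(spec.ry * c)

    t = math.radians(spec.tilt_deg)
    rot_x = np.array([[1.0, 0.0, 0.0],
                      [0.0, math.cos(t), -math.sin(t)],
                      [0.0, math.sin(t), math.cos(t)]])
    apex = np.asarray(spec.apex_offset, dtype=float)
    # canonical apex sits at (0, 0, +c); place it at the requested offset
    center = apex - rot_x @ np.array([0.0, 0.0, c])
    return CanonicalEllipsoid(semi_axes=(a, b, c), rotation=rot_x, center=center)


def make_ellipsoid_grid(spec: SyntheticSpec) -> tuple[PolarElevationGrid, GroundTruth]:
    """Sample the specified ellipsoid on the polar grid; return grid + truth.

    Grid nodes outside the ellipsoid's xy-footprint are sentinel-coded and
    counted in the returned truth. Noise and dropout are applied afterwards,
    then the optional cone deformation.
    """
    rng = np.random.default_rng(spec.seed)
    ellipsoid = _realized_ellipsoid(spec)
    coeffs = ellipsoid.to_coefficients()

    radii = default_ring_radii(spec.n_rings)
    angles = default_meridian_angles(spec.n_meridians)
    r = radii[:, None]
    x = r * np.cos(angles[None, :])
    y = r * np.sin(angles[None, :])
    apex_z = spec.apex_offset[2]
    z = solve_elevation(coeffs, x.ravel(), y.ravel(),
                        z_ref=np.full(x.size, apex_z)).reshape(x.shape)

    outside = ~np.isfinite(z)
    n_footprint = int(outside.sum())
    if spec.noise_sigma > 0:
        z = z + spec.noise_sigma * rng.standard_normal(z.shape)
    z[outside] = SENTINEL

    n_drop = math.floor(spec.dropout_fraction * z.size)
    if n_drop > 0:
        if spec.dropout_mode == "random":
            valid = np.flatnonzero(~outside.ravel())
            idx = rng.choice(valid, size=min(n_drop, len(valid)), replace=False)
            z.ravel()[idx] = SENTINEL
        elif spec.dropout_mode == "wedge":
            n_mer = max(1, round(spec.dropout_fraction * spec.n_meridians))
            start = int(rng.integers(0, spec.n_meridians))
            cols = (start + np.arange(n_mer)) % spec.n_meridians
            z[:, cols] = SENTINEL
        else:  # ring: peripheral rings, where tear-film loss hits first
            n_r = max(1, math.ceil(spec.dropout_fraction * spec.n_rings))
            z[-n_r:, :] = SENTINEL

    grid = PolarElevationGrid(ring_radii=radii, meridian_angles=angles,
                              elevations=z)
    if spec.cone is not None:
        grid = add_cone(grid, spec.cone.amplitude_mm, spec.cone.width_mm,
                        spec.cone.center_xy_mm)
    truth = GroundTruth(coefficients=coeffs, ellipsoid=ellipsoid,
                        morphometry=morpho_parameters(ellipsoid),
                        n_footprint_sentinels=n_footprint)
    return grid, truth


def add_cone(grid: PolarElevationGrid, amplitude: float, width: float,
             center: tuple[float, float]) -> PolarElevationGrid:
    """Add a Gaussian protrusion amplitude * exp(-d^2 / (2 width^2)) (mm).

    d is the xy-distance from each node to the cone centre; sentinel cells are
    untouched. Returns a new grid.
    """
    if amplitude < 0 or width <= 0:
        raise ValueError("amplitude must be >= 0 and width > 0")
    r = grid.ring_radii[:, None]
    x = r * np.cos(grid.meridian_angles[None, :])
    y = r * np.sin(grid.meridian_angles[None, :])
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2
    bump = amplitude * np.exp(-d2 / (2.0 * width ** 2))
    elev = grid.elevations.copy()
    valid = ~grid.sentinel_mask
    elev[valid] += bump[valid]
    return PolarElevationGrid(ring_radii=grid.ring_radii.copy(),
                              meridian_angles=grid.meridian_angles.copy(),
                              elevations=elev, surface_label=grid.surface_label)


#: cohort presets: (mean radius mm, mean Q, Q sd, noise sigma mm, cone amplitude mm)
COHORT_PRESETS = {
    "control": dict(r_mean=7.8, q_mean=-0.30, q_sd=0.05, sigma=0.003, cone_amp=0.0),
    "ak1": dict(r_mean=7.2, q_mean=-0.55, q_sd=0.10, sigma=0.005, cone_amp=0.02),
    "ak2": dict(r_mean=6.9, q_mean=-0.75, q_sd=0.10, sigma=0.005, cone_amp=0.05),
    "ak34": dict(r_mean=6.7, q_mean=-0.90, q_sd=0.08, sigma=0.005, cone_amp=0.10),
}


def make_cohort(n: int, grade_preset: str, seed: Optional[int] = None,
                dropout_fraction: float = 0.0, dropout_mode: str = "random",
                ) -> list[tuple[PolarElevationGrid, GroundTruth]]:
    """Generate n synthetic corneas from a graded preset, deterministic per seed.

    Presets mirror a clinical grading ladder: the control group is a mildly
    noisy healthy ellipsoid; the keratoconus grades add Gaussian cones of
    increasing amplitude (0.02 / 0.05 / 0.10 mm) with asphericity drawn toward
    -1 and steeper radii.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if grade_preset not in COHORT_PRESETS:
        raise ValueError(f"unknown preset {grade_preset!r}; "
                         f"choose from {sorted(COHORT_PRESETS)}")
    p = COHORT_PRESETS[grade_preset]
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        rx = float(rng.normal(p["r_mean"], 0.25))
        ry = float(rng.normal(p["r_mean"] - 0.1, 0.25))
        qx = float(np.clip(rng.normal(p["q_mean"], p["q_sd"]), -0.95, 0.2))
        qy = float(np.clip(rng.normal(p["q_mean"], p["q_sd"]), -0.95, 0.2))
        cone = None
        if p["cone_amp"] > 0:
            theta = rng.uniform(0, 2 * math.pi)
            rc = rng.uniform(0.8, 2.0)
            cone = ConeSpec(amplitude_mm=p["cone_amp"],
                            width_mm=float(rng.uniform(1.2, 1.8)),
                            center_xy_mm=(rc * math.cos(theta),
                                          rc * math.sin(theta)))
        spec = SyntheticSpec(rx=rx, ry=ry, qx=qx, qy=qy,
                             noise_sigma=p["sigma"], cone=cone,
                             dropout_fraction=dropout_fraction,
                             dropout_mode=dropout_mode,
                             seed=int(rng.integers(0, 2**31 - 1)))
        out.append(make_ellipsoid_grid(spec))
    return out
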