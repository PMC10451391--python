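"""Batch method comparison, failure-rate aggregation, and STL mesh export."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import Delaunay

from .classical import fit_direct_linear, fit_lsq_trra, fit_sqp
from .errors import FootprintError, NotAnEllipsoidError
from .ga import GAConfig, fit_ga
from .grid import PolarElevationGrid, polar_to_cartesian
from .morphometrics import morpho_parameters, to_canonical_ellipsoid
from .quadric import FitResult, QuadricCoefficients, evaluate_quadric, solve_elevation

#: stable schema of the comparison table
COMPARISON_COLUMNS = [
    "method", "group", "n_surfaces", "n_failed",
    "mse_mean", "mse_sd", "fqn",
    "rx_mean", "rx_sd", "ry_mean", "ry_sd",
    "qx_mean", "qx_sd", "qy_mean", "qy_sd",
]

METHODS = ("GA", "LSQ", "SQP", "DIRECT")


def aggregate_fqn(results: Sequence[FitResult]) -> int:
    """Failure quadric number: the count of fq = 1 reconstructions."""
    if len(results) == 0:
        raise ValueError("results must be non-empty")
    return int(sum(r.fq for r in results))


def _fit_one(grid: PolarElevationGrid, method: str, seed: Optional[int],
             ga_config: Optional[GAConfig]) -> FitResult:
    cloud = polar_to_cartesian(grid)
    if method == "GA":
        return fit_ga(cloud, config=ga_config, seed=seed)
    if method == "LSQ":
        return fit_lsq_trra(cloud)
    if method == "SQP":
        return fit_sqp(cloud)
    if method == "DIRECT":
        return fit_direct_linear(cloud)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def compare_methods(grids: Sequence[PolarElevationGrid],
                    methods: Sequence[str] = ("GA", "LSQ"),
                    groups: Optional[Sequence[str]] = None,
                    seed: Optional[int] = None,
                    ga_config: Optional[GAConfig] = None,
                    csv_path=None) -> pd.DataFrame:
    """Fit every grid with every method; aggregate per method x group.

    Returns a table with mean/SD of the elevation MSE and of the morphometric
    parameters (fq = 1 fits excluded from morphometry means), plus the FQN per
    cell. A method failure on one grid is recorded in n_failed, never aborts
    the batch. Optionally written as CSV.
    """
    if len(grids) == 0 or len(methods) == 0:
        raise ValueError("need at least one grid and one method")
    groups = list(groups) if groups is not None else ["all"] * len(grids)
    if len(groups) != len(grids):
        raise ValueError("groups must match grids in length")

    rows = []
    for method in methods:
        per_group: dict[str, dict] = {}
        for i, (grid, group) in enumerate(zip(grids, groups)):
            cell = per_group.setdefault(
                group, {"mse": [], "rx": [], "ry": [], "qx": [], "qy": [],
                        "fqn": 0, "failed": 0, "n": 0})
            cell["n"] += 1
            run_seed = None if seed is None else (seed * 1009 + i) % (2**31 - 1)
            try:
                res = _fit_one(grid, method, run_seed, ga_config)
            except Exception:
                cell["failed"] += 1
                continue
            cell["mse"].append(res.mse)
            cell["fqn"] += res.fq
            if res.fq == 0:
                try:
                    m = morpho_parameters(to_canonical_ellipsoid(res.coefficients))
                except NotAnEllipsoidError:
                    continue
                cell["rx"].append(m.rx)
                cell["ry"].append(m.ry)
                cell["qx"].append(m.qx)
                cell["qy"].append(m.qy)

        for group, cell in per_group.items():
            def _stats(vals):
                if not vals:
                    return float("nan"), float("nan")
                arr = np.asarray(vals)
                return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
            mse_m, mse_s = _stats(cell["mse"])
            rx_m, rx_s = _stats(cell["rx"])
            ry_m, ry_s = _stats(cell["ry"])
            qx_m, qx_s = _stats(cell["qx"])
            qy_m, qy_s = _stats(cell["qy"])
            rows.append(dict(method=method, group=group,
                             n_surfaces=cell["n"], n_failed=cell["failed"],
                             mse_mean=mse_m, mse_sd=mse_s, fqn=cell["fqn"],
                             rx_mean=rx_m, rx_sd=rx_s, ry_mean=ry_m, ry_sd=ry_s,
                             qx_mean=qx_m, qx_sd=qx_s, qy_mean=qy_m, qy_sd=qy_s))

    df = pd.DataFrame(rows, columns=COMPARISON_COLUMNS)
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    return df


def sample_cap(c: QuadricCoefficients, footprint_radius: float,
               resolution: int, z_ref: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Sample and triangulate the quadric cap over a polar footprint.

    Elevations are solved on a polar sample (``resolution`` rings, 4x as many
    meridians, plus the centre point) and triangulated by Delaunay in the
    xy-plane, faces oriented so normals point to +z. Returns (vertices, faces)
    in mm/float64. Raises FootprintError (with the count) if any sample node
    has no real elevation.
    """
    if resolution < 2 or footprint_radius <= 0:
        raise ValueError("resolution must be >= 2 and footprint_radius > 0")
    rr = footprint_radius * np.arange(1, resolution + 1) / resolution
    th = 2.0 * np.pi * np.arange(4 * resolution) / (4 * resolution)
    x = np.concatenate([[0.0], (rr[:, None] * np.cos(th)[None, :]).ravel()])
    y = np.concatenate([[0.0], (rr[:, None] * np.sin(th)[None, :]).ravel()])
    z = solve_elevation(c, x, y, z_ref=np.full_like(x, z_ref))
    bad = int(np.sum(~np.isfinite(z)))
    if bad:
        raise FootprintError(
            f"{bad} of {len(x)} footprint nodes have no real elevation; "
            "shrink footprint_radius")

    tri = Delaunay(np.column_stack([x, y]))
    faces = tri.simplices.copy()
    verts = np.column_stack([x, y, z])
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    nz = np.cross(v1 - v0, v2 - v0)[:, 2]
    flip = nz < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return verts, faces


def export_stl(c: QuadricCoefficients, footprint_radius: float,
               resolution: int, path, z_ref: float = 0.0):
    """Write the triangulated quadric cap as binary STL (units mm).

    Note STL stores float32 vertices, so on-surface residuals of the written
    file are limited to single precision.
    """
    verts, faces = sample_cap(c, footprint_radius, resolution, z_ref)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.export(path, file_type="stl")
    return path
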