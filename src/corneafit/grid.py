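"""Polar elevation grids and their conversion to Cartesian point clouds.

Scheimpflug tomographers of the Sirius family export corneal elevation as a
polar grid: 24 concentric rings (0.2 mm radial spacing) by 256 semi-meridians,
one elevation in mm per node, with the sentinel value -1000 marking samples
that failed during acquisition (tear-film breakup, lid shadow, noise).
This module reads and writes that CSV dialect and converts grids to the
Cartesian (x, y, z) clouds the surface fitters consume, dropping sentinels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyCloudError, GridDimensionError, GridParseError

SENTINEL = -1000.0

DEFAULT_N_RINGS = 24
DEFAULT_N_MERIDIANS = 256
DEFAULT_RING_SPACING_MM = 0.2


@dataclass(frozen=True)
class CsvDialect:
    """Layout of a polar-grid CSV export.

    Vendor exports vary; the default is a bare comma-separated numeric table
    with rings as rows, no header, '.' decimal separator, rings every 0.2 mm.
    """

    delimiter: str = ","
    decimal: str = "."
    rings_as_rows: bool = True
    n_rings: int = DEFAULT_N_RINGS
    n_meridians: int = DEFAULT_N_MERIDIANS
    ring_spacing_mm: float = DEFAULT_RING_SPACING_MM


def default_ring_radii(n_rings: int = DEFAULT_N_RINGS,
                       spacing_mm: float = DEFAULT_RING_SPACING_MM) -> np.ndarray:
    """Ring radii r_i = i * spacing for i = 1..n (first ring at 0.2 mm, not 0)."""
    return spacing_mm * np.arange(1, n_rings + 1, dtype=float)


def default_meridian_angles(n_meridians: int = DEFAULT_N_MERIDIANS) -> np.ndarray:
    """Meridian angles theta_j = (j-1) * 2*pi/n, column 1 at 0 rad, CCW."""
    return 2.0 * math.pi * np.arange(n_meridians, dtype=float) / n_meridians


@dataclass
class PolarElevationGrid:
    """One corneal surface sampled on the tomographer's polar grid.

    elevations[i, j] is the elevation (mm) at ring i, meridian j; entries equal
    to SENTINEL (-1000.0 exactly) are invalid. The default grid has
    24 x 256 = 6144 cells.
    """

    ring_radii: np.ndarray
    meridian_angles: np.ndarray
    elevations: np.ndarray
    surface_label: str = "anterior"

    def __post_init__(self) -> None:
        self.ring_radii = np.asarray(self.ring_radii, dtype=float)
        self.meridian_angles = np.asarray(self.meridian_angles, dtype=float)
        self.elevations = np.asarray(self.elevations, dtype=float)
        if self.ring_radii.ndim != 1 or self.meridian_angles.ndim != 1:
            raise GridDimensionError("ring_radii and meridian_angles must be 1-D")
        if self.ring_radii.size == 0 or self.meridian_angles.size == 0:
            raise GridDimensionError("grid must have at least one ring and one meridian")
        if self.elevations.shape != (self.ring_radii.size, self.meridian_angles.size):
            raise GridDimensionError(
                f"elevations shape {self.elevations.shape} does not match "
                f"{self.ring_radii.size} rings x {self.meridian_angles.size} meridians")
        if np.any(self.ring_radii <= 0) or np.any(np.diff(self.ring_radii) <= 0):
            raise GridDimensionError("ring_radii must be strictly increasing and positive")
        d = np.diff(self.meridian_angles)
        if self.meridian_angles[0] != 0.0 or np.any(d <= 0) or not np.allclose(d, d[0]):
            raise GridDimensionError("meridian_angles must start at 0, equally spaced, increasing")
        bad = ~np.isfinite(self.elevations)
        if np.any(bad):
            raise GridParseError("elevations contain non-finite entries")
        if self.surface_label not in ("anterior", "posterior"):
            raise ValueError(f"unknown surface_label {self.surface_label!r}")

    @property
    def n_cells(self) -> int:
        return self.elevations.size

    @property
    def sentinel_mask(self) -> np.ndarray:
        return self.elevations == SENTINEL

    @property
    def n_sentinels(self) -> int:
        return int(self.sentinel_mask.sum())


@dataclass
class PointCloud:
    """Cartesian point cloud (mm) derived from a grid, sentinels removed."""

    points: np.ndarray                       # (N, 3)
    source_node_ids: np.ndarray = field(default=None)  # (N, 2) 0-based (ring, meridian)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if self.source_node_ids is None:
            self.source_node_ids = np.full((len(self.points), 2), -1, dtype=int)
        else:
            self.source_node_ids = np.asarray(self.source_node_ids, dtype=int)

    def __len__(self) -> int:
        return len(self.points)


def read_polar_csv(path, dialect: CsvDialect = CsvDialect(),
                   surface_label: str = "anterior") -> PolarElevationGrid:
    """Read a polar elevation grid from CSV under the given dialect.

    Raises GridParseError naming the offending cell for non-numeric entries and
    GridDimensionError stating expected vs found shape.
    """
    try:
        df = pd.read_csv(path, header=None, sep=dialect.delimiter,
                         decimal=dialect.decimal, dtype=str,
                         skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GridParseError(f"cannot read {path}: {exc}") from exc

    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for (i, j), cell in np.ndenumerate(raw):
        try:
            values[i, j] = float(str(cell).replace(dialect.decimal, "."))
        except (TypeError, ValueError):
            raise GridParseError(
                f"non-numeric cell at row {i + 1}, column {j + 1}: {cell!r}") from None

    if not dialect.rings_as_rows:
        values = values.T
    expected = (dialect.n_rings, dialect.n_meridians)
    if values.shape != expected:
        raise GridDimensionError(
            f"expected {expected[0]} x {expected[1]} table, found "
            f"{values.shape[0]} x {values.shape[1]}")

    return PolarElevationGrid(
        ring_radii=default_ring_radii(dialect.n_rings, dialect.ring_spacing_mm),
        meridian_angles=default_meridian_angles(dialect.n_meridians),
        elevations=values,
        surface_label=surface_label,
    )


def write_polar_csv(grid: PolarElevationGrid, path,
                    dialect: CsvDialect = CsvDialect()):
    """Write a grid to CSV; round-trips bit-for-bit through read_polar_csv.

    Elevations are printed with 17 significant digits, which reproduces any
    float64 exactly; the -1000 sentinel is written literally.
    """
    values = grid.elevations if dialect.rings_as_rows else grid.elevations.T
    np.savetxt(path, values, fmt="%.17g", delimiter=dialect.delimiter)
    return path


def polar_to_cartesian(grid: PolarElevationGrid) -> PointCloud:
    """Convert a polar grid to a Cartesian cloud, dropping sentinel cells.

    Node (ring i, meridian j) maps to x = r_i cos(theta_j), y = r_i sin(theta_j),
    z = elevation, all in mm. Raises EmptyCloudError if every cell is sentinel.
    """
    r = grid.ring_radii[:, None]
    th = grid.meridian_angles[None, :]
    x = r * np.cos(th)
    y = r * np.sin(th)
    valid = ~grid.sentinel_mask
    if not np.any(valid):
        raise EmptyCloudError("all grid cells are sentinel-coded")
    ii, jj = np.nonzero(valid)
    pts = np.column_stack([x[valid], y[valid], grid.elevations[valid]])
    return PointCloud(points=pts, source_node_ids=np.column_stack([ii, jj]))
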