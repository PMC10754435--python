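"""Digital spatial sampling frame: square-grid tessellation of a study
boundary and assignment of geolocated household points to grid cells.

The frame plays the role a census enumeration-area list plays in a
conventional multistage survey: each grid cell is a primary sampling unit
whose population size is estimated as (number of inhabited households in
the cell) x (mean household size).  All geometry is planar, in meters, in
a projected CRS; geographic coordinates must be projected upstream.

Conventions
-----------
* The lattice is anchored at the minimum corner of the boundary's bounding
  box; cells that only partially overlap the boundary are retained.
* Cell membership is half-open, ``x in [x0, x1)`` and ``y in [y0, y1)``,
  so a point on a shared edge belongs to exactly one cell (the right/upper
  neighbour).
* Only points flagged ``inhabited`` contribute to household counts and
  population estimates; uninhabited points are kept for bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

__all__ = [
    "Boundary",
    "GridCell",
    "GriddedFrame",
    "POINT_COLUMNS",
    "tessellate",
    "assign_points",
    "estimate_population",
    "build_frame",
    "cells_to_dataframe",
    "validate_points",
]

#: required columns of a household-point table; ``size`` is optional.
POINT_COLUMNS = ("id", "x", "y", "inhabited")

DEFAULT_CELL_SIZE = 5_000.0  # meters
DEFAULT_MEAN_HOUSEHOLD_SIZE = 8.0  # persons per household


@dataclass(frozen=True)
class Boundary:
    """Study-area polygon in a projected planar CRS (meters)."""

    geometry: BaseGeometry
    identifier: str = "study-area"

    def __post_init__(self) -> None:
        geom = self.geometry
        if geom is None or geom.is_empty:
            raise ValueError(f"boundary {self.identifier!r} is empty")
        if not geom.is_valid:
            raise ValueError(
                f"boundary {self.identifier!r} is not a valid simple polygon"
            )
        if geom.area <= 0:
            raise ValueError(f"boundary {self.identifier!r} has zero area")

    @property
    def area_km2(self) -> float:
        return self.geometry.area / 1e6


@dataclass(frozen=True)
class GridCell:
    """One axis-aligned square cell of the sampling lattice."""

    cell_id: str
    row: int
    col: int
    x0: float
    y0: float
    x1: float
    y1: float
    household_count: int = 0
    est_population: float = 0.0

    @property
    def centroid(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    def contains(self, x: float, y: float) -> bool:
        """Half-open membership test."""
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


@dataclass
class GriddedFrame:
    """The digital sampling frame: boundary, cells, points, assignment.

    ``cells`` are in row-major order (row, then column ascending), which is
    also the fixed order used for the cumulative population walk in
    systematic PPS selection.
    """

    boundary: Boundary
    cells: list[GridCell]
    points: pd.DataFrame
    assignment: dict[str, str]
    mean_household_size: float = DEFAULT_MEAN_HOUSEHOLD_SIZE
    out_of_frame: list[str] = field(default_factory=list)

    @property
    def total_population(self) -> float:
        return float(sum(c.est_population for c in self.cells))

    @property
    def n_households(self) -> int:
        """Inhabited households assigned to a cell."""
        return int(sum(c.household_count for c in self.cells))

    def cell(self, cell_id: str) -> GridCell:
        try:
            return self._index[cell_id]
        except AttributeError:
            self._index = {c.cell_id: c for c in self.cells}
            return self._index[cell_id]

    def households_in_cell(self, cell_id: str, inhabited_only: bool = True) -> pd.DataFrame:
        try:
            groups = self._groups
        except AttributeError:
            pts = self.points.copy()
            pts["cell_id"] = pts["id"].map(self.assignment)
            pts = pts.dropna(subset=["cell_id"]).sort_values("id")
            groups = self._groups = dict(tuple(pts.groupby("cell_id", sort=False)))
        sub = groups.get(cell_id)
        if sub is None:
            return self.points.iloc[0:0]
        if inhabited_only:
            sub = sub[sub["inhabited"]]
        return sub.reset_index(drop=True)


def validate_points(points: pd.DataFrame) -> pd.DataFrame:
    """Check schema, id uniqueness and coordinate finiteness."""
    missing = [c for c in POINT_COLUMNS if c not in points.columns]
    if missing:
        raise ValueError(f"point table is missing columns: {missing}")
    dupes = points["id"][points["id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate point ids: {dupes[:10]}")
    xy = points[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        bad = points.loc[~np.isfinite(xy).all(axis=1), "id"].tolist()
        raise ValueError(f"non-finite coordinates for ids: {bad[:10]}")
    pts = points.copy()
    pts["id"] = pts["id"].astype(str)
    pts["inhabited"] = pts["inhabited"].astype(bool)
    return pts


def tessellate(boundary: Boundary, cell_size: float) -> list[GridCell]:
    """Cover ``boundary`` with a regular square lattice of side ``cell_size``.

    The lattice is anchored at the bounding-box minimum corner; every cell
    whose square overlaps the boundary with positive area is returned, in
    row-major order.  Deterministic for identical inputs.
    """
    if cell_size <= 0:
        raise ValueError(f"cell_size must be positive, got {cell_size}")
    geom = boundary.geometry
    minx, miny, maxx, maxy = geom.bounds
    n_cols = max(1, math.ceil((maxx - minx) / cell_size - 1e-12))
    n_rows = max(1, math.ceil((maxy - miny) / cell_size - 1e-12))
    cells: list[GridCell] = []
    for row in range(n_rows):
        y0 = miny + row * cell_size
        for col in range(n_cols):
            x0 = minx + col * cell_size
            square = box(x0, y0, x0 + cell_size, y0 + cell_size)
            if square.intersects(geom) and square.intersection(geom).area > 0:
                cells.append(
                    GridCell(
                        cell_id=f"r{row:03d}c{col:03d}",
                        row=row,
                        col=col,
                        x0=x0,
                        y0=y0,
                        x1=x0 + cell_size,
                        y1=y0 + cell_size,
                    )
                )
    return cells


def assign_points(
    points: pd.DataFrame, cells: Sequence[GridCell]
) -> tuple[dict[str, str], dict[str, int], list[str]]:
    """Assign each point to the unique cell containing it (half-open).

    Returns ``(assignment, counts, out_of_frame)``: the id -> cell_id map,
    per-cell counts of *inhabited* points, and ids of points that fall in
    no cell.  Out-of-frame points are reported, never silently dropped.
    """
    pts = validate_points(points)
    if not cells:
        raise ValueError("no grid cells supplied")
    cell_size = cells[0].x1 - cells[0].x0
    minx = min(c.x0 for c in cells)
    miny = min(c.y0 for c in cells)
    by_rc = {(c.row, c.col): c.cell_id for c in cells}

    assignment: dict[str, str] = {}
    counts: dict[str, int] = {c.cell_id: 0 for c in cells}
    out_of_frame: list[str] = []
    ids = pts["id"].to_numpy()
    cols = np.floor((pts["x"].to_numpy(dtype=float) - minx) / cell_size).astype(int)
    rows = np.floor((pts["y"].to_numpy(dtype=float) - miny) / cell_size).astype(int)
    inhabited = pts["inhabited"].to_numpy()
    for pid, r, c, inh in zip(ids, rows, cols, inhabited):
        cid = by_rc.get((int(r), int(c)))
        if cid is None:
            out_of_frame.append(str(pid))
            continue
        assignment[str(pid)] = cid
        if inh:
            counts[cid] += 1
    return assignment, counts, out_of_frame


def estimate_population(
    cells: Sequence[GridCell],
    counts: Mapping[str, int] | None = None,
    mean_household_size: float = DEFAULT_MEAN_HOUSEHOLD_SIZE,
) -> tuple[list[GridCell], float]:
    """Estimate each cell's population as count x mean household size.

    If ``counts`` is given it overwrites the cells' household counts first.
    Returns the updated cells and the frame total.
    """
    if mean_household_size <= 0:
        raise ValueError(
            f"mean_household_size must be positive, got {mean_household_size}"
        )
    updated: list[GridCell] = []
    for cell in cells:
        n = counts.get(cell.cell_id, 0) if counts is not None else cell.household_count
        updated.append(
            replace(cell, household_count=int(n), est_population=n * mean_household_size)
        )
    total = float(sum(c.est_population for c in updated))
    return updated, total


def build_frame(
    boundary: Boundary,
    points: pd.DataFrame,
    cell_size: float = DEFAULT_CELL_SIZE,
    mean_household_size: float = DEFAULT_MEAN_HOUSEHOLD_SIZE,
) -> GriddedFrame:
    """Tessellate, assign and estimate in one step."""
    cells = tessellate(boundary, cell_size)
    assignment, counts, out_of_frame = assign_points(points, cells)
    cells, _total = estimate_population(cells, counts, mean_household_size)
    return GriddedFrame(
        boundary=boundary,
        cells=cells,
        points=validate_points(points),
        assignment=assignment,
        mean_household_size=mean_household_size,
        out_of_frame=out_of_frame,
    )


def cells_to_dataframe(cells: Iterable[GridCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "row": c.row,
                "col": c.col,
                "x0": c.x0,
                "y0": c.y0,
                "x1": c.x1,
                "y1": c.y1,
                "household_count": c.household_count,
                "est_population": c.est_population,
            }
            for c in cells
        ]
    )
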