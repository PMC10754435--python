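"""GeoJSON and CSV input/output for boundaries, points, grids and rosters.

All coordinates are expected to be in a projected planar CRS in meters;
no reprojection is performed anywhere in the package.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.ops import unary_union

from .frame import Boundary, GridCell

__all__ = [
    "read_boundary",
    "read_points",
    "write_points_csv",
    "write_grid",
    "write_roster",
    "read_roster",
]


def read_boundary(path: str | Path, identifier: str | None = None) -> Boundary:
    """Read a GeoJSON Polygon/MultiPolygon boundary (projected meters)."""
    path = Path(path)
    gj = json.loads(path.read_text())
    if gj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in gj["features"]]
        geom = unary_union(geoms)
    elif gj.get("type") == "Feature":
        geom = shape(gj["geometry"])
    else:
        geom = shape(gj)
    return Boundary(geom, identifier=identifier or path.stem)


def read_points(path: str | Path) -> pd.DataFrame:
    """Read household points from CSV (id,x,y,inhabited[,size]) or GeoJSON
    Point features with the same properties."""
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        gj = json.loads(path.read_text())
        rows = []
        for feat in gj["features"]:
            x, y = feat["geometry"]["coordinates"][:2]
            props = feat.get("properties") or {}
            rows.append({"x": x, "y": y, **props})
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path)
    if "inhabited" in df.columns:
        df["inhabited"] = (
            df["inhabited"].astype(str).str.lower().isin(("true", "1", "yes"))
        )
    df["id"] = df["id"].astype(str)
    return df


def write_points_csv(points: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("id", "x", "y", "inhabited", "size", "manyatta_id") if c in points]
    points[cols].to_csv(path, index=False)


def write_grid(cells: Iterable[GridCell], path: str | Path, csv_mirror: bool = True) -> None:
    """Write grid cells as GeoJSON polygons, with an optional CSV mirror."""
    path = Path(path)
    features = []
    for c in cells:
        geom = {
            "type": "Polygon",
            "coordinates": [[
                [c.x0, c.y0], [c.x1, c.y0], [c.x1, c.y1], [c.x0, c.y1], [c.x0, c.y0],
            ]],
        }
        features.append(
            {
                "type": "Feature",
                "geometry": geom,
                "properties": {
                    "cell_id": c.cell_id,
                    "row": c.row,
                    "col": c.col,
                    "household_count": c.household_count,
                    "est_population": c.est_population,
                },
            }
        )
    path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )
    if csv_mirror:
        from .frame import cells_to_dataframe

        cells_to_dataframe(cells).to_csv(path.with_suffix(".csv"), index=False)


def write_boundary(boundary: Boundary, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "type": "Feature",
                "geometry": mapping(boundary.geometry),
                "properties": {"identifier": boundary.identifier},
            }
        )
    )


def write_roster(roster: pd.DataFrame, path: str | Path) -> None:
    roster.to_csv(path, index=False)


def read_roster(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["id"] = df["id"].astype(str)
    return df
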