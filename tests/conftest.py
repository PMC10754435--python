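import numpy as np
import pandas as pd
import pytest
from hypothesis import settings
from shapely.geometry import box

from gridsample.frame import Boundary, GridCell, GriddedFrame

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture
def square_boundary():
    """10 km x 10 km square study area."""
    return Boundary(box(0, 0, 10_000, 10_000), identifier="square-10km")


def make_toy_frame(populations, cell_size=1_000.0):
    """A frame with given per-cell populations on a 1-row lattice.

    Household points are not materialised; only selection logic that
    relies on cells and totals should use this.
    """
    cells = [
        GridCell(
            cell_id=f"r000c{i:03d}", row=0, col=i,
            x0=i * cell_size, y0=0.0, x1=(i + 1) * cell_size, y1=cell_size,
            household_count=int(p), est_population=float(p),
        )
        for i, p in enumerate(populations)
    ]
    boundary = Boundary(box(0, 0, len(populations) * cell_size, cell_size))
    return GriddedFrame(
        boundary=boundary,
        cells=cells,
        points=pd.DataFrame(columns=["id", "x", "y", "inhabited"]),
        assignment={},
    )


def make_points(coords, inhabited=True, sizes=None, prefix="p"):
    n = len(coords)
    inh = [inhabited] * n if isinstance(inhabited, bool) else list(inhabited)
    df = pd.DataFrame(
        {
            "id": [f"{prefix}{i}" for i in range(n)],
            "x": [c[0] for c in coords],
            "y": [c[1] for c in coords],
            "inhabited": inh,
        }
    )
    if sizes is not None:
        df["size"] = sizes
    return df


@pytest.fixture(scope="session")
def dense_landscape():
    """A landscape dense enough that every selectable cell can supply a
    full 25-household cluster plus replacements."""
    from gridsample.simulator import LandscapeParams, gen_landscape

    params = LandscapeParams(
        width_km=50, height_km=50, parent_intensity=0.5, mean_offspring=12,
        inhabited_prob=0.95, seed=101,
    )
    return gen_landscape(params)


@pytest.fixture(scope="session")
def dense_frame(dense_landscape):
    from gridsample.frame import build_frame

    points, boundary = dense_landscape
    return build_frame(boundary, points)
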