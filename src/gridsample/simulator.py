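"""Synthetic pastoralist landscapes, movement, and snakebite outcomes.

The generator produces, with known ground truth, the three ingredients a
grid-based mobile-population survey has to cope with:

1. **Landscape** — homestead locations from a Thomas (Poisson-cluster)
   point process: settlement centres ("manyattas") are a homogeneous
   Poisson process, each spawning a Poisson number of homesteads displaced
   by an isotropic Gaussian.  Household sizes are 1 + Poisson(mean - 1);
   a Bernoulli flag marks which digitised structures are inhabited.
2. **Movement** — between mapping and fieldwork, whole manyattas may
   abandon their site and move as a rigid unit (untraceable to a field
   team), and individual households may independently move a lognormally
   distributed distance in a uniform direction.
3. **Outcomes** — per-person snakebite indicators from a logistic model
   in standardised local household density, with a negative coefficient by
   default: people in sparsely settled areas are at higher risk.

Default rates emulate the magnitudes reported for a North-Kenyan
pastoralist county: a ~21,000 km² study area holding ~50,000 homesteads
(~2.4 per km², which a 5 km grid divides into ~900 cells), mean household
size 8, and a field-recovery mix in which roughly half of sampled
households are found in place, a fifth have moved a few km, and a third
are lost to long-range movement or wholesale settlement abandonment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import expit, logit
from shapely.geometry import box

from .frame import Boundary

__all__ = [
    "LandscapeParams",
    "MovementParams",
    "OutcomeParams",
    "gen_landscape",
    "gen_movement",
    "gen_outcomes",
    "field_observations",
    "true_prevalence",
]

MAX_EXPECTED_POINTS = 1_000_000


@dataclass(frozen=True)
class LandscapeParams:
    """Thomas-process landscape parameters.

    width_km, height_km : rectangular study-area dimensions.
    parent_intensity : manyattas per km².
    mean_offspring : mean homesteads per manyatta.
    dispersion : within-manyatta Gaussian spread, meters.
    household_size_mean : persons per household (1 + Poisson(mean - 1)).
    inhabited_prob : probability a digitised structure is inhabited.
    """

    width_km: float = 145.0
    height_km: float = 145.0
    parent_intensity: float = 0.3
    mean_offspring: float = 8.0
    dispersion: float = 150.0
    household_size_mean: float = 8.0
    inhabited_prob: float = 0.9
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.width_km <= 0 or self.height_km <= 0:
            raise ValueError("study area dimensions must be positive")
        if self.parent_intensity < 0 or self.mean_offspring < 0:
            raise ValueError("intensities must be non-negative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.household_size_mean < 1:
            raise ValueError("household_size_mean must be >= 1")
        if not 0 <= self.inhabited_prob <= 1:
            raise ValueError("inhabited_prob must be in [0, 1]")

    @property
    def expected_points(self) -> float:
        return self.width_km * self.height_km * self.parent_intensity * self.mean_offspring


@dataclass(frozen=True)
class MovementParams:
    """Between-mapping-and-fieldwork movement process.

    move_prob : per-household probability of an independent move.
    displacement_scale : median independent-move distance, meters.
    displacement_sigma : lognormal shape of move distances.
    abandon_prob : per-manyatta probability the settlement relocates as a
        unit (its households become untraceable to the field team).
    abandon_scale : median distance of a wholesale relocation, meters.
    """

    move_prob: float = 0.2
    displacement_scale: float = 2_000.0
    displacement_sigma: float = 1.0
    abandon_prob: float = 0.15
    abandon_scale: float = 20_000.0
    abandon_sigma: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("move_prob", "abandon_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.displacement_scale <= 0 or self.abandon_scale <= 0:
            raise ValueError("displacement scales must be positive")


@dataclass(frozen=True)
class OutcomeParams:
    """Density-dependent binary-outcome model.

    Per-person probability = expit(logit(baseline_prevalence)
    + density_coefficient * z), where z is the standardised count of
    households within density_bandwidth meters.
    """

    baseline_prevalence: float = 0.04
    density_coefficient: float = -0.8
    density_bandwidth: float = 2_000.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must be in [0, 1)")
        if self.density_bandwidth <= 0:
            raise ValueError("density_bandwidth must be positive")


def gen_landscape(params: LandscapeParams) -> tuple[pd.DataFrame, Boundary]:
    """Generate homestead points and the rectangular study boundary.

    Returns ``(points, boundary)`` where points has columns id, x, y,
    inhabited, size, manyatta_id.  Offspring falling outside the boundary
    rectangle are discarded (edge effects are not corrected).
    """
    if params.expected_points > MAX_EXPECTED_POINTS:
        raise ValueError(
            f"expected point count {params.expected_points:.0f} exceeds "
            f"{MAX_EXPECTED_POINTS}; reduce area, parent_intensity or "
            "mean_offspring"
        )
    rng = np.random.default_rng(params.seed)
    w, h = params.width_km * 1_000.0, params.height_km * 1_000.0
    boundary = Boundary(box(0.0, 0.0, w, h), identifier="synthetic-study-area")

    n_parents = rng.poisson(params.parent_intensity * params.width_km * params.height_km)
    px = rng.uniform(0, w, n_parents)
    py = rng.uniform(0, h, n_parents)
    n_off = rng.poisson(params.mean_offspring, n_parents)

    xs = np.repeat(px, n_off) + rng.normal(0, params.dispersion, n_off.sum())
    ys = np.repeat(py, n_off) + rng.normal(0, params.dispersion, n_off.sum())
    manyatta = np.repeat(np.arange(n_parents), n_off)
    inside = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
    xs, ys, manyatta = xs[inside], ys[inside], manyatta[inside]
    n = len(xs)

    sizes = 1 + rng.poisson(params.household_size_mean - 1.0, n)
    inhabited = rng.random(n) < params.inhabited_prob
    points = pd.DataFrame(
        {
            "id": [f"hh{i:06d}" for i in range(n)],
            "x": xs,
            "y": ys,
            "inhabited": inhabited,
            "size": sizes,
            "manyatta_id": manyatta,
        }
    )
    return points, boundary


def gen_movement(points: pd.DataFrame, params: MovementParams) -> pd.DataFrame:
    """Simulate positions at fieldwork time.

    Returns a table with columns id, new_x, new_y, moved, abandoned,
    distance.  Abandoned manyattas share one rigid displacement; other
    households move independently with probability ``move_prob``;
    non-movers keep their coordinates exactly.
    """
    rng = np.random.default_rng(params.seed)
    n = len(points)
    x = points["x"].to_numpy(float).copy()
    y = points["y"].to_numpy(float).copy()

    if "manyatta_id" in points.columns:
        manyatta = points["manyatta_id"].to_numpy()
    else:  # real data carries no settlement labels: no block moves
        manyatta = np.full(n, -1)
    uniq = np.unique(manyatta[manyatta >= 0])
    aband_flags = rng.random(len(uniq)) < params.abandon_prob
    aband_set = set(uniq[aband_flags].tolist())
    abandoned = np.array([m in aband_set for m in manyatta])

    # one shared displacement per abandoned manyatta
    shift = {
        m: _displacement(rng, 1, params.abandon_scale, params.abandon_sigma)
        for m in sorted(aband_set)
    }
    for m, (dx, dy) in shift.items():
        sel = manyatta == m
        x[sel] += dx
        y[sel] += dy

    movers = (~abandoned) & (rng.random(n) < params.move_prob)
    n_mov = int(movers.sum())
    if n_mov:
        dx, dy = _displacement(
            rng, n_mov, params.displacement_scale, params.displacement_sigma
        )
        x[movers] += dx
        y[movers] += dy

    dist = np.hypot(x - points["x"].to_numpy(float), y - points["y"].to_numpy(float))
    return pd.DataFrame(
        {
            "id": points["id"].to_numpy(),
            "new_x": x,
            "new_y": y,
            "moved": movers | abandoned,
            "abandoned": abandoned,
            "distance": dist,
        }
    )


def _displacement(
    rng: np.random.Generator, n: int, median: float, sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    """n random planar displacements: uniform direction, lognormal
    magnitude with the given median."""
    r = rng.lognormal(np.log(median), sigma, n)
    theta = rng.uniform(0, 2 * np.pi, n)
    dx, dy = r * np.cos(theta), r * np.sin(theta)
    if n == 1:
        return float(dx[0]), float(dy[0])
    return dx, dy


def field_observations(movement: pd.DataFrame) -> pd.DataFrame:
    """Positions as a field team would observe them.

    Households of abandoned manyattas leave no trace (NaN coordinates —
    untraceable); everyone else is observed at their fieldwork-time
    position.
    """
    obs = movement[["id", "new_x", "new_y"]].rename(
        columns={"new_x": "x", "new_y": "y"}
    ).copy()
    gone = movement["abandoned"].to_numpy()
    obs.loc[gone, ["x", "y"]] = np.nan
    return obs


def gen_outcomes(points: pd.DataFrame, params: OutcomeParams) -> pd.DataFrame:
    """Per-household snakebite outcomes under the density model.

    Returns a table with columns id, persons, cases, risk, density_z.
    Cases are Binomial(persons, risk) per household; local density is the
    number of inhabited households within ``density_bandwidth`` meters
    (standardised across households).
    """
    rng = np.random.default_rng(params.seed)
    n = len(points)
    persons = points["size"].to_numpy(int) if "size" in points.columns else np.ones(n, int)
    xy = points[["x", "y"]].to_numpy(float)
    mask = points["inhabited"].to_numpy(bool) if "inhabited" in points.columns else np.ones(n, bool)

    if params.baseline_prevalence == 0:
        risk = np.zeros(n)
    else:
        tree = cKDTree(xy[mask])
        density = np.asarray(
            tree.query_ball_point(xy, params.density_bandwidth, return_length=True),
            dtype=float,
        )
        sd = density.std()
        z = (density - density.mean()) / sd if sd > 0 else np.zeros(n)
        risk = expit(logit(params.baseline_prevalence) + params.density_coefficient * z)
    cases = rng.binomial(persons, risk)
    out = pd.DataFrame(
        {
            "id": points["id"].to_numpy(),
            "persons": persons,
            "cases": cases,
            "risk": risk,
        }
    )
    if params.baseline_prevalence != 0:
        out["density_z"] = z
    else:
        out["density_z"] = 0.0
    return out


def true_prevalence(points: pd.DataFrame, outcomes: pd.DataFrame) -> float:
    """Census identity: population prevalence among persons of inhabited
    households, by full enumeration."""
    merged = points[["id", "inhabited"]].merge(outcomes, on="id")
    inh = merged[merged["inhabited"]]
    return float(inh["cases"].sum() / inh["persons"].sum())
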