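"""Systematic PPS selection of grid cells and within-cell household draws.

First stage: clusters (grid cells) are selected with probability
proportional to estimated population using the classic systematic scheme —
a sampling interval SI = floor(total / n_clusters), a uniform random start
RS in [1, SI], and the series RS, RS + SI, ..., RS + (n-1)·SI walked
against the cells' cumulative population in frame (row-major) order.
Second stage: a simple random sample of k households without replacement
inside each selected cell.  A cell whose cumulative interval contains m
series values is selected with multiplicity m and contributes m·k
households.

Design weights follow: pi = pi_cluster x (k_drawn / N_g) with
pi_cluster = min(1, n·pop_g / total).  With a constant mean household
size and no shortfalls this is self-weighting (all weights equal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frame import GriddedFrame

__all__ = [
    "PPSPlan",
    "Selection",
    "sampling_interval",
    "random_start",
    "start_series",
    "make_plan",
    "pps_select",
    "draw_households",
    "sample_households",
    "design_weights",
    "sample",
]

DEFAULT_N_CLUSTERS = 36
DEFAULT_K_HOUSEHOLDS = 25


@dataclass(frozen=True)
class PPSPlan:
    """Parameters of one systematic PPS draw."""

    n_clusters: int
    k_households: int
    si: int
    rs: int
    series: tuple[int, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.rs <= self.si:
            raise ValueError(f"random start {self.rs} outside [1, {self.si}]")
        expected = tuple(self.rs + j * self.si for j in range(self.n_clusters))
        if self.series != expected:
            raise ValueError("series inconsistent with RS + j*SI")


@dataclass(frozen=True)
class Selection:
    """A selected cluster with its cumulative interval and multiplicity."""

    cell_id: str
    multiplicity: int
    cum_lo: float
    cum_hi: float
    pi_cluster: float


def sampling_interval(total_population: float, n_clusters: int) -> int:
    """SI = floor(total population / number of clusters)."""
    if n_clusters <= 0:
        raise ValueError(f"n_clusters must be positive, got {n_clusters}")
    if total_population < n_clusters:
        raise ValueError(
            f"total population {total_population} smaller than n_clusters {n_clusters}"
        )
    return int(total_population // n_clusters)


def random_start(si: int, rng: np.random.Generator) -> int:
    """Uniform random integer in [1, SI]."""
    if si < 1:
        raise ValueError(f"sampling interval must be >= 1, got {si}")
    return int(rng.integers(1, si + 1))


def start_series(rs: int, si: int, n_clusters: int) -> np.ndarray:
    """The selection numbers RS + j*SI for j = 0 .. n_clusters-1."""
    if not 1 <= rs <= si:
        raise ValueError(f"random start {rs} outside [1, {si}]")
    return rs + si * np.arange(n_clusters, dtype=np.int64)


def make_plan(
    total_population: float,
    n_clusters: int = DEFAULT_N_CLUSTERS,
    k_households: int = DEFAULT_K_HOUSEHOLDS,
    seed: int | None = None,
    rs: int | None = None,
) -> PPSPlan:
    """Build a PPSPlan; ``rs`` may be supplied directly to replay a draw."""
    si = sampling_interval(total_population, n_clusters)
    if rs is None:
        rs = random_start(si, np.random.default_rng(seed))
    series = tuple(int(v) for v in start_series(rs, si, n_clusters))
    return PPSPlan(
        n_clusters=n_clusters,
        k_households=k_households,
        si=si,
        rs=int(rs),
        series=series,
        seed=seed,
    )


def pps_select(frame: GriddedFrame, series: np.ndarray | list[int]) -> list[Selection]:
    """Select the cells whose cumulative-population intervals contain the
    series values.

    Cells are walked in frame order; cell g owns the half-open-from-below
    interval (cum_lo, cum_hi].  Multiplicity is the number of series values
    in the interval; sum of multiplicities always equals len(series).
    """
    series = np.asarray(series, dtype=float)
    total = frame.total_population
    if np.any(series <= 0) or np.any(series > total):
        bad = series[(series <= 0) | (series > total)]
        raise ValueError(
            f"series values {bad.tolist()} outside (0, total_population={total}]"
        )
    n = len(series)
    pops = np.array([c.est_population for c in frame.cells], dtype=float)
    cum_hi = np.cumsum(pops)
    cum_lo = cum_hi - pops
    # value v selects cell g iff cum_lo[g] < v <= cum_hi[g]
    idx = np.searchsorted(cum_hi, series, side="left")
    selections: list[Selection] = []
    for g in np.unique(idx):
        m = int(np.sum(idx == g))
        cell = frame.cells[int(g)]
        selections.append(
            Selection(
                cell_id=cell.cell_id,
                multiplicity=m,
                cum_lo=float(cum_lo[g]),
                cum_hi=float(cum_hi[g]),
                pi_cluster=min(1.0, n * cell.est_population / total),
            )
        )
    return selections


def draw_households(
    cell_id: str,
    frame: GriddedFrame,
    k_households: int,
    rng: np.random.Generator,
    multiplicity: int = 1,
) -> pd.DataFrame:
    """Simple random sample without replacement of inhabited households
    in one cell.

    Draws multiplicity x k households, capped at the number available; a
    shortfall (fewer inhabited households than requested) takes all and
    flags every row, never silently under-reports.
    """
    if k_households < 1:
        raise ValueError(f"k_households must be >= 1, got {k_households}")
    pool = frame.households_in_cell(cell_id, inhabited_only=True)
    want = multiplicity * k_households
    n_avail = len(pool)
    take = min(want, n_avail)
    chosen = rng.choice(n_avail, size=take, replace=False) if take else np.array([], int)
    out = pool.iloc[np.sort(chosen)][["id", "x", "y"]].copy()
    out.insert(1, "cell_id", cell_id)
    out["n_inhabited"] = n_avail
    out["k_drawn"] = take
    out["shortfall"] = take < want
    return out.reset_index(drop=True)


def sample_households(
    frame: GriddedFrame,
    selections: list[Selection],
    k_households: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw households in every selected cluster; concatenated roster."""
    parts = [
        draw_households(s.cell_id, frame, k_households, rng, s.multiplicity)
        for s in selections
    ]
    roster = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["id", "cell_id", "x", "y", "n_inhabited", "k_drawn", "shortfall"]
    )
    return roster


def design_weights(
    frame: GriddedFrame,
    selections: list[Selection],
    roster: pd.DataFrame,
) -> pd.DataFrame:
    """Attach inclusion probabilities and weights to a household roster.

    pi = pi_cluster x (k_drawn / N_g_inhabited); weight = 1 / pi.
    """
    by_cell = {s.cell_id: s for s in selections}
    pis = np.empty(len(roster))
    for i, (cid, kd, n_inh) in enumerate(
        zip(roster["cell_id"], roster["k_drawn"], roster["n_inhabited"])
    ):
        sel = by_cell[cid]
        if n_inh == 0:
            raise ValueError(f"selected cell {cid} has no inhabited households")
        pis[i] = sel.pi_cluster * (kd / n_inh)
    out = roster.copy()
    out["pi"] = pis
    out["weight"] = 1.0 / pis
    return out


def sample(
    frame: GriddedFrame,
    n_clusters: int = DEFAULT_N_CLUSTERS,
    k_households: int = DEFAULT_K_HOUSEHOLDS,
    seed: int | None = None,
    rs: int | None = None,
) -> tuple[PPSPlan, list[Selection], pd.DataFrame]:
    """Full two-stage draw: plan, cluster selection, weighted roster."""
    plan = make_plan(frame.total_population, n_clusters, k_households, seed=seed, rs=rs)
    selections = pps_select(frame, np.array(plan.series))
    rng = np.random.default_rng(None if seed is None else seed + 1)
    roster = sample_households(frame, selections, k_households, rng)
    roster = design_weights(frame, selections, roster)
    return plan, selections, roster
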