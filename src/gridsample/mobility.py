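"""Household mobility between mapping and fieldwork, and the field rules
that resolve it.

Between the time a satellite-derived frame is digitised and the day a
field team arrives, pastoralist households move.  The rules implemented
here mirror standard field practice for grid-based designs:

* a household found at (or within GPS noise of) its mapped position is
  surveyed in place;
* a household that moved within the *relocate radius* (default 5 km) is
  followed and attributed back to its original grid, on the assumption
  that the mapped location was its true residence;
* a household that moved beyond the *replace radius* (default 10 km) is
  replaced by a fresh random draw from the same grid's remaining frame;
* a grid in which no sampled household can be found at all is abandoned,
  and its full planned take is oversampled from a nearby grid.

Distances in the intermediate band (5-10 km by default) are governed by a
configurable ``band_rule`` (default: replace).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .frame import GriddedFrame
from .sampling import Selection

__all__ = [
    "IN_PLACE",
    "RELOCATED",
    "REPLACED",
    "UNTRACEABLE",
    "AS_PLANNED",
    "GRID_RELOCATED",
    "GRID_REPLACED",
    "ABANDONED",
    "MobilityPolicy",
    "MovementRecord",
    "FieldRoster",
    "classify_household",
    "classify_households",
    "classify_grid",
    "resolve",
    "tabulate",
    "round_half_up_pct",
]

# household movement statuses
IN_PLACE = "IN_PLACE"
RELOCATED = "RELOCATED"
REPLACED = "REPLACED"
UNTRACEABLE = "UNTRACEABLE"
HH_STATUSES = (IN_PLACE, RELOCATED, REPLACED, UNTRACEABLE)

# grid outcomes (precedence ABANDONED > REPLACED > RELOCATED > AS_PLANNED)
AS_PLANNED = "AS_PLANNED"
GRID_RELOCATED = "RELOCATED"
GRID_REPLACED = "REPLACED"
ABANDONED = "ABANDONED"
GRID_OUTCOMES = (AS_PLANNED, GRID_RELOCATED, GRID_REPLACED, ABANDONED)


@dataclass(frozen=True)
class MobilityPolicy:
    """Field-resolution thresholds and rules.

    relocate_radius, replace_radius : meters.  band_rule governs distances
    in (relocate_radius, replace_radius]: "replace" (default, conservative)
    or "relocate".  nearby_rule picks the donor grid for abandoned-grid
    oversampling: "nearest" (nearest non-abandoned frame cell by centroid,
    ties broken by cell_id) or "nearest_selected".  gps_tolerance is the
    consumer-GPS noise radius within which a household counts as in place.
    """

    relocate_radius: float = 5_000.0
    replace_radius: float = 10_000.0
    band_rule: str = "replace"
    nearby_rule: str = "nearest"
    gps_tolerance: float = 25.0

    def __post_init__(self) -> None:
        if not 0 < self.relocate_radius <= self.replace_radius:
            raise ValueError(
                f"need 0 < relocate_radius <= replace_radius, got "
                f"{self.relocate_radius}, {self.replace_radius}"
            )
        if self.band_rule not in ("replace", "relocate"):
            raise ValueError(f"unknown band_rule {self.band_rule!r}")
        if self.nearby_rule not in ("nearest", "nearest_selected"):
            raise ValueError(f"unknown nearby_rule {self.nearby_rule!r}")


@dataclass(frozen=True)
class MovementRecord:
    household_id: str
    original_xy: tuple[float, float]
    observed_xy: tuple[float, float] | None
    distance: float | None
    status: str


@dataclass
class FieldRoster:
    """The sample as finally surveyed.

    ``roster`` rows carry: id, cell_id (attributed grid), x, y, source
    (original | relocated | replacement | oversample), origin_cell_id (the
    planned grid the row's slot belongs to) and weight.  ``outcomes`` is
    the per-grid outcome table; ``shortfalls`` lists grids whose
    replacement or backfill capacity ran out (never silently truncated).
    """

    roster: pd.DataFrame
    outcomes: pd.DataFrame
    records: pd.DataFrame
    shortfalls: list[dict] = field(default_factory=list)


def classify_household(
    original_xy: tuple[float, float],
    observed_xy: tuple[float, float] | None,
    policy: MobilityPolicy = MobilityPolicy(),
) -> MovementRecord:
    """Classify one household's movement status from its displacement."""
    if observed_xy is None or any(
        v is None or (isinstance(v, float) and math.isnan(v)) for v in observed_xy
    ):
        return MovementRecord(
            household_id="", original_xy=tuple(original_xy), observed_xy=None,
            distance=None, status=UNTRACEABLE,
        )
    d = math.dist(original_xy, observed_xy)
    if d <= policy.gps_tolerance:
        status = IN_PLACE
    elif d <= policy.relocate_radius:
        status = RELOCATED
    elif d <= policy.replace_radius:
        status = REPLACED if policy.band_rule == "replace" else RELOCATED
    else:
        status = REPLACED
    return MovementRecord(
        household_id="", original_xy=tuple(original_xy),
        observed_xy=tuple(observed_xy), distance=d, status=status,
    )


def classify_households(
    roster: pd.DataFrame,
    observed: pd.DataFrame,
    policy: MobilityPolicy = MobilityPolicy(),
) -> pd.DataFrame:
    """Vectorised movement classification for a sampled roster.

    ``observed`` has columns id, x, y; households absent from it (or with
    NaN coordinates) are untraceable.  Returns a record table with columns
    id, cell_id, distance, status.
    """
    obs = observed.set_index("id")[["x", "y"]] if len(observed) else pd.DataFrame(
        columns=["x", "y"]
    )
    ox = roster["id"].map(obs["x"]) if len(obs) else pd.Series(np.nan, index=roster.index)
    oy = roster["id"].map(obs["y"]) if len(obs) else pd.Series(np.nan, index=roster.index)
    dist = np.hypot(
        ox.to_numpy(float) - roster["x"].to_numpy(float),
        oy.to_numpy(float) - roster["y"].to_numpy(float),
    )
    status = np.full(len(roster), UNTRACEABLE, dtype=object)
    found = np.isfinite(dist)
    band_status = REPLACED if policy.band_rule == "replace" else RELOCATED
    status[found & (dist <= policy.gps_tolerance)] = IN_PLACE
    status[found & (dist > policy.gps_tolerance) & (dist <= policy.relocate_radius)] = RELOCATED
    status[found & (dist > policy.relocate_radius) & (dist <= policy.replace_radius)] = band_status
    status[found & (dist > policy.replace_radius)] = REPLACED
    return pd.DataFrame(
        {
            "id": roster["id"].to_numpy(),
            "cell_id": roster["cell_id"].to_numpy(),
            "distance": dist,
            "status": status,
        }
    )


def classify_grid(statuses: Sequence[str] | pd.Series) -> str:
    """Grid outcome from its households' movement statuses.

    Precedence: ABANDONED (nothing found at all) > REPLACED (any household
    replaced or untraceable) > RELOCATED (any relocated) > AS_PLANNED.
    """
    statuses = list(statuses)
    if not statuses:
        raise ValueError("cannot classify a grid with no classified households")
    if all(s == UNTRACEABLE for s in statuses):
        return ABANDONED
    if any(s in (REPLACED, UNTRACEABLE) for s in statuses):
        return GRID_REPLACED
    if any(s == RELOCATED for s in statuses):
        return GRID_RELOCATED
    return AS_PLANNED


def _nearest_donor(
    frame: GriddedFrame,
    abandoned_id: str,
    abandoned_ids: set[str],
    needed: int,
    used_ids: set[str],
    selections: Sequence[Selection] | None,
    policy: MobilityPolicy,
) -> str | None:
    """Nearest non-abandoned cell with enough unused inhabited households."""
    cx, cy = frame.cell(abandoned_id).centroid
    if policy.nearby_rule == "nearest_selected" and selections is not None:
        candidates = [frame.cell(s.cell_id) for s in selections]
    else:
        candidates = frame.cells
    ranked = sorted(
        (c for c in candidates if c.cell_id not in abandoned_ids),
        key=lambda c: (math.dist((cx, cy), c.centroid), c.cell_id),
    )
    for c in ranked:
        pool = frame.households_in_cell(c.cell_id, inhabited_only=True)
        if (~pool["id"].isin(used_ids)).sum() >= needed:
            return c.cell_id
    return None


def resolve(
    roster: pd.DataFrame,
    records: pd.DataFrame,
    frame: GriddedFrame,
    policy: MobilityPolicy = MobilityPolicy(),
    rng: np.random.Generator | None = None,
    selections: Sequence[Selection] | None = None,
) -> FieldRoster:
    """Apply the field rules to a classified sample and produce the final
    roster.

    Kept households keep their design weight; replacement and oversample
    rows inherit the weight of the planned slot they fill, so the planned
    design (and roster size) is preserved whenever capacity suffices.
    """
    if rng is None:
        rng = np.random.default_rng()
    rec = records.set_index("id")
    status_by_cell = records.groupby("cell_id", sort=False)["status"]
    outcomes = {cid: classify_grid(s) for cid, s in status_by_cell}
    abandoned = {cid for cid, o in outcomes.items() if o == ABANDONED}

    used_ids: set[str] = set(roster["id"])
    rows: list[dict] = []
    shortfalls: list[dict] = []
    has_weight = "weight" in roster.columns

    for cell_id, group in roster.groupby("cell_id", sort=False):
        outcome = outcomes[cell_id]
        if outcome == ABANDONED:
            needed = len(group)
            donor = _nearest_donor(
                frame, cell_id, abandoned, needed, used_ids, selections, policy
            )
            if donor is None:
                shortfalls.append(
                    {"cell_id": cell_id, "needed": needed, "filled": 0,
                     "reason": "no donor grid with capacity"}
                )
                continue
            pool = frame.households_in_cell(donor, inhabited_only=True)
            pool = pool[~pool["id"].isin(used_ids)].reset_index(drop=True)
            pick = rng.choice(len(pool), size=needed, replace=False)
            weights = group["weight"].to_numpy() if has_weight else [np.nan] * needed
            for slot_w, (_, hh) in zip(weights, pool.iloc[np.sort(pick)].iterrows()):
                used_ids.add(hh["id"])
                rows.append(
                    {"id": hh["id"], "cell_id": donor, "x": hh["x"], "y": hh["y"],
                     "source": "oversample", "origin_cell_id": cell_id,
                     "weight": slot_w}
                )
            continue
        # non-abandoned grid: keep, relocate, or replace row by row
        replacements_needed = []
        for _, row in group.iterrows():
            status = rec.loc[row["id"], "status"]
            w = row["weight"] if has_weight else np.nan
            if status in (IN_PLACE, RELOCATED):
                rows.append(
                    {"id": row["id"], "cell_id": cell_id, "x": row["x"], "y": row["y"],
                     "source": "original" if status == IN_PLACE else "relocated",
                     "origin_cell_id": cell_id, "weight": w}
                )
            else:  # REPLACED or UNTRACEABLE: substitute from the same grid
                replacements_needed.append(w)
        if replacements_needed:
            pool = frame.households_in_cell(cell_id, inhabited_only=True)
            pool = pool[~pool["id"].isin(used_ids)].reset_index(drop=True)
            n_fill = min(len(replacements_needed), len(pool))
            if n_fill < len(replacements_needed):
                shortfalls.append(
                    {"cell_id": cell_id, "needed": len(replacements_needed),
                     "filled": n_fill, "reason": "replacement pool exhausted"}
                )
            if n_fill:
                pick = rng.choice(len(pool), size=n_fill, replace=False)
                for w, (_, hh) in zip(
                    replacements_needed[:n_fill], pool.iloc[np.sort(pick)].iterrows()
                ):
                    used_ids.add(hh["id"])
                    rows.append(
                        {"id": hh["id"], "cell_id": cell_id, "x": hh["x"], "y": hh["y"],
                         "source": "replacement", "origin_cell_id": cell_id,
                         "weight": w}
                    )

    roster_out = pd.DataFrame(
        rows, columns=["id", "cell_id", "x", "y", "source", "origin_cell_id", "weight"]
    )
    outcome_df = pd.DataFrame(
        {"cell_id": list(outcomes), "outcome": [outcomes[c] for c in outcomes]}
    )
    return FieldRoster(
        roster=roster_out, outcomes=outcome_df, records=records,
        shortfalls=shortfalls,
    )


def round_half_up_pct(count: int, denom: int, decimals: int = 1) -> float:
    """Percentage rounded half-up to ``decimals`` places."""
    if denom == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(count) * 100 / Decimal(denom)).quantize(q, rounding=ROUND_HALF_UP)
    )


def tabulate(
    records: pd.DataFrame | None = None,
    outcomes: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Outcome tables with counts, explicit denominators, and percentages
    (round-half-up, one decimal).

    Returns a dict with keys "households" (movement-status counts) and/or
    "grids" (grid-outcome counts), depending on what was supplied.
    """
    tables: dict[str, pd.DataFrame] = {}
    if records is not None:
        n = len(records)
        counts = records["status"].value_counts()
        tables["households"] = pd.DataFrame(
            {
                "status": HH_STATUSES,
                "count": [int(counts.get(s, 0)) for s in HH_STATUSES],
                "denominator": n,
                "percent": [round_half_up_pct(int(counts.get(s, 0)), n) for s in HH_STATUSES],
            }
        )
    if outcomes is not None:
        n = len(outcomes)
        counts = outcomes["outcome"].value_counts()
        tables["grids"] = pd.DataFrame(
            {
                "outcome": GRID_OUTCOMES,
                "count": [int(counts.get(o, 0)) for o in GRID_OUTCOMES],
                "denominator": n,
                "percent": [round_half_up_pct(int(counts.get(o, 0)), n) for o in GRID_OUTCOMES],
            }
        )
    return tables
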