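"""Systematic PPS selection and within-cell household draws.

The independent oracle for pps_select is a brute-force per-value linear
scan over the cumulative population intervals.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from gridsample.sampling import (
    design_weights,
    draw_households,
    make_plan,
    pps_select,
    random_start,
    sample,
    sample_households,
    sampling_interval,
    start_series,
)

from conftest import make_toy_frame


def brute_force_select(populations, series):
    """Oracle: for each series value walk the cells accumulating
    population and return the first cell whose cumulative total reaches
    the value.  Independent of the vectorised implementation."""
    hits = {}
    for v in series:
        cum = 0.0
        for g, p in enumerate(populations):
            if cum < v <= cum + p:
                hits[g] = hits.get(g, 0) + 1
                break
            cum += p
    return hits


class TestSamplingInterval:
    @pytest.mark.parametrize(
        "total, n, expected",
        [
            (405_656, 36, 11_268),  # 50,707 households x 8 persons / 36
            (100, 10, 10),
            (407, 36, 11),
        ],
    )
    def test_floor_division(self, total, n, expected):
        assert sampling_interval(total, n) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            sampling_interval(100, 0)
        with pytest.raises(ValueError):
            sampling_interval(10, 36)


class TestRandomStart:
    def test_si_one_forces_one(self):
        assert random_start(1, np.random.default_rng(0)) == 1

    def test_reproducible_under_seed(self):
        a = random_start(11_268, np.random.default_rng(42))
        b = random_start(11_268, np.random.default_rng(42))
        assert a == b and 1 <= a <= 11_268

    def test_uniform_over_range(self):
        rng = np.random.default_rng(7)
        draws = [random_start(10, rng) for _ in range(10_000)]
        freq = np.bincount(draws, minlength=11)[1:]
        assert stats.chisquare(freq).pvalue > 1e-3


class TestStartSeries:
    def test_replay_printed_draw(self):
        series = start_series(3_374, 11_268, 36)
        assert list(series[:3]) == [3_374, 14_642, 25_910]
        assert len(series) == 36
        assert series[-1] == 397_754 <= 405_656

    def test_unit_interval(self):
        assert list(start_series(1, 1, 3)) == [1, 2, 3]

    def test_rs_out_of_range(self):
        with pytest.raises(ValueError):
            start_series(0, 10, 3)
        with pytest.raises(ValueError):
            start_series(11, 10, 3)


class TestPPSSelect:
    def test_symmetric_case(self):
        frame = make_toy_frame([100, 100, 100])
        sel = pps_select(frame, [50, 150, 250])
        assert [s.cell_id for s in sel] == [c.cell_id for c in frame.cells]
        assert all(s.multiplicity == 1 for s in sel)

    def test_multiplicity_on_dominant_cell(self):
        frame = make_toy_frame([10, 990])
        sel = pps_select(frame, [300, 800])
        assert len(sel) == 1
        assert sel[0].cell_id == frame.cells[1].cell_id
        assert sel[0].multiplicity == 2
        assert (sel[0].cum_lo, sel[0].cum_hi) == (10, 1000)
        assert sel[0].pi_cluster == 1.0  # 2 * 990/1000 capped

    def test_series_value_out_of_range_rejected(self):
        frame = make_toy_frame([100, 100])
        with pytest.raises(ValueError, match="series"):
            pps_select(frame, [250])

    def test_oracle_equivalence_random_frames(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n_cells = rng.integers(1, 51)
            pops = rng.integers(0, 200, n_cells).astype(float)
            if pops.sum() < 1:
                continue
            total = pops.sum()
            n = int(rng.integers(1, 8))
            si = int(total // n)
            if si < 1:
                continue
            rs = int(rng.integers(1, si + 1))
            series = start_series(rs, si, n)
            frame = make_toy_frame(pops)
            got = {s.cell_id: s.multiplicity for s in pps_select(frame, series)}
            want = {
                frame.cells[g].cell_id: m
                for g, m in brute_force_select(pops, series).items()
            }
            assert got == want

    @given(
        st.lists(st.integers(0, 100), min_size=1, max_size=30).filter(
            lambda p: sum(p) >= 5
        ),
        st.integers(1, 5),
        st.randoms(use_true_random=False),
    )
    def test_multiplicities_sum_to_series_length(self, pops, n, rnd):
        total = sum(pops)
        si = total // n
        if si < 1:
            return
        rs = rnd.randint(1, si)
        frame = make_toy_frame([float(p) for p in pops])
        sel = pps_select(frame, start_series(rs, si, n))
        assert sum(s.multiplicity for s in sel) == n


class TestDrawHouseholds:
    def _frame(self, n_points, cell_size=1000.0, seed=0):
        import pandas as pd

        from gridsample.frame import build_frame, Boundary
        from shapely.geometry import box

        rng = np.random.default_rng(seed)
        pts = pd.DataFrame(
            {
                "id": [f"h{i}" for i in range(n_points)],
                "x": rng.uniform(0, cell_size, n_points),
                "y": rng.uniform(0, cell_size, n_points),
                "inhabited": True,
            }
        )
        return build_frame(Boundary(box(0, 0, cell_size, cell_size)), pts, cell_size)

    def test_exact_take_all(self):
        frame = self._frame(25)
        out = draw_households(frame.cells[0].cell_id, frame, 25, np.random.default_rng(0))
        assert len(out) == 25 and not out["shortfall"].any()

    def test_deterministic_subset(self):
        frame = self._frame(100)
        cid = frame.cells[0].cell_id
        a = draw_households(cid, frame, 25, np.random.default_rng(5))
        b = draw_households(cid, frame, 25, np.random.default_rng(5))
        assert list(a["id"]) == list(b["id"])

    def test_shortfall_takes_all_and_flags(self):
        frame = self._frame(10)
        out = draw_households(frame.cells[0].cell_id, frame, 25, np.random.default_rng(0))
        assert len(out) == 10 and out["shortfall"].all()

    def test_hypergeometric_inclusion_frequency(self):
        """Each of 4 households should appear in ~half of 2-of-4 draws."""
        frame = self._frame(4)
        cid = frame.cells[0].cell_id
        rng = np.random.default_rng(9)
        reps = 20_000
        counts = {f"h{i}": 0 for i in range(4)}
        for _ in range(reps):
            for hid in draw_households(cid, frame, 2, rng)["id"]:
                counts[hid] += 1
        se = np.sqrt(0.5 * 0.5 / reps)
        for hid, c in counts.items():
            assert abs(c / reps - 0.5) < 4 * se, hid


class TestDesignWeights:
    def test_two_cell_hand_computation(self):
        # cells with 40 and 60 inhabited households, unit mean size,
        # one cluster, k=10: both cells weight exactly 10
        frame = make_toy_frame([40.0, 60.0])
        for g, (N, pi_cl) in enumerate([(40, 0.4), (60, 0.6)]):
            sel = pps_select(frame, [frame.cells[g].est_population - 1])
            import pandas as pd

            roster = pd.DataFrame(
                {
                    "id": ["a"],
                    "cell_id": [frame.cells[g].cell_id],
                    "x": [0.0],
                    "y": [0.0],
                    "n_inhabited": [N],
                    "k_drawn": [10],
                    "shortfall": [False],
                }
            )
            out = design_weights(frame, sel, roster)
            assert out["pi"].iloc[0] == pytest.approx(pi_cl * 10 / N)
            assert out["weight"].iloc[0] == pytest.approx(10.0)

    def test_self_weighting_on_real_frame(self, dense_frame):
        """Constant mean household size + no shortfalls => equal weights."""
        _, _, roster = sample(dense_frame, 12, 20, seed=3)
        assert not roster["shortfall"].any()
        w = roster["weight"].to_numpy()
        assert np.max(w) - np.min(w) <= 1e-9 * np.max(w)

    def test_single_cell_take_all_weights_one(self):
        frame = make_toy_frame([30.0])
        sel = pps_select(frame, [15])
        rng = np.random.default_rng(0)
        # materialise 30 points in the single cell
        import pandas as pd

        from gridsample.frame import Boundary, GriddedFrame
        from shapely.geometry import box

        pts = pd.DataFrame(
            {
                "id": [f"h{i}" for i in range(30)],
                "x": rng.uniform(0, 1000, 30),
                "y": rng.uniform(0, 500, 30),
                "inhabited": True,
            }
        )
        frame = GriddedFrame(
            boundary=frame.boundary,
            cells=[frame.cells[0]],
            points=pts,
            assignment={f"h{i}": frame.cells[0].cell_id for i in range(30)},
        )
        roster = sample_households(frame, sel, 30, rng)
        out = design_weights(frame, sel, roster)
        assert (out["pi"] == 1.0).all()
        assert (out["weight"] == 1.0).all()


def test_pps_empirical_probability_matches_pi():
    """Over many random starts, each cell's selection frequency matches
    min(1, n * pop_g / total) within binomial error."""
    rng = np.random.default_rng(20)
    pops = rng.integers(200, 1_000, 20).astype(float)
    frame = make_toy_frame(pops)
    total = pops.sum()
    n = 5
    si = int(total // n)
    reps = 4_000
    hits = np.zeros(20)
    for _ in range(reps):
        rs = int(rng.integers(1, si + 1))
        for s in pps_select(frame, start_series(rs, si, n)):
            g = int(s.cell_id[-3:])
            hits[g] += 1
    expected = np.minimum(1.0, n * pops / total)
    se = np.sqrt(expected * (1 - expected) / reps)
    assert np.all(np.abs(hits / reps - expected) <= 3 * se + 1e-12)
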