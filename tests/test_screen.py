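"""Frame averaging, grid LMM screen, BH-FDR, clusters, ERD/ERS split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from betapipe._errors import DataError
from betapipe.screen import (
    FRAME_CENTERS_MS,
    FrameGrid,
    ScreenResult,
    bh_mask,
    extract_clusters,
    fit_lmm_cell,
    frame_average,
    frames_in_window,
    screen_frames,
    split_by_sign,
)
from betapipe.synth_meg import make_layout, simulate_null_frames
from betapipe.tfr import BetaPowerGrid

from conftest import make_labeled_frame


def _grid(values, times):
    return BetaPowerGrid(
        values=values, times_ms=times,
        baseline_db=np.zeros(values.shape[1]),
        trial_rows=np.arange(values.shape[0]),
    )


class TestFrames:
    def test_17_frames(self):
        assert len(FRAME_CENTERS_MS) == 17
        assert FRAME_CENTERS_MS[0] == -800.0
        assert FRAME_CENTERS_MS[-1] == 2400.0

    def test_grid_is_1734_cells(self):
        assert len(FRAME_CENTERS_MS) * 102 == 1734

    def test_constant_input_gives_constant_frames(self):
        times = np.arange(-900.0, 2500.0, 25.0)
        values = np.full((2, 3, len(times)), 1.25)
        frames = frame_average(_grid(values, times))
        assert frames.values.shape == (2, 3, 17)
        np.testing.assert_allclose(frames.values, 1.25)

    def test_each_frame_has_8_points(self):
        # frames tile the lattice without overlap
        times = np.arange(-900.0, 2500.0, 25.0)
        values = np.zeros((1, 1, len(times)))
        for i, c in enumerate(FRAME_CENTERS_MS):
            sel = (times >= c - 100 - 1e-9) & (times < c + 100 - 1e-9)
            assert sel.sum() == 8
            values[0, 0, sel] = i
        frames = frame_average(_grid(values, times))
        np.testing.assert_allclose(frames.values[0, 0], np.arange(17))

    def test_missing_coverage_raises(self):
        times = np.arange(-800.0, 2500.0, 25.0)  # first frame unsupported
        with pytest.raises(DataError):
            frame_average(_grid(np.zeros((1, 1, len(times))), times))

    def test_frames_in_window(self):
        assert frames_in_window((-900.0, -300.0)) == [0, 1, 2]
        assert frames_in_window((1100.0, 1500.0)) == [10, 11]
        assert frames_in_window((1500.0, 1900.0)) == [12, 13]
        with pytest.raises(DataError):
            frames_in_window((10.0, 20.0))


class TestBH:
    def test_hand_example(self):
        # oracle: step-up by hand; thresholds q*i/m = .0125,.025,.0375,.05
        p = np.array([0.001, 0.02, 0.03, 0.5])
        np.testing.assert_array_equal(bh_mask(p, 0.05), [True, True, True, False])

    def test_all_ones_empty(self):
        assert not bh_mask(np.ones((5, 4))).any()

    def test_against_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(10):
            p = rng.random(200) ** 2
            mine = bh_mask(p, 0.05)
            oracle = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            np.testing.assert_array_equal(mine, oracle)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_monotonicity(self, seed):
        r = np.random.default_rng(seed)
        p = r.random(50)
        base = bh_mask(p, 0.05)
        i = int(r.integers(0, 50))
        lowered = p.copy()
        lowered[i] = p[i] / 2
        keep = base.copy()
        keep[i] = False
        # lowering any p never removes another discovery
        assert bh_mask(lowered, 0.05)[keep].all()

    def test_out_of_range_raises(self):
        with pytest.raises(DataError):
            bh_mask(np.array([0.5, 1.5]))


class TestCellModel:
    def test_injected_effect_detected(self):
        rng = np.random.default_rng(0)
        labels = make_labeled_frame(20, 30, rng)
        y = rng.normal(0, 0.5, len(labels)) + np.where(labels["choice_type"] == "LP", 1.0, 0.0)
        ps = fit_lmm_cell(y, labels)
        assert ps["choice_type"] < 1e-6

    def test_single_subject_rejected(self, rng):
        labels = make_labeled_frame(1, 40, rng)
        with pytest.raises(DataError):
            fit_lmm_cell(rng.normal(size=len(labels)), labels)

    def test_empty_cell_rejected(self, rng):
        labels = make_labeled_frame(6, 30, rng)
        labels = labels[~((labels.choice_type == "LP") & (labels.feedback == "gain"))]
        with pytest.raises(DataError):
            fit_lmm_cell(rng.normal(size=len(labels)), labels)

    def test_null_p_uniform_over_grid(self):
        rng = np.random.default_rng(1)
        values, labels = simulate_null_frames(12, 25, 10, 4, rng)
        frames = FrameGrid(values=values, centers_ms=np.arange(4.0), width_ms=200.0,
                           trial_rows=np.arange(len(labels)))
        p_grids, ok = screen_frames(frames, labels)
        assert ok.all()
        ps = p_grids["choice_type"].ravel()
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestClusters:
    def test_persistence_rule(self):
        lay = make_layout(12)
        mask = np.ones((4, 12), dtype=bool)
        mask[2, 5] = False  # sensor 5 significant in only 3 of 4 frames
        kept = extract_clusters(mask, [0, 1, 2, 3], lay)
        assert 5 not in kept
        # oracle: single-pass pruning of the persistent set {0..11} \ {5}
        persistent = [s for s in range(12) if s != 5]
        expected = [
            s for s in persistent
            if len(set(lay.neighbors(s).tolist()) & set(persistent)) >= 2
        ]
        assert kept == expected

    def test_full_grid_keeps_all(self):
        lay = make_layout(102)
        mask = np.ones((3, 102), dtype=bool)
        assert extract_clusters(mask, [0, 1, 2], lay) == list(range(102))

    def test_neighbor_pruning_single_pass(self):
        lay = make_layout(30)
        # keep a sensor and exactly one of its neighbors: both pruned
        i = 0
        nb = lay.neighbors(i)
        mask = np.zeros((1, 30), dtype=bool)
        mask[0, [i, nb[0]]] = True
        assert extract_clusters(mask, [0], lay) == []
        # a sensor with two kept neighbors that are themselves connected
        trio = None
        for a in range(30):
            for b in lay.neighbors(a):
                common = set(lay.neighbors(a)) & set(lay.neighbors(b))
                if common:
                    trio = (a, int(b), int(sorted(common)[0]))
                    break
            if trio:
                break
        mask = np.zeros((1, 30), dtype=bool)
        mask[0, list(trio)] = True
        assert sorted(extract_clusters(mask, [0], lay)) == sorted(trio)

    def test_empty_window_raises(self):
        lay = make_layout(12)
        with pytest.raises(DataError):
            extract_clusters(np.ones((2, 12), dtype=bool), [], lay)


class TestSplitBySign:
    def test_all_negative_goes_to_erd(self, rng):
        means = -1.0 + 0.01 * rng.standard_normal((10, 6))
        out = split_by_sign(list(range(6)), means)
        assert out["ERD"] == list(range(6))
        assert out["ERS"] == []

    def test_exact_zero_mean_dropped(self):
        means = np.zeros((8, 3))
        out = split_by_sign([0, 1, 2], means)
        assert out["ERD"] == [] and out["ERS"] == []

    def test_mixed_signs_split(self, rng):
        means = np.concatenate(
            [np.full((12, 2), -2.0), np.full((12, 2), 2.0)], axis=1
        ) + 0.1 * rng.standard_normal((12, 4))
        out = split_by_sign([0, 1, 2, 3], means)
        assert out["ERD"] == [0, 1]
        assert out["ERS"] == [2, 3]

    def test_empty_cluster_raises(self, rng):
        with pytest.raises(DataError):
            split_by_sign([], rng.standard_normal((5, 3)))


class TestScreenResult:
    def test_json_round_trip(self, rng):
        res = ScreenResult(
            p_grids={"choice_type": rng.random((3, 4))},
            masks={"choice_type": rng.random((3, 4)) < 0.2},
            q=0.05,
            frame_centers_ms=np.array([-800.0, -600.0, -400.0]),
            windows={"decision": [0, 1, 2]},
            clusters=[{"name": "decision_erd", "effect": "choice_type",
                       "window": "decision", "sign": "ERD", "sensors": [1, 2]}],
            fit_ok=np.ones((3, 4), dtype=bool),
        )
        back = ScreenResult.from_json(res.to_json())
        np.testing.assert_allclose(back.p_grids["choice_type"], res.p_grids["choice_type"])
        np.testing.assert_array_equal(back.masks["choice_type"], res.masks["choice_type"])
        assert back.clusters == res.clusters
        assert back.windows == res.windows
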