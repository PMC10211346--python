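"""Effect-level analyses: pooled models, RT analyses, cross-trial regression."""

import numpy as np
import pandas as pd
import pytest

from betapipe._errors import DataError
from betapipe.effects import (
    beta_rt_regression,
    build_cross_trial_pairs,
    cross_trial_regression,
    pooled_effect_model,
    pooled_trial_values,
    rt_model,
    two_step_average,
    two_step_mean,
    within_level_contrast,
)
from betapipe.screen import FrameGrid
from betapipe.task_sim import CHOICE_TYPES

from conftest import make_labeled_frame


def _pooled(rng, n_subj=20, n_tr=40, cell_means=None, subj_sd=0.5, noise_sd=0.8):
    df = make_labeled_frame(n_subj, n_tr, rng)
    base = np.zeros(len(df))
    if cell_means:
        for (ct, fb), mu in cell_means.items():
            base += np.where((df["choice_type"] == ct) & (df["feedback"] == fb), mu, 0.0)
    subj_fx = dict(zip(sorted(df["subject_id"].unique()),
                       rng.normal(0, subj_sd, df["subject_id"].nunique())))
    df["beta_db"] = base + df["subject_id"].map(subj_fx) + rng.normal(0, noise_sd, len(df))
    return df


class TestTwoStepAveraging:
    def test_unbalanced_counts_weighted_equally(self):
        values = np.array([2.0] * 90 + [0.0] * 10)
        valence = np.array(["gain"] * 90 + ["loss"] * 10)
        assert two_step_mean(values, valence) == pytest.approx(1.0)

    def test_balanced_equals_flat_mean(self, rng):
        values = rng.normal(size=40)
        valence = np.array(["gain", "loss"] * 20)
        flat = values.mean()
        gains, losses = values[::2].mean(), values[1::2].mean()
        assert two_step_mean(values, valence) == pytest.approx((gains + losses) / 2)
        assert (gains + losses) / 2 == pytest.approx(flat, abs=1e-12)

    def test_duplicating_gain_trials_invariant(self, rng):
        values = rng.normal(size=20)
        valence = np.array(["gain"] * 12 + ["loss"] * 8)
        doubled = np.concatenate([values, values[:12]])
        val2 = np.concatenate([valence, ["gain"] * 12])
        assert two_step_mean(doubled, val2) == pytest.approx(two_step_mean(values, valence))

    def test_missing_valence_flagged(self):
        assert np.isnan(two_step_mean(np.ones(5), np.array(["gain"] * 5)))

    def test_dataframe_wrapper(self, rng):
        df = _pooled(rng, n_subj=4, n_tr=60)
        out = two_step_average(df)
        assert set(out.columns) == {"choice_type", "mean", "n", "n_missing"}
        assert (out["n"] + 0 >= 0).all()


class TestPooling:
    def test_pooled_values_are_plain_means(self, rng):
        values = rng.normal(size=(5, 6, 4))
        frames = FrameGrid(values=values, centers_ms=np.arange(4.0), width_ms=200.0,
                           trial_rows=np.arange(5))
        pooled = pooled_trial_values(frames, [1, 3], [0, 2])
        np.testing.assert_allclose(pooled, values[:, [1, 3]][:, :, [0, 2]].mean(axis=(1, 2)))

    def test_empty_cluster_raises(self, rng):
        frames = FrameGrid(values=rng.normal(size=(5, 6, 4)), centers_ms=np.arange(4.0),
                           width_ms=200.0, trial_rows=np.arange(5))
        with pytest.raises(DataError):
            pooled_trial_values(frames, [], [0])


class TestRtModel:
    def test_lp_slowdown_recovered(self):
        rng = np.random.default_rng(0)
        df = make_labeled_frame(25, 60, rng)
        shift = np.where(df["choice_type"] == "LP", 0.3, 0.0)
        df["log_rt"] = 6.5 + shift + rng.normal(0, 0.25, len(df))
        out = rt_model(df)
        row = within_level_contrast(out["contrasts"], "LP", "HP")
        assert row["estimate"] > 0.2
        assert row["p_tukey"] < 0.001

    def test_null_rt_no_differences(self):
        rng = np.random.default_rng(1)
        hits = 0
        reps = 20
        for _ in range(reps):
            df = make_labeled_frame(10, 50, rng)
            df["log_rt"] = 6.5 + rng.normal(0, 0.25, len(df))
            out = rt_model(df)
            hits += int((out["contrasts"]["p_tukey"] < 0.05).any())
        assert hits <= 3  # Tukey controls the family at ~5%

    def test_subjects_with_empty_cells_dropped(self):
        rng = np.random.default_rng(2)
        df = make_labeled_frame(6, 60, rng, p_types=(0.4, 0.2, 0.2, 0.2))
        full = rt_model(df)
        drop = (df["subject_id"] == "s00") & (df["choice_type"] == "LP")
        out = rt_model(df[~drop])
        assert out["n_subjects"] == full["n_subjects"] - 1


class TestPooledEffectModel:
    def test_decision_pattern_lp_deeper(self):
        rng = np.random.default_rng(3)
        means = {(ct, fb): -1.5 for ct in CHOICE_TYPES for fb in ("gain", "loss")}
        for fb in ("gain", "loss"):
            means[("LP", fb)] = -2.25
        pooled = _pooled(rng, cell_means=means)
        out = pooled_effect_model(pooled, "choice")
        for other in ("HP", "pre-LP", "post-LP"):
            row = within_level_contrast(out["contrasts"]["choice_type"], "LP", other)
            assert row["estimate"] < 0
            assert row["p_tukey"] < 0.001

    def test_late_anterior_pattern(self):
        # losses drive the LP response; HP responds to both valences
        rng = np.random.default_rng(4)
        means = {
            ("HP", "gain"): 0.6, ("HP", "loss"): 0.6,
            ("pre-LP", "gain"): 0.2, ("pre-LP", "loss"): 0.2,
            ("LP", "gain"): -0.2, ("LP", "loss"): 0.6,
            ("post-LP", "gain"): 0.2, ("post-LP", "loss"): 0.6,
        }
        pooled = _pooled(rng, n_subj=25, n_tr=60, cell_means=means)
        out = pooled_effect_model(pooled, "choice_feedback")
        cells = out["contrasts"]["choice_type:feedback"]
        lp = within_level_contrast(cells, "LP:loss", "LP:gain")
        hp = within_level_contrast(cells, "HP:loss", "HP:gain")
        assert lp["estimate"] > 0 and lp["p_tukey"] < 0.01
        assert hp["p_tukey"] > 0.05

    def test_null_omnibus_calibrated(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(20):
            pooled = _pooled(rng, n_subj=10, n_tr=30)
            out = pooled_effect_model(pooled, "choice_feedback")
            p = out["omnibus"].set_index("term").loc["choice_type", "p"]
            hits += int(p < 0.05)
        assert hits <= 4

    def test_triple_design_restricted_to_hp_lp(self):
        rng = np.random.default_rng(6)
        pooled = _pooled(rng, n_subj=15, n_tr=60)
        out = pooled_effect_model(pooled, "choice_feedback_prev")
        terms = set(out["omnibus"]["term"])
        assert "feedback:previous_feedback:choice_type" in terms
        key = "choice_type:feedback:previous_feedback"
        levels = set(out["emmeans"][key]["level"].str.split(":").str[0])
        assert levels == {"HP", "LP"}

    def test_empty_cell_raises(self):
        rng = np.random.default_rng(7)
        pooled = _pooled(rng, n_subj=8, n_tr=30)
        pooled = pooled[~((pooled.choice_type == "LP") & (pooled.feedback == "gain"))]
        with pytest.raises(DataError):
            pooled_effect_model(pooled, "choice_feedback")


class TestBetaRtRegression:
    def test_slope_recovery(self):
        rng = np.random.default_rng(8)
        df = _pooled(rng, n_subj=40, n_tr=30, noise_sd=0.8)
        df["beta_db"] += -2.0 * (df["log_rt"] - df["log_rt"].mean())
        out = beta_rt_regression(df)
        assert out["slope"] == pytest.approx(-2.0, abs=0.3)
        assert out["p"] < 0.001

    def test_null_slope_coverage(self):
        rng = np.random.default_rng(9)
        covered = 0
        reps = 40
        for _ in range(reps):
            df = _pooled(rng, n_subj=8, n_tr=25)
            out = beta_rt_regression(df)
            lo = out["slope"] - 1.96 * out["se"]
            hi = out["slope"] + 1.96 * out["se"]
            covered += int(lo <= 0.0 <= hi)
        assert covered / reps >= 0.85

    def test_r2_bounds(self):
        rng = np.random.default_rng(10)
        df = _pooled(rng)
        df["beta_db"] += -1.0 * (df["log_rt"] - df["log_rt"].mean())
        out = beta_rt_regression(df)
        assert 0 < out["r2_marginal"] <= out["r2_conditional"] < 1

    def test_constant_rt_raises(self, rng):
        df = _pooled(rng, n_subj=4, n_tr=10)
        df["log_rt"] = 6.5
        with pytest.raises(DataError):
            beta_rt_regression(df)


def _paired_tables(rng, n_subj=15, n_blocks=4, coupling=0.5, latent_sd=1.0):
    """Labels with explicit LP->post-LP successions plus pooled tables."""
    rows = []
    for s in range(n_subj):
        for b in range(n_blocks):
            for t, ct in enumerate(["HP", "pre-LP", "LP", "post-LP", "HP", "HP"]):
                rows.append({"subject_id": f"s{s:02d}", "block": b, "trial": t,
                             "choice_type": ct,
                             "feedback": "loss" if ct == "LP" else "gain",
                             "previous_feedback": "gain", "log_rt": 6.6,
                             "analyzed": True})
    labels = pd.DataFrame(rows)
    ant = labels.copy()
    post = labels.copy()
    z = rng.normal(0, latent_sd, len(labels))
    ant["beta_db"] = 0.6 + z + rng.normal(0, 0.1, len(labels))
    post["beta_db"] = -1.5 + rng.normal(0, 0.3, len(labels))
    # couple each LP trial's latent into the following post-LP trial
    lp_idx = labels.index[labels["choice_type"] == "LP"]
    post.loc[lp_idx + 1, "beta_db"] += coupling * z[lp_idx]
    return labels, ant, post


class TestCrossTrial:
    def test_pairing_rule(self, rng):
        labels, ant, post = _paired_tables(rng, n_subj=3, n_blocks=2)
        pairs = build_cross_trial_pairs(labels, ant, post)
        assert len(pairs) == 3 * 2  # one LP-loss -> post-LP pair per block
        assert (pairs["lp_trial"] == 2).all()

    def test_coupling_recovered(self):
        rng = np.random.default_rng(11)
        labels, ant, post = _paired_tables(rng, n_subj=25, n_blocks=6, coupling=0.5)
        pairs = build_cross_trial_pairs(labels, ant, post)
        out = cross_trial_regression(pairs, "trial")
        assert out["slope"] == pytest.approx(0.5, abs=2.5 * out["se"])
        assert out["p"] < 0.01

    def test_independent_generators_ns(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(20):
            labels, ant, post = _paired_tables(rng, n_subj=10, n_blocks=3, coupling=0.0)
            pairs = build_cross_trial_pairs(labels, ant, post)
            hits += int(cross_trial_regression(pairs, "trial")["p"] < 0.05)
        assert hits <= 4

    def test_subject_mode(self):
        rng = np.random.default_rng(13)
        labels, ant, post = _paired_tables(rng, n_subj=20, n_blocks=6, coupling=0.8)
        pairs = build_cross_trial_pairs(labels, ant, post)
        out = cross_trial_regression(pairs, "subject")
        assert out["n_pairs"] == 20
        assert np.isfinite(out["slope"])

    def test_no_pairs_raises(self, rng):
        with pytest.raises(DataError):
            cross_trial_regression(pd.DataFrame(), "trial")
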