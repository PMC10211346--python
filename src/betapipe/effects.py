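"""Stage-two effect-level analyses.

Pooled-window mixed models with Tukey HSD contrasts, the RT model, the
beta ~ RT regression, the previous-feedback (triple interaction) model
restricted to HP/LP, the LP-loss -> post-LP cross-trial regression, and
the two-step (valence-balanced) averaging used for visualization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._errors import DataError
from .lmm import Design, fit_lmm, type3_table, tukey_table, emmeans, wald_f
from .screen import FrameGrid
from .task_sim import CHOICE_TYPES

FEEDBACK_LEVELS = ["gain", "loss"]


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def pooled_trial_values(
    frames: FrameGrid, sensors: list[int], frame_idx: list[int]
) -> np.ndarray:
    """Per-trial dB averaged over a cluster's sensors and a window's frames."""
    if len(sensors) == 0 or len(frame_idx) == 0:
        raise DataError("pooled_trial_values: empty sensor set or frame window")
    sub = frames.values[np.ix_(range(frames.values.shape[0]), sensors, frame_idx)]
    return sub.mean(axis=(1, 2))


def make_pooled_table(
    labels: pd.DataFrame, frames: FrameGrid, sensors: list[int], frame_idx: list[int]
) -> pd.DataFrame:
    """Tidy per-trial table of pooled beta power plus the analysis factors."""
    values = pooled_trial_values(frames, sensors, frame_idx)
    out = labels.loc[frames.trial_rows, [
        "subject_id", "block", "trial", "choice_type", "feedback",
        "previous_feedback", "log_rt",
    ]].copy()
    out["beta_db"] = values
    return out.reset_index(drop=True)


def _drop_incomplete_subjects(
    df: pd.DataFrame, factors: list[str], levels: dict[str, list[str]]
) -> pd.DataFrame:
    """Drop subjects with an empty cell of the given factorial design."""
    n_cells = int(np.prod([len(levels[f]) for f in factors]))
    ok = []
    for subj, g in df.groupby("subject_id"):
        cells = set(map(tuple, g[factors].to_numpy()))
        if len(cells) == n_cells:
            ok.append(subj)
    return df[df["subject_id"].isin(ok)].copy()


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def rt_model(labels: pd.DataFrame, ddf_method: str = "between-within") -> dict:
    """log RT ~ ChoiceType * PreviousFeedback + (1 | subject).

    Trials without a previous outcome are dropped; subjects missing any of
    the 4 x 2 cells are dropped to keep the design estimable per subject.
    """
    df = labels[labels["analyzed"] & (labels["previous_feedback"] != "none")].copy()
    levels = {"choice_type": list(CHOICE_TYPES), "previous_feedback": FEEDBACK_LEVELS}
    df = _drop_incomplete_subjects(df, ["choice_type", "previous_feedback"], levels)
    if df.empty:
        raise DataError("rt_model: no subjects with a complete 4x2 design")
    design = Design(
        factors=levels,
        terms=[("choice_type",), ("previous_feedback",), ("choice_type", "previous_feedback")],
    )
    fit = fit_lmm(df, "log_rt", design)
    return {
        "fit": fit,
        "design": design,
        "n_trials": len(df),
        "n_subjects": df["subject_id"].nunique(),
        "omnibus": type3_table(fit, design, ddf_method),
        "contrasts": tukey_table(fit, design, "choice_type", ddf_method),
        "emmeans": emmeans(fit, design, "choice_type"),
    }


def pooled_effect_model(
    pooled: pd.DataFrame,
    design_kind: str = "choice_feedback",
    ddf_method: str = "between-within",
) -> dict:
    """Mixed model on pooled beta power with Tukey post-hocs.

    ``design_kind``:

    * ``"choice"`` -- beta ~ ChoiceType + (1|subject); Tukey over the four
      choice types (decision-window analysis).
    * ``"choice_feedback"`` -- beta ~ ChoiceType * Feedback + (1|subject);
      Tukey over choice-type margins and over the 8 cells.
    * ``"choice_feedback_prev"`` -- beta ~ Feedback * PreviousFeedback *
      ChoiceType + (1|subject), restricted to HP and LP choices with a
      defined previous outcome; Tukey over the 8 cells.
    """
    df = pooled.copy()
    if design_kind == "choice":
        design = Design({"choice_type": list(CHOICE_TYPES)}, [("choice_type",)])
        by = [("choice_type",)]
    elif design_kind == "choice_feedback":
        design = Design(
            {"choice_type": list(CHOICE_TYPES), "feedback": FEEDBACK_LEVELS},
            [("choice_type",), ("feedback",), ("choice_type", "feedback")],
        )
        by = [("choice_type",), ("choice_type", "feedback")]
    elif design_kind == "choice_feedback_prev":
        df = df[(df["choice_type"].isin(["HP", "LP"])) & (df["previous_feedback"] != "none")]
        design = Design(
            {
                "feedback": FEEDBACK_LEVELS,
                "previous_feedback": FEEDBACK_LEVELS,
                "choice_type": ["HP", "LP"],
            },
            [
                ("feedback",), ("previous_feedback",), ("choice_type",),
                ("feedback", "previous_feedback"), ("feedback", "choice_type"),
                ("previous_feedback", "choice_type"),
                ("feedback", "previous_feedback", "choice_type"),
            ],
        )
        by = [("choice_type", "feedback", "previous_feedback")]
    else:
        raise ValueError(f"unknown design_kind {design_kind!r}")
    cells = df.groupby([f for f in design.factors], observed=True).size()
    expected = int(np.prod([len(v) for v in design.factors.values()]))
    if len(cells) < expected:
        raise DataError(
            f"pooled_effect_model: design {design_kind!r} has empty cells "
            f"(found {len(cells)} of {expected})"
        )
    fit = fit_lmm(df, "beta_db", design)
    out = {
        "fit": fit,
        "design": design,
        "n_trials": len(df),
        "n_subjects": df["subject_id"].nunique(),
        "omnibus": type3_table(fit, design, ddf_method),
        "contrasts": {},
        "emmeans": {},
    }
    for b in by:
        key = ":".join(b)
        out["contrasts"][key] = tukey_table(fit, design, b, ddf_method)
        out["emmeans"][key] = emmeans(fit, design, b)
    return out


def within_level_contrast(
    contrasts: pd.DataFrame, level_a: str, level_b: str
) -> pd.Series:
    """Pull one pair (in either orientation) out of a Tukey table.

    When the stored orientation is ``level_b - level_a`` the estimate and t
    are sign-flipped so the returned row is always ``level_a - level_b``.
    """
    hit = contrasts[(contrasts["level_a"] == level_a) & (contrasts["level_b"] == level_b)]
    if len(hit) == 1:
        return hit.iloc[0]
    hit = contrasts[(contrasts["level_a"] == level_b) & (contrasts["level_b"] == level_a)]
    if len(hit) == 1:
        row = hit.iloc[0].copy()
        row["estimate"] = -row["estimate"]
        row["t"] = -row["t"]
        row["level_a"], row["level_b"] = level_a, level_b
        return row
    raise KeyError(f"contrast {level_a} vs {level_b} not found")


def beta_rt_regression(pooled: pd.DataFrame, ddf_method: str = "between-within") -> dict:
    """beta ~ logRT * ChoiceType * PreviousFeedback + (1 | subject).

    Reports the overall (factor-averaged) RT slope with its test, plus
    marginal/conditional R^2.  log-RT is centered before entering the
    model, so with sum-coded factors the main RT coefficient is the
    average slope.
    """
    df = pooled[pooled["previous_feedback"] != "none"].copy()
    if df["log_rt"].std(ddof=0) == 0:
        raise DataError("beta_rt_regression: response time is constant")
    center = df["log_rt"].mean()
    df["log_rt_c"] = df["log_rt"] - center
    design = Design(
        factors={"choice_type": list(CHOICE_TYPES), "previous_feedback": FEEDBACK_LEVELS},
        terms=[
            ("log_rt_c",), ("choice_type",), ("previous_feedback",),
            ("log_rt_c", "choice_type"), ("log_rt_c", "previous_feedback"),
            ("choice_type", "previous_feedback"),
            ("log_rt_c", "choice_type", "previous_feedback"),
        ],
        continuous=("log_rt_c",),
    )
    fit = fit_lmm(df, "beta_db", design)
    slope_col = design.term_cols[("log_rt_c",)][0]
    slope = float(fit.beta[slope_col])
    se = float(np.sqrt(fit.cov_beta[slope_col, slope_col]))
    F, _, df2, p = wald_f(fit, [slope_col], ddf_method)
    r2m, r2c = fit.r2()
    return {
        "fit": fit,
        "slope": slope,
        "se": se,
        "intercept": float(fit.beta[0]),
        "p": p,
        "df": df2,
        "r2_marginal": r2m,
        "r2_conditional": r2c,
        "n_trials": len(df),
        "rt_center": float(center),
    }


def build_cross_trial_pairs(
    labels: pd.DataFrame,
    anterior_pooled: pd.DataFrame,
    posterior_pooled: pd.DataFrame,
) -> pd.DataFrame:
    """Pair each LP-loss trial with its immediately following post-LP trial.

    ``anterior_pooled``/``posterior_pooled`` are pooled tables (from
    :func:`make_pooled_table`) holding the late-window anterior values and
    the decision-window posterior values of every analyzed trial.  By the
    taxonomy the paired post-LP trial is the next within-block trial.
    """
    key = ["subject_id", "block", "trial"]
    ant = anterior_pooled.set_index(key)
    post = posterior_pooled.set_index(key)
    rows = []
    lp_loss = anterior_pooled[
        (anterior_pooled["choice_type"] == "LP") & (anterior_pooled["feedback"] == "loss")
    ]
    for _, r in lp_loss.iterrows():
        nxt = (r["subject_id"], r["block"], r["trial"] + 1)
        if nxt in post.index and post.loc[nxt, "choice_type"] == "post-LP":
            rows.append(
                {
                    "subject_id": r["subject_id"],
                    "block": r["block"],
                    "lp_trial": r["trial"],
                    "anterior_lp_loss": r["beta_db"],
                    "posterior_post_lp": float(post.loc[nxt, "beta_db"]),
                }
            )
    return pd.DataFrame(rows)


def cross_trial_regression(
    pairs: pd.DataFrame, mode: str = "trial", ddf_method: str = "between-within"
) -> dict:
    """posterior post-LP beta ~ anterior LP-loss beta + (1 | subject).

    ``mode="trial"`` fits across paired trials with a subject random
    intercept; ``mode="subject"`` first averages pairs within subjects and
    fits ordinary least squares across subjects.
    """
    if pairs.empty:
        raise DataError("cross_trial_regression: no LP-loss -> post-LP pairs")
    if mode == "subject":
        agg = pairs.groupby("subject_id", as_index=False)[
            ["anterior_lp_loss", "posterior_post_lp"]
        ].mean()
        df, groups = agg, None
    elif mode == "trial":
        df, groups = pairs.copy(), "subject_id"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if df["anterior_lp_loss"].std(ddof=0) == 0:
        raise DataError("cross_trial_regression: constant predictor")
    df = df.copy()
    df["x_c"] = df["anterior_lp_loss"] - df["anterior_lp_loss"].mean()
    design = Design(factors={}, terms=[("x_c",)], continuous=("x_c",))
    fit = fit_lmm(df, "posterior_post_lp", design, groups=groups)
    col = design.term_cols[("x_c",)][0]
    ddf = ddf_method if groups is not None else "residual"
    F, _, df2, p = wald_f(fit, [col], ddf)
    r2m, r2c = fit.r2()
    return {
        "fit": fit,
        "slope": float(fit.beta[col]),
        "se": float(np.sqrt(fit.cov_beta[col, col])),
        "p": p,
        "r2_marginal": r2m,
        "r2_conditional": r2c,
        "n_pairs": len(df),
        "mode": mode,
    }


# ---------------------------------------------------------------------------
# two-step (valence-balanced) averaging
# ---------------------------------------------------------------------------

def two_step_mean(values: np.ndarray, valence: np.ndarray) -> float:
    """Mean of the per-valence means (1:1 ratio regardless of trial counts).

    Returns NaN when one of the two valences is absent (flagged upstream,
    never silently skipped).
    """
    values = np.asarray(values, dtype=float)
    valence = np.asarray(valence)
    means = []
    for v in ("gain", "loss"):
        sel = valence == v
        if not sel.any():
            return float("nan")
        means.append(values[sel].mean())
    return float(np.mean(means))


def two_step_average(
    df: pd.DataFrame,
    value_col: str = "beta_db",
    group_cols: tuple[str, ...] = ("choice_type",),
    valence_col: str = "feedback",
) -> pd.DataFrame:
    """Grand averages per group: subject-level two-step means, then across subjects.

    Subjects lacking a valence within a group contribute NaN to that group
    and are excluded from its grand mean with ``n_missing`` reported.
    """
    rows = []
    for keys, g in df.groupby(["subject_id", *group_cols], observed=True):
        keys = (keys,) if not isinstance(keys, tuple) else keys
        rows.append(
            dict(
                zip(["subject_id", *group_cols], keys),
                value=two_step_mean(g[value_col].to_numpy(), g[valence_col].to_numpy()),
            )
        )
    per_subject = pd.DataFrame(rows)
    out = (
        per_subject.groupby(list(group_cols), observed=True)["value"]
        .agg(mean="mean", n="count", n_missing=lambda s: int(s.isna().sum()))
        .reset_index()
    )
    return out
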