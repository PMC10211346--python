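"""Trial selection and choice-type taxonomy.

Implements, per subject and block independently: the two-condition learning
criterion (an uninterrupted run of four advantageous choices, then strictly
more than 65% advantageous choices until the end of the block), the
four-level choice-type classification (HP / pre-LP / LP / post-LP), RT-based
exclusion (< 300 ms or > 4000 ms) and feedback / previous-feedback labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._errors import DataError
from .task_sim import ADV, DIS, GAIN, LOSS, CHOICE_TYPES  # noqa: F401

RT_MIN_MS = 300.0
RT_MAX_MS = 4000.0
CRITERION_FRACTION = 0.65
CRITERION_RUN = 4

EXCLUSION_REASONS = ("pre-criterion", "block-failed", "rt-extreme", "unlabeled-type", "none")


def find_learning_point(choices: list[str]) -> int | None:
    """Index of the first trial after the earliest run of 4 advantageous choices.

    Everything before that index (including the run itself) is excluded.
    Returns ``None`` if the block contains no such run.
    """
    if len(choices) == 0:
        raise DataError("find_learning_point: empty block")
    run = 0
    for i, c in enumerate(choices):
        run = run + 1 if c == ADV else 0
        if run == CRITERION_RUN:
            return i + 1
    return None


def block_passes_criterion(post_point_choices: list[str]) -> bool:
    """True iff strictly more than 65% of the post-criterion choices are advantageous."""
    n = len(post_point_choices)
    if n == 0:
        return False
    frac = sum(c == ADV for c in post_point_choices) / n
    return frac > CRITERION_FRACTION


def classify_choice_types(choices: list[str], learning_point: int) -> list[str]:
    """Per-trial choice types over the full block sequence.

    Labels are assigned only to trials at index >= ``learning_point``; the
    predecessor/successor context is taken from the full sequence including
    pre-criterion trials.  Trials matching none of the four definitions
    (runs of disadvantageous choices, an advantageous choice between two
    disadvantageous ones, the final trial of a block) get ``"none"``.
    """
    n = len(choices)
    if not 0 <= learning_point <= n:
        raise DataError("classify_choice_types: learning_point outside block")
    out = ["none"] * n
    for t in range(learning_point, n):
        prev = choices[t - 1] if t > 0 else None
        nxt = choices[t + 1] if t < n - 1 else None
        c = choices[t]
        if c == ADV and prev == ADV and nxt == ADV:
            out[t] = "HP"
        elif c == ADV and prev == ADV and nxt == DIS:
            out[t] = "pre-LP"
        elif c == DIS and prev == ADV and nxt == ADV:
            out[t] = "LP"
        elif c == ADV and prev == DIS and nxt == ADV:
            out[t] = "post-LP"
    return out


def previous_feedback(outcomes: list[str]) -> list[str]:
    """Outcome of the chronologically previous within-block trial; 'none' at block start."""
    return ["none"] + list(outcomes[:-1])


def filter_rt(rt_ms: np.ndarray) -> np.ndarray:
    """Boolean mask of retained trials; the 300/4000 ms bounds are inclusive."""
    rt = np.asarray(rt_ms, dtype=float)
    if np.any(rt < 0):
        raise DataError("filter_rt: negative RT encountered")
    return (rt >= RT_MIN_MS) & (rt <= RT_MAX_MS)


def label_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Attach taxonomy columns to a tidy trial table.

    Adds ``analyzed``, ``exclusion_reason``, ``choice_type``, ``feedback``,
    ``previous_feedback`` and ``log_rt``.  Exactly one exclusion reason is
    assigned per trial; ``choice_type`` is non-'none' only for analyzed
    trials.  ``previous_feedback`` uses the chronologically previous trial
    even if that trial was itself excluded.
    """
    df = trials.sort_values(["subject_id", "block", "trial"]).reset_index(drop=True).copy()
    reason = np.empty(len(df), dtype=object)
    ctype = np.empty(len(df), dtype=object)
    prevfb = np.empty(len(df), dtype=object)
    rt_ok = filter_rt(df["rt_ms"].to_numpy())

    for (_, _), idx in df.groupby(["subject_id", "block"]).indices.items():
        idx = np.sort(idx)
        choices = df.loc[idx, "choice"].tolist()
        outcomes = df.loc[idx, "outcome"].tolist()
        prevfb[idx] = previous_feedback(outcomes)
        lp = find_learning_point(choices)
        if lp is None:
            reason[idx] = "block-failed"
            ctype[idx] = "none"
            continue
        passed = block_passes_criterion(choices[lp:])
        raw_types = classify_choice_types(choices, lp)
        for k, i in enumerate(idx):
            if k < lp:
                reason[i] = "pre-criterion"
                ctype[i] = "none"
            elif not passed:
                reason[i] = "block-failed"
                ctype[i] = "none"
            elif not rt_ok[i]:
                reason[i] = "rt-extreme"
                ctype[i] = "none"
            elif raw_types[k] == "none":
                reason[i] = "unlabeled-type"
                ctype[i] = "none"
            else:
                reason[i] = "none"
                ctype[i] = raw_types[k]

    df["analyzed"] = reason == "none"
    df["exclusion_reason"] = reason
    df["choice_type"] = ctype
    df["feedback"] = df["outcome"]
    df["previous_feedback"] = prevfb
    df["log_rt"] = np.log(df["rt_ms"].to_numpy())
    return df


def subject_cell_counts(labeled: pd.DataFrame) -> pd.DataFrame:
    """Trials per subject in each of the 8 ChoiceType x Feedback cells."""
    an = labeled[labeled["analyzed"]]
    counts = (
        an.groupby(["subject_id", "choice_type", "feedback"], observed=True)
        .size()
        .unstack(["choice_type", "feedback"], fill_value=0)
    )
    full_cols = pd.MultiIndex.from_product([list(CHOICE_TYPES), [GAIN, LOSS]])
    return counts.reindex(columns=full_cols, fill_value=0)


def subjects_with_full_design(labeled: pd.DataFrame) -> list[str]:
    """Subjects with at least one analyzed trial in every ChoiceType x Feedback cell."""
    counts = subject_cell_counts(labeled)
    keep = counts[(counts > 0).all(axis=1)].index.tolist()
    return sorted(keep)
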