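"""Stage-one mass screening over the frame x sensor grid.

200-ms frame averaging of the dB power lattice, a per-cell mixed model
(beta power ~ ChoiceType * Feedback + (1 | subject)), Benjamini-Hochberg
FDR over the flattened grid for each effect, persistence-based cluster
extraction with single-pass neighbor pruning, and an ERD/ERS split of each
cluster by the sign of the against-baseline subject means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import DataError, FitError
from .lmm import Design, RandomInterceptLM, wald_f
from .synth_meg import SensorLayout
from .task_sim import CHOICE_TYPES
from .tfr import BetaPowerGrid

#: frame centers in ms relative to response onset (17 frames)
FRAME_CENTERS_MS = np.arange(-800.0, 2400.0 + 1.0, 200.0)
FRAME_WIDTH_MS = 200.0

EFFECTS = ("choice_type", "feedback", "interaction")

CHOICE_FEEDBACK_DESIGN = Design(
    factors={"choice_type": list(CHOICE_TYPES), "feedback": ["gain", "loss"]},
    terms=[("choice_type",), ("feedback",), ("choice_type", "feedback")],
)

_EFFECT_TERMS = {
    "choice_type": ("choice_type",),
    "feedback": ("feedback",),
    "interaction": ("choice_type", "feedback"),
}


@dataclass
class FrameGrid:
    """Per-trial dB power averaged in consecutive 200-ms frames."""

    values: np.ndarray  # (trials, sensors, frames)
    centers_ms: np.ndarray
    width_ms: float
    trial_rows: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]


def frame_average(
    grid: BetaPowerGrid,
    centers_ms: np.ndarray = FRAME_CENTERS_MS,
    width_ms: float = FRAME_WIDTH_MS,
    step_ms: float = 25.0,
) -> FrameGrid:
    """Average the 25-ms lattice into non-overlapping 200-ms frames.

    Each frame covers the half-open interval ``[c - w/2, c + w/2)`` so the
    frames tile the span; every frame must be fully supported by the
    lattice (8 points at the default parameters).
    """
    t = grid.times_ms
    per_frame = int(round(width_ms / step_ms))
    cols = []
    for c in np.asarray(centers_ms, dtype=float):
        sel = (t >= c - width_ms / 2 - 1e-9) & (t < c + width_ms / 2 - 1e-9)
        if sel.sum() != per_frame:
            raise DataError(
                f"frame_average: frame centered at {c} ms has {int(sel.sum())} lattice "
                f"points, expected {per_frame} (missing coverage)"
            )
        cols.append(grid.values[:, :, sel].mean(axis=2))
    values = np.stack(cols, axis=2)
    return FrameGrid(
        values=values,
        centers_ms=np.asarray(centers_ms, dtype=float),
        width_ms=width_ms,
        trial_rows=grid.trial_rows,
    )


def _check_labels(labels: pd.DataFrame) -> None:
    if labels["subject_id"].nunique() < 2:
        raise DataError("screening requires at least 2 subjects")
    cells = set(zip(labels["choice_type"], labels["feedback"]))
    missing = [
        (ct, fb)
        for ct in CHOICE_TYPES
        for fb in ("gain", "loss")
        if (ct, fb) not in cells
    ]
    if missing:
        raise DataError(f"screening: empty ChoiceType x Feedback cells in pooled data: {missing}")


def fit_lmm_cell(
    y: np.ndarray,
    labels: pd.DataFrame,
    ddf_method: str = "between-within",
) -> dict[str, float]:
    """p-values of the three effects for a single frame x sensor cell."""
    _check_labels(labels)
    X = CHOICE_FEEDBACK_DESIGN.build(labels)
    engine = RandomInterceptLM(X, labels["subject_id"].to_numpy())
    return _cell_pvalues(engine, np.asarray(y, dtype=float), ddf_method)[0]


def _cell_pvalues(
    engine: RandomInterceptLM, y: np.ndarray, ddf_method: str
) -> tuple[dict[str, float], bool]:
    try:
        fit = engine.fit(y)
        out = {}
        for eff, term in _EFFECT_TERMS.items():
            cols = CHOICE_FEEDBACK_DESIGN.term_cols[term]
            out[eff] = wald_f(fit, cols, ddf_method)[3]
        return out, True
    except (FitError, np.linalg.LinAlgError):
        # conservative: a failed fit is never a discovery
        return {eff: 1.0 for eff in EFFECTS}, False


def screen_frames(
    frames: FrameGrid,
    labels: pd.DataFrame,
    ddf_method: str = "between-within",
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Fit the cell model over the whole grid.

    Returns ``(p_grids, ok)`` where each p-grid is (n_frames, n_sensors)
    and ``ok`` flags cells whose fit converged (failures get p = 1).
    """
    if len(labels) != frames.values.shape[0]:
        raise DataError("screen_frames: labels/values length mismatch")
    _check_labels(labels)
    X = CHOICE_FEEDBACK_DESIGN.build(labels)
    engine = RandomInterceptLM(X, labels["subject_id"].to_numpy())
    n_frames, n_sensors = frames.values.shape[2], frames.values.shape[1]
    p_grids = {eff: np.ones((n_frames, n_sensors)) for eff in EFFECTS}
    ok = np.ones((n_frames, n_sensors), dtype=bool)
    for f in range(n_frames):
        for s in range(n_sensors):
            ps, converged = _cell_pvalues(engine, frames.values[:, s, f], ddf_method)
            ok[f, s] = converged
            for eff in EFFECTS:
                p_grids[eff][f, s] = ps[eff]
    return p_grids, ok


def bh_mask(p: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up over all cells of ``p`` (any shape)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DataError("bh_mask: p-values outside [0, 1]")
    flat = p.ravel()
    m = flat.size
    order = np.argsort(flat, kind="stable")
    thresh = q * (np.arange(1, m + 1)) / m
    passed = flat[order] <= thresh
    if not passed.any():
        return np.zeros_like(p, dtype=bool)
    k = np.max(np.flatnonzero(passed))
    return p <= flat[order][k]


def fdr_masks(p_grids: dict[str, np.ndarray], q: float = 0.05) -> dict[str, np.ndarray]:
    """BH mask per effect, each over its own flattened grid."""
    return {eff: bh_mask(p, q) for eff, p in p_grids.items()}


def extract_clusters(
    mask: np.ndarray,
    window_frames: list[int] | np.ndarray,
    layout: SensorLayout,
) -> list[int]:
    """Sensors significant in *every* frame of the window, neighbor-pruned.

    Pruning is a single pass: sensors with fewer than two kept neighbors
    are removed simultaneously (not iterated to a fixpoint).
    """
    window_frames = np.asarray(window_frames, dtype=int)
    if window_frames.size == 0:
        raise DataError("extract_clusters: empty frame window")
    persistent = mask[window_frames, :].all(axis=0)
    kept = np.flatnonzero(persistent)
    keep_set = set(kept.tolist())
    pruned = [
        s for s in kept
        if len(keep_set.intersection(layout.neighbors(s).tolist())) >= 2
    ]
    return sorted(pruned)


def split_by_sign(
    cluster: list[int],
    subject_means: np.ndarray,
    alpha: float = 0.05,
) -> dict[str, list[int]]:
    """Split a cluster into ERD/ERS subclusters by the against-baseline test.

    ``subject_means`` is (n_subjects, n_sensors): per-subject window-mean dB
    (conditions pooled).  Each sensor is tested against 0 across subjects
    (two-sided one-sample t, uncorrected); non-significant sensors are
    dropped, the rest split by the sign of the mean.
    """
    if len(cluster) == 0:
        raise DataError("split_by_sign: empty cluster")
    erd, ers = [], []
    for s in cluster:
        vals = subject_means[:, s]
        if np.allclose(vals.std(ddof=1), 0) and np.allclose(vals.mean(), 0):
            continue
        t, p = stats.ttest_1samp(vals, 0.0)
        if p < alpha:
            (erd if vals.mean() < 0 else ers).append(int(s))
    return {"ERD": sorted(erd), "ERS": sorted(ers)}


@dataclass
class ScreenResult:
    """Outcome of the stage-one screen."""

    p_grids: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]
    q: float
    frame_centers_ms: np.ndarray
    windows: dict[str, list[int]]  # window name -> frame indices
    clusters: list[dict]  # {"name", "effect", "window", "sign", "sensors"}
    fit_ok: np.ndarray

    def to_json(self) -> str:
        payload = {
            "q": self.q,
            "frame_centers_ms": self.frame_centers_ms.tolist(),
            "p_grids": {k: v.tolist() for k, v in self.p_grids.items()},
            "masks": {k: v.astype(int).tolist() for k, v in self.masks.items()},
            "windows": {k: list(map(int, v)) for k, v in self.windows.items()},
            "clusters": self.clusters,
            "fit_ok": self.fit_ok.astype(int).tolist(),
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ScreenResult":
        d = json.loads(text)
        return cls(
            p_grids={k: np.asarray(v) for k, v in d["p_grids"].items()},
            masks={k: np.asarray(v, dtype=bool) for k, v in d["masks"].items()},
            q=d["q"],
            frame_centers_ms=np.asarray(d["frame_centers_ms"]),
            windows={k: list(v) for k, v in d["windows"].items()},
            clusters=d["clusters"],
            fit_ok=np.asarray(d["fit_ok"], dtype=bool),
        )


def frames_in_window(
    window_ms: tuple[float, float],
    centers_ms: np.ndarray = FRAME_CENTERS_MS,
    width_ms: float = FRAME_WIDTH_MS,
) -> list[int]:
    """Indices of the frames fully contained in ``window_ms``."""
    lo, hi = window_ms
    idx = [
        i
        for i, c in enumerate(np.asarray(centers_ms, dtype=float))
        if c - width_ms / 2 >= lo - 1e-9 and c + width_ms / 2 <= hi + 1e-9
    ]
    if not idx:
        raise DataError(f"frames_in_window: no frames inside {window_ms}")
    return idx
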