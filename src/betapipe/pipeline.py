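"""Cohort orchestration: behavior -> epochs -> band power -> screen -> effects.

Processing is per subject to bound memory: each subject's epochs are
generated, reduced to the 200-ms frame grid, and discarded.  All stages are
seeded from the run's master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ConfigError, DataError
from . import effects as fx
from .io import RunConfig, validate_config
from .screen import (
    FRAME_CENTERS_MS,
    FrameGrid,
    ScreenResult,
    extract_clusters,
    fdr_masks,
    frame_average,
    frames_in_window,
    screen_frames,
    split_by_sign,
)
from .synth_meg import generate_baseline_epochs, generate_epochs, make_layout
from .task_sim import simulate_cohort
from .taxonomy import label_trials, subjects_with_full_design
from .tfr import compute_beta_power_grid, hp_baseline, valid_center_times_ms


@dataclass
class CohortData:
    """Labeled behavior plus the pooled frame grid of all analyzed trials."""

    trials: pd.DataFrame  # labeled trial table (analysis subjects only)
    frames: FrameGrid
    layout: object
    subject_ids: list[str]
    subject_frame_means: np.ndarray  # (n_subjects, n_sensors, n_frames)


def frame_lattice_times(cfg: RunConfig) -> np.ndarray:
    """25-ms lattice covering exactly the 17-frame span."""
    lo = FRAME_CENTERS_MS[0] - 100.0
    hi = FRAME_CENTERS_MS[-1] + 100.0
    n_samp = int(round((cfg.epoch_span_ms[1] - cfg.epoch_span_ms[0]) / 1000.0 * cfg.sfreq)) + 1
    lattice = valid_center_times_ms(n_samp, cfg.sfreq, cfg.epoch_span_ms[0], cfg.tfr)
    return lattice[(lattice >= lo - 1e-9) & (lattice < hi - 1e-9)]


def build_cohort(cfg: RunConfig) -> CohortData:
    """Simulate behavior and epochs and reduce to the frame grid."""
    errs = validate_config(cfg)
    if errs:
        raise ConfigError("; ".join(errs))
    seeds = cfg.stage_seeds()
    layout = make_layout(cfg.layout_n, cfg.layout_seed)
    trials = simulate_cohort(cfg.task, cfg.agent, cfg.n_subjects, seeds["behavior"])
    labeled = label_trials(trials)
    keep = subjects_with_full_design(labeled)
    if len(keep) < 2:
        raise DataError("build_cohort: fewer than 2 subjects with a full 4x2 design")
    labeled = labeled[labeled["subject_id"].isin(keep)].reset_index(drop=True)

    times = frame_lattice_times(cfg)
    epoch_seeds = seeds["epochs"].spawn(len(keep))
    base_seeds = seeds["baseline"].spawn(len(keep))
    frame_blocks: list[np.ndarray] = []
    row_blocks: list[np.ndarray] = []
    subj_means: list[np.ndarray] = []
    for i, subj in enumerate(keep):
        sub = labeled[labeled["subject_id"] == subj]
        rng_e = np.random.default_rng(epoch_seeds[i])
        offset = (
            float(rng_e.normal(0.0, cfg.noise.subject_offset_sd_db))
            if cfg.noise.subject_offset_sd_db > 0
            else 0.0
        )
        epochs = generate_epochs(
            sub, layout, cfg.templates, cfg.noise, rng_e,
            sfreq=cfg.sfreq, span_ms=cfg.epoch_span_ms, cross=cfg.cross,
            subject_offset_db=offset,
        )
        fix = generate_baseline_epochs(
            sub, layout, cfg.noise, np.random.default_rng(base_seeds[i]),
            sfreq=cfg.sfreq, span_ms=cfg.baseline_span_ms,
        )
        baseline = hp_baseline(fix, cfg.tfr, cfg.baseline_window_ms)
        grid = compute_beta_power_grid(epochs, baseline, cfg.tfr, times)
        frames = frame_average(grid)
        frame_blocks.append(frames.values)
        row_blocks.append(frames.trial_rows)
        subj_means.append(frames.values.mean(axis=0))
    all_frames = FrameGrid(
        values=np.concatenate(frame_blocks, axis=0),
        centers_ms=FRAME_CENTERS_MS.copy(),
        width_ms=200.0,
        trial_rows=np.concatenate(row_blocks),
    )
    return CohortData(
        trials=labeled,
        frames=all_frames,
        layout=layout,
        subject_ids=keep,
        subject_frame_means=np.stack(subj_means),
    )


def run_screen(cohort: CohortData, cfg: RunConfig) -> ScreenResult:
    """Stage one: LMM grid, FDR masks, clusters per configured window."""
    labels = cohort.trials.loc[cohort.frames.trial_rows]
    p_grids, ok = screen_frames(cohort.frames, labels, cfg.ddf_method)
    masks = fdr_masks(p_grids, cfg.q_fdr)
    windows = {name: frames_in_window(w) for name, w in cfg.windows_ms.items()}
    clusters = []
    for name, frame_idx in windows.items():
        effect = cfg.window_effects[name]
        sensors = extract_clusters(masks[effect], frame_idx, cohort.layout)
        if not sensors:
            continue
        window_means = cohort.subject_frame_means[:, :, frame_idx].mean(axis=2)
        signed = split_by_sign(sensors, window_means)
        for sign in ("ERD", "ERS"):
            if signed[sign]:
                clusters.append(
                    {
                        "name": f"{name}_{sign.lower()}",
                        "effect": effect,
                        "window": name,
                        "sign": sign,
                        "sensors": signed[sign],
                    }
                )
    return ScreenResult(
        p_grids=p_grids,
        masks=masks,
        q=cfg.q_fdr,
        frame_centers_ms=FRAME_CENTERS_MS.copy(),
        windows=windows,
        clusters=clusters,
        fit_ok=ok,
    )


def _find_cluster(screen: ScreenResult, name: str) -> dict | None:
    for c in screen.clusters:
        if c["name"] == name:
            return c
    return None


def run_effects(cohort: CohortData, screen: ScreenResult, cfg: RunConfig) -> dict:
    """Stage two: pooled-window models, RT analyses, cross-trial regression."""
    out: dict = {"pooled": {}, "models": {}}
    labels = cohort.trials
    out["models"]["rt"] = fx.rt_model(labels, cfg.ddf_method)

    def pooled_for(cluster: dict) -> pd.DataFrame:
        frame_idx = screen.windows[cluster["window"]]
        return fx.make_pooled_table(labels, cohort.frames, cluster["sensors"], frame_idx)

    decision = _find_cluster(screen, "decision_erd")
    if decision:
        pooled = pooled_for(decision)
        out["pooled"]["decision_erd"] = pooled
        out["models"]["decision_choice"] = fx.pooled_effect_model(
            pooled, "choice", cfg.ddf_method
        )
        out["models"]["decision_beta_rt"] = fx.beta_rt_regression(pooled, cfg.ddf_method)

    early = _find_cluster(screen, "early_feedback_erd")
    if early:
        pooled = pooled_for(early)
        out["pooled"]["early_feedback_erd"] = pooled
        out["models"]["early_choice_feedback"] = fx.pooled_effect_model(
            pooled, "choice_feedback", cfg.ddf_method
        )

    late_ers = _find_cluster(screen, "late_feedback_ers")
    if late_ers:
        pooled = pooled_for(late_ers)
        out["pooled"]["late_anterior_ers"] = pooled
        out["models"]["late_anterior"] = fx.pooled_effect_model(
            pooled, "choice_feedback", cfg.ddf_method
        )
        out["models"]["late_anterior_prev"] = fx.pooled_effect_model(
            pooled, "choice_feedback_prev", cfg.ddf_method
        )

    late_erd = _find_cluster(screen, "late_feedback_erd")
    if late_erd:
        pooled = pooled_for(late_erd)
        out["pooled"]["late_posterior_erd"] = pooled
        out["models"]["late_posterior"] = fx.pooled_effect_model(
            pooled, "choice_feedback", cfg.ddf_method
        )

    if decision and late_ers:
        pairs = fx.build_cross_trial_pairs(
            labels, out["pooled"]["late_anterior_ers"], out["pooled"]["decision_erd"]
        )
        out["pairs"] = pairs
        if not pairs.empty and pairs["subject_id"].nunique() >= 2:
            out["models"]["cross_trial"] = fx.cross_trial_regression(
                pairs, "trial", cfg.ddf_method
            )
    return out


@dataclass
class CohortResult:
    cohort: CohortData
    screen: ScreenResult
    effects: dict
    config: RunConfig

    def summary_dict(self) -> dict:
        """Deterministic JSON-serializable summary of every fitted model."""
        def table(df: pd.DataFrame) -> list[dict]:
            return json.loads(df.to_json(orient="records", double_precision=12))

        models = {}
        for name, m in self.effects["models"].items():
            if "omnibus" in m:
                entry = {
                    "omnibus": table(m["omnibus"]),
                    "n_trials": m["n_trials"],
                    "n_subjects": m.get("n_subjects"),
                }
                if isinstance(m.get("contrasts"), dict):
                    entry["contrasts"] = {k: table(v) for k, v in m["contrasts"].items()}
                elif m.get("contrasts") is not None:
                    entry["contrasts"] = table(m["contrasts"])
                models[name] = entry
            else:
                models[name] = {
                    k: m[k]
                    for k in ("slope", "se", "p", "r2_marginal", "r2_conditional")
                    if k in m
                }
        return {
            "config_hash": self.config.config_hash(),
            "n_subjects_analyzed": len(self.cohort.subject_ids),
            "n_trials_analyzed": int(self.cohort.trials["analyzed"].sum()),
            "clusters": self.screen.clusters,
            "models": models,
        }

    def to_json(self) -> str:
        return json.dumps(self.summary_dict(), sort_keys=True)


def run_cohort(cfg: RunConfig) -> CohortResult:
    """End-to-end run from one master seed."""
    cohort = build_cohort(cfg)
    screen = run_screen(cohort, cfg)
    effects = run_effects(cohort, screen, cfg)
    return CohortResult(cohort=cohort, screen=screen, effects=effects, config=cfg)
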