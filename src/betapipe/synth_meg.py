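"""Synthetic multichannel epochs with injected beta ERD/ERS effects.

Epochs are generated directly at the combined-sensor level: each channel is
band-limited (16-30 Hz) Gaussian noise whose amplitude envelope is scaled by
``10**(delta_db/20)`` inside effect windows (with smooth 50-ms cosine
ramps), plus broadband 1/f noise.  Fixation-locked baseline epochs carry the
flat baseline envelope only.  The default effect set encodes the pipeline's
three target patterns: a decision-period posterior ERD that is deeper for
LP choices, an early post-feedback posterior ERD deeper for LP, and a late
anterior ERS present after gains and losses for HP but driven exclusively
by losses for LP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from ._errors import ConfigError

BETA_BAND_HZ = (16.0, 30.0)


# ---------------------------------------------------------------------------
# sensor layout
# ---------------------------------------------------------------------------

@dataclass
class SensorLayout:
    """Flattened-helmet sensor geometry on the unit disc."""

    positions: np.ndarray  # (n, 2)
    adjacency: np.ndarray  # (n, n) boolean, symmetric, no self-edges
    region_masks: dict[str, np.ndarray]  # name -> (n,) boolean

    @property
    def n_combined(self) -> int:
        return self.positions.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[i])

    def region_sensors(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.region_masks[name])


def make_layout(n_combined: int = 102, seed: int = 0) -> SensorLayout:
    """Deterministic quasi-uniform layout with a distance-threshold neighbor graph.

    Points follow a sunflower (golden-angle) spiral; the neighbor threshold
    is grown from a density-scaled start until every sensor has at least two
    neighbors.  ``seed`` is accepted for interface symmetry; the layout is
    fully deterministic.
    """
    if n_combined < 4:
        raise ConfigError("make_layout: need at least 4 sensors")
    i = np.arange(n_combined)
    r = np.sqrt((i + 0.5) / n_combined)
    theta = i * np.pi * (3.0 - np.sqrt(5.0))
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    thresh = 1.9 / np.sqrt(n_combined)
    for _ in range(60):
        adj = (d > 0) & (d <= thresh)
        if adj.sum(axis=1).min() >= 2:
            break
        thresh *= 1.1
    else:  # pragma: no cover
        raise ConfigError("make_layout: could not satisfy the degree >= 2 invariant")
    masks = {
        "anterior": pos[:, 1] > 0.35,
        "posterior": pos[:, 1] < -0.35,
        "left_central": (pos[:, 0] < -0.35) & (np.abs(pos[:, 1]) <= 0.35),
    }
    return SensorLayout(positions=pos, adjacency=adj, region_masks=masks)


# ---------------------------------------------------------------------------
# effect templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectRule:
    """One additive dB contribution, optionally restricted by condition.

    ``None`` fields match any level; the contributions of all matching rules
    within a template are summed.
    """

    delta_db: float
    choice_type: str | None = None
    feedback: str | None = None
    prev_feedback: str | None = None

    def matches(self, choice_type: str, feedback: str, prev_feedback: str) -> bool:
        return (
            (self.choice_type is None or self.choice_type == choice_type)
            and (self.feedback is None or self.feedback == feedback)
            and (self.prev_feedback is None or self.prev_feedback == prev_feedback)
        )


@dataclass(frozen=True)
class EffectTemplate:
    """Condition-dependent beta power change in one region and time window.

    ``rt_slope_db`` optionally couples the per-trial delta to centered
    log-RT (dB per log-RT unit), enabling the beta~RT regression check.
    """

    name: str
    region: str
    window_ms: tuple[float, float]
    rules: tuple[EffectRule, ...]
    rt_slope_db: float = 0.0

    def delta_for(self, choice_type: str, feedback: str, prev_feedback: str) -> float:
        return sum(
            r.delta_db for r in self.rules if r.matches(choice_type, feedback, prev_feedback)
        )


def default_templates(
    prev_feedback_coupling: bool = False,
    rt_slope_db: float = 0.0,
    scale: float = 1.0,
) -> tuple[EffectTemplate, ...]:
    """The default injected effect set (magnitudes in dB, configurable).

    * decision window, posterior: -1.5 dB base ERD, extra -0.75 dB for LP;
    * early feedback, posterior: -1.0 dB base ERD, extra -0.75 dB for LP;
    * late feedback, posterior: -0.8 dB base ERD (keeps a late ERD cluster);
    * late feedback, anterior ERS: +0.6 dB for HP gains and losses and for
      LP/post-LP losses, reduced (+0.2 dB) for pre-LP and post-LP gains,
      negative (-0.2 dB) for LP gains.

    With ``prev_feedback_coupling`` the late anterior ERS for HP gains and
    LP losses is shifted +-0.125 dB by the previous outcome (previous gain
    up, previous loss down) — a zero-sum triple-interaction structure that
    leaves the (choice, feedback) marginals untouched.
    """
    s = scale
    anterior_rules = [
        EffectRule(0.6 * s, "HP", "gain"),
        EffectRule(0.6 * s, "HP", "loss"),
        EffectRule(0.2 * s, "pre-LP", "gain"),
        EffectRule(0.2 * s, "pre-LP", "loss"),
        EffectRule(-0.2 * s, "LP", "gain"),
        EffectRule(0.6 * s, "LP", "loss"),
        EffectRule(0.2 * s, "post-LP", "gain"),
        EffectRule(0.6 * s, "post-LP", "loss"),
    ]
    if prev_feedback_coupling:
        # zero-sum modulation: shifts the previous-feedback contrast without
        # moving the (choice, feedback) marginals
        anterior_rules += [
            EffectRule(0.125 * s, "HP", "gain", "gain"),
            EffectRule(-0.125 * s, "HP", "gain", "loss"),
            EffectRule(0.125 * s, "LP", "loss", "gain"),
            EffectRule(-0.125 * s, "LP", "loss", "loss"),
        ]
    return (
        EffectTemplate(
            "decision_erd",
            "posterior",
            (-900.0, -300.0),
            (EffectRule(-1.5 * s), EffectRule(-0.75 * s, "LP")),
            rt_slope_db=rt_slope_db,
        ),
        EffectTemplate(
            "early_feedback_erd",
            "posterior",
            (1100.0, 1500.0),
            (EffectRule(-1.0 * s), EffectRule(-0.75 * s, "LP")),
        ),
        EffectTemplate(
            "late_feedback_erd",
            "posterior",
            (1500.0, 1900.0),
            (EffectRule(-0.8 * s),),
        ),
        EffectTemplate(
            "late_anterior_ers",
            "anterior",
            (1500.0, 1900.0),
            tuple(anterior_rules),
        ),
    )


@dataclass
class NoiseParams:
    """Amplitudes of the oscillatory carrier and broadband noise.

    The broadband (pink) noise level is chosen so that its in-band power is
    a small fraction of the carrier's, keeping the dB-in / dB-out identity
    accurate to ~0.1 dB.
    """

    carrier_sd: float = 1.0
    broadband_sd: float = 0.2
    ramp_ms: float = 50.0
    subject_offset_sd_db: float = 0.2  # per-subject shift of all injected deltas


@dataclass
class CrossTrialCoupling:
    """Couples a latent per-trial source fluctuation into the next trial.

    For every analyzed LP trial with a loss, a latent ``z ~ N(0, latent_sd)``
    is added (in dB) to the source region/window of that trial; ``coef * z``
    is added to the target region/window of the immediately following
    analyzed post-LP trial.
    """

    coef: float = 0.5
    latent_sd_db: float = 1.0
    source_region: str = "anterior"
    source_window_ms: tuple[float, float] = (1500.0, 1900.0)
    target_region: str = "posterior"
    target_window_ms: tuple[float, float] = (-900.0, -300.0)


# ---------------------------------------------------------------------------
# epoch container
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Multichannel time-locked segments (trials x sensors x samples)."""

    data: np.ndarray
    sfreq: float
    t0_ms: float
    lock: str  # "response" or "fixation"
    trial_rows: np.ndarray  # indices into the labeled trial table

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) / self.sfreq * 1000.0


def _n_samples(span_ms: tuple[float, float], sfreq: float) -> int:
    return int(round((span_ms[1] - span_ms[0]) / 1000.0 * sfreq)) + 1


def _window_profile(
    times_ms: np.ndarray, window_ms: tuple[float, float], ramp_ms: float
) -> np.ndarray:
    """0..1 profile: 1 inside the window, cosine ramps of ``ramp_ms`` at the edges."""
    a, b = window_ms
    w = np.zeros_like(times_ms)
    inside = (times_ms >= a) & (times_ms <= b)
    w[inside] = 1.0
    if ramp_ms > 0:
        up = (times_ms >= a - ramp_ms) & (times_ms < a)
        w[up] = 0.5 * (1 + np.cos(np.pi * (a - times_ms[up]) / ramp_ms))
        down = (times_ms > b) & (times_ms <= b + ramp_ms)
        w[down] = 0.5 * (1 + np.cos(np.pi * (times_ms[down] - b) / ramp_ms))
    return w


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], sfreq: float) -> np.ndarray:
    """Broadband 1/f (amplitude ~ f^-1/2) noise, unit variance."""
    from scipy import fft as sfft

    n = shape[-1]
    nfast = sfft.next_fast_len(n, real=True)
    white = rng.standard_normal(shape[:-1] + (nfast,)).astype(np.float32)
    spec = sfft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(nfast, d=1.0 / sfreq)
    shaping = (1.0 / np.sqrt(np.maximum(f, 1.0))).astype(np.float32)
    shaping[0] = 0.0
    out = sfft.irfft(spec * shaping, n=nfast, axis=-1)[..., :n]
    sd = out.std()
    return out / sd if sd > 0 else out


def _beta_fir(sfreq: float, numtaps: int = 231) -> np.ndarray:
    lo, hi = BETA_BAND_HZ
    return signal.firwin(numtaps, [lo, hi], fs=sfreq, pass_zero=False)


def generate_epochs(
    labeled: pd.DataFrame,
    layout: SensorLayout,
    templates: tuple[EffectTemplate, ...],
    noise: NoiseParams,
    rng: np.random.Generator,
    sfreq: float = 300.0,
    span_ms: tuple[float, float] = (-1750.0, 2750.0),
    cross: CrossTrialCoupling | None = None,
    subject_offset_db: float = 0.0,
    rt_log_center: float | None = None,
) -> EpochSet:
    """Response-locked epochs for the analyzed trials of ``labeled``.

    ``labeled`` is a labeled trial table (typically one subject); only rows
    with ``analyzed == True`` receive epochs.  ``subject_offset_db`` shifts
    every injected delta (models between-subject effect-size variability;
    drawn by the caller).  ``rt_log_center`` is the reference for the
    optional RT coupling; defaults to the mean analyzed log-RT.
    """
    for tpl in templates:
        if tpl.region not in layout.region_masks:
            raise ConfigError(f"template {tpl.name!r}: unknown region {tpl.region!r}")
        if tpl.window_ms[0] < span_ms[0] or tpl.window_ms[1] > span_ms[1]:
            raise ConfigError(
                f"template {tpl.name!r}: window {tpl.window_ms} outside epoch span {span_ms}"
            )
    df = labeled[labeled["analyzed"]].sort_values(["subject_id", "block", "trial"])
    rows = df.index.to_numpy()
    n_trials = len(df)
    n_sensors = layout.n_combined
    n_samp = _n_samples(span_ms, sfreq)
    times = span_ms[0] + np.arange(n_samp) / sfreq * 1000.0
    taps = _beta_fir(sfreq)
    pad = len(taps) - 1
    if rt_log_center is None:
        rt_log_center = float(df["log_rt"].mean()) if n_trials else 0.0

    profiles = {tpl.name: _window_profile(times, tpl.window_ms, noise.ramp_ms) for tpl in templates}
    masks = {tpl.name: layout.region_masks[tpl.region].astype(float) for tpl in templates}

    # per-trial extra (region-window, delta) contributions from the
    # cross-trial coupling
    extras: dict[int, list[tuple[np.ndarray, np.ndarray, float]]] = {}
    if cross is not None:
        src_prof = _window_profile(times, cross.source_window_ms, noise.ramp_ms)
        tgt_prof = _window_profile(times, cross.target_window_ms, noise.ramp_ms)
        src_mask = layout.region_masks[cross.source_region].astype(float)
        tgt_mask = layout.region_masks[cross.target_region].astype(float)
        recs = df.reset_index(drop=True)
        for i in range(n_trials):
            r = recs.iloc[i]
            if r["choice_type"] == "LP" and r["feedback"] == "loss":
                z = float(rng.normal(0.0, cross.latent_sd_db))
                extras.setdefault(i, []).append((src_mask, src_prof, z))
                if i + 1 < n_trials:
                    nxt = recs.iloc[i + 1]
                    if (
                        nxt["choice_type"] == "post-LP"
                        and nxt["subject_id"] == r["subject_id"]
                        and nxt["block"] == r["block"]
                        and nxt["trial"] == r["trial"] + 1
                    ):
                        extras.setdefault(i + 1, []).append((tgt_mask, tgt_prof, cross.coef * z))

    data = np.empty((n_trials, n_sensors, n_samp), dtype=np.float32)
    recs = df.reset_index(drop=True)
    supports = {name: np.flatnonzero(prof > 0) for name, prof in profiles.items()}
    chunk = max(1, 4_000_000 // max(1, n_sensors * n_samp))
    for a in range(0, n_trials, chunk):
        b = min(a + chunk, n_trials)
        white = rng.standard_normal((b - a, n_sensors, n_samp + pad)).astype(np.float32)
        white *= noise.carrier_sd
        carrier = signal.fftconvolve(white, taps[None, None, :].astype(np.float32),
                                     mode="valid", axes=2)
        pink = _pink_noise(rng, (b - a, n_sensors, n_samp), sfreq) * noise.broadband_sd
        data[a:b] = carrier + pink
        for i in range(a, b):
            r = recs.iloc[i]
            contribs: list[tuple[np.ndarray, np.ndarray, np.ndarray, float]] = []
            for tpl in templates:
                delta = tpl.delta_for(r["choice_type"], r["feedback"], r["previous_feedback"])
                if delta:
                    delta += subject_offset_db
                if tpl.rt_slope_db:
                    delta += tpl.rt_slope_db * (float(r["log_rt"]) - rt_log_center)
                if delta:
                    contribs.append(
                        (masks[tpl.name], profiles[tpl.name], supports[tpl.name], delta)
                    )
            for mask, prof, z in extras.get(i, []):
                contribs.append((mask, prof, np.flatnonzero(prof > 0), z))
            if not contribs:
                continue
            cols = np.unique(np.concatenate([sup for _, _, sup, _ in contribs]))
            gain_db = np.zeros((n_sensors, len(cols)), dtype=np.float32)
            for mask, prof, _, delta in contribs:
                gain_db += np.float32(delta) * np.outer(
                    mask.astype(np.float32), prof[cols].astype(np.float32)
                )
            factor = 10.0 ** (gain_db / 20.0)
            data[i, :, cols] = (
                carrier[i - a][:, cols] * factor + pink[i - a][:, cols]
            ).T
    return EpochSet(data=data, sfreq=sfreq, t0_ms=span_ms[0], lock="response", trial_rows=rows)


def generate_baseline_epochs(
    labeled: pd.DataFrame,
    layout: SensorLayout,
    noise: NoiseParams,
    rng: np.random.Generator,
    sfreq: float = 300.0,
    span_ms: tuple[float, float] = (-750.0, 500.0),
) -> EpochSet:
    """Fixation-locked epochs for the HP trials, baseline envelope only."""
    df = labeled[labeled["analyzed"] & (labeled["choice_type"] == "HP")]
    rows = df.index.to_numpy()
    n_trials = len(df)
    n_sensors = layout.n_combined
    n_samp = _n_samples(span_ms, sfreq)
    taps = _beta_fir(sfreq)
    pad = len(taps) - 1
    data = np.empty((n_trials, n_sensors, n_samp), dtype=np.float32)
    chunk = max(1, 8_000_000 // max(1, n_sensors * n_samp))
    for a in range(0, n_trials, chunk):
        b = min(a + chunk, n_trials)
        white = rng.standard_normal((b - a, n_sensors, n_samp + pad)).astype(np.float32)
        white *= noise.carrier_sd
        carrier = signal.fftconvolve(white, taps[None, None, :].astype(np.float32),
                                     mode="valid", axes=2)
        pink = _pink_noise(rng, (b - a, n_sensors, n_samp), sfreq) * noise.broadband_sd
        data[a:b] = carrier + pink
    return EpochSet(data=data, sfreq=sfreq, t0_ms=span_ms[0], lock="fixation", trial_rows=rows)


# ---------------------------------------------------------------------------
# frame-level null generator (statistical calibration)
# ---------------------------------------------------------------------------

def simulate_null_frames(
    n_subjects: int,
    trials_per_subject: int,
    n_sensors: int,
    n_frames: int,
    rng: np.random.Generator,
    subject_sd: float = 0.5,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Label-independent frame grids for FDR calibration of the screen.

    Frame values are subject intercepts plus white noise; labels mimic
    realistic condition frequencies but carry no signal.  Redraws labels
    until all 8 ChoiceType x Feedback cells are populated in the pooled
    data.
    """
    n = n_subjects * trials_per_subject
    for _ in range(100):
        ct = rng.choice(["HP", "pre-LP", "LP", "post-LP"], size=n, p=[0.7, 0.1, 0.1, 0.1])
        p_gain = np.where(ct == "LP", 0.3, 0.7)
        fb = np.where(rng.random(n) < p_gain, "gain", "loss")
        if len(set(zip(ct.tolist(), fb.tolist()))) == 8:
            break
    else:  # pragma: no cover
        raise RuntimeError("could not populate all 8 cells")
    prev = np.where(rng.random(n) < 0.6, "gain", "loss")
    subj = np.repeat([f"s{i:02d}" for i in range(n_subjects)], trials_per_subject)
    labels = pd.DataFrame(
        {
            "subject_id": subj,
            "choice_type": ct,
            "feedback": fb,
            "previous_feedback": prev,
        }
    )
    intercepts = rng.normal(0.0, subject_sd, size=n_subjects)
    values = (
        np.repeat(intercepts, trials_per_subject)[:, None, None]
        + rng.normal(0.0, noise_sd, size=(n, n_sensors, n_frames))
    )
    return values, labels
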