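"""DPSS multitaper beta band power, dB transform, fixed-condition baseline.

The estimator matches the analysis recipe exactly: frequencies 16-30 Hz in
2-Hz steps, cycle count f/2 (so the sliding window is 500 ms at every
frequency), time-bandwidth product 4 (i.e. 8 Hz of total frequency
smoothing), 25-ms output steps, power summed across the band, then
``10*log10`` and subtraction of a per-subject per-sensor baseline derived
from the HP-condition fixation window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import dpss

from ._errors import ConfigError, DataError
from .synth_meg import EpochSet


@dataclass(frozen=True)
class TfrParams:
    """Multitaper parameters."""

    freqs_hz: tuple[float, ...] = tuple(float(f) for f in range(16, 31, 2))
    cycles_per_hz: float = 0.5  # n_cycles(f) = f * cycles_per_hz
    time_bandwidth: float = 4.0
    step_ms: float = 25.0

    def n_cycles(self, f: float) -> float:
        return f * self.cycles_per_hz

    def window_duration_s(self, f: float) -> float:
        """Sliding-window duration at frequency ``f`` (constant by construction)."""
        return self.n_cycles(f) / f

    def common_window_duration_s(self) -> float:
        durs = {round(self.window_duration_s(f), 12) for f in self.freqs_hz}
        if len(durs) != 1:
            raise ConfigError("TfrParams: window duration varies across frequencies")
        return durs.pop()

    def freq_smoothing_hz(self) -> float:
        """Total (two-sided) frequency smoothing of the estimator."""
        return self.time_bandwidth / self.common_window_duration_s()

    def n_tapers(self) -> int:
        return max(1, int(np.floor(self.time_bandwidth)) - 1)


def _window_length(params: TfrParams, sfreq: float) -> int:
    return int(round(params.common_window_duration_s() * sfreq))

def _kernels(params: TfrParams, sfreq: float) -> np.ndarray:
    """Complex demodulation kernels, shape (n_freqs * n_tapers, L)."""
    L = _window_length(params, sfreq)
    half_nbw = params.time_bandwidth / 2.0
    tapers = dpss(L, half_nbw, Kmax=params.n_tapers())  # (K, L)
    t = np.arange(L) / sfreq
    out = []
    for f in params.freqs_hz:
        osc = np.exp(-2j * np.pi * f * t)
        for k in range(tapers.shape[0]):
            out.append(tapers[k] * osc)
    return np.asarray(out)


def valid_center_times_ms(
    n_samples: int, sfreq: float, t0_ms: float, params: TfrParams
) -> np.ndarray:
    """25-ms lattice of output times with full window support.

    The lattice consists of integer multiples of ``step_ms``; times whose
    500-ms window would run off the epoch edge are excluded (never
    zero-padded).
    """
    L = _window_length(params, sfreq)
    half = L // 2
    t_end = t0_ms + (n_samples - 1) / sfreq * 1000.0
    lo = int(np.ceil((t0_ms + half / sfreq * 1000.0) / params.step_ms))
    hi = int(np.floor((t_end - (L - half) / sfreq * 1000.0) / params.step_ms))
    lattice = np.arange(lo, hi + 1) * params.step_ms
    starts = np.round((lattice - t0_ms) / 1000.0 * sfreq).astype(int) - half
    ok = (starts >= 0) & (starts + L <= n_samples)
    return lattice[ok]


def multitaper_band_power(
    data: np.ndarray,
    sfreq: float,
    t0_ms: float,
    times_ms: np.ndarray,
    params: TfrParams = TfrParams(),
) -> np.ndarray:
    """Linear beta band power at the requested output times.

    ``data`` is (trials, sensors, samples).  Power is estimated per
    frequency with DPSS tapers, averaged over tapers and summed over the
    band.  Window centers fall on the sample grid to within half a sample.
    Output times lacking full window support raise ``DataError``.
    """
    data = np.asarray(data)
    if data.ndim != 3:
        raise DataError("multitaper_band_power: data must be (trials, sensors, samples)")
    if sfreq < 2.0 * max(params.freqs_hz):
        raise ConfigError(
            f"multitaper_band_power: sfreq {sfreq} below Nyquist for "
            f"{max(params.freqs_hz)} Hz"
        )
    times_ms = np.asarray(times_ms, dtype=float)
    L = _window_length(params, sfreq)
    half = L // 2
    n_samp = data.shape[2]
    starts = np.round((times_ms - t0_ms) / 1000.0 * sfreq).astype(int) - half
    bad = (starts < 0) | (starts + L > n_samp)
    if bad.any():
        raise DataError(
            f"multitaper_band_power: output times {times_ms[bad].tolist()} lack "
            f"full {L}-sample window support"
        )
    kernels = _kernels(params, sfreq)  # (F*K, L)
    K = params.n_tapers()
    F = len(params.freqs_hz)
    # two real GEMMs instead of one complex one (float32 keeps BLAS fast;
    # absolute scale cancels in the dB-re-baseline transform)
    kr = np.ascontiguousarray(kernels.T.real, dtype=np.float32)  # (L, F*K)
    ki = np.ascontiguousarray(kernels.T.imag, dtype=np.float32)
    n_trials, n_sensors = data.shape[:2]
    T = len(times_ms)
    out = np.empty((n_trials, n_sensors, T), dtype=np.float64)
    data32 = data if data.dtype == np.float32 else data.astype(np.float32)
    scale = 2.0 / sfreq
    for ti, s in enumerate(starts):
        seg = np.ascontiguousarray(data32[:, :, s:s + L]).reshape(-1, L)
        pw = (seg @ kr) ** 2 + (seg @ ki) ** 2  # (rows, F*K)
        pw = pw.reshape(-1, F, K)
        out[:, :, ti] = (
            pw.mean(axis=2, dtype=np.float64).sum(axis=1) * scale
        ).reshape(n_trials, n_sensors)
    return out


def combine_pairs(power: np.ndarray, pairing: np.ndarray | None = None) -> np.ndarray:
    """Sum linear power within declared sensor pairs.

    ``pairing`` is an (n_pairs, 2) index array covering every input channel
    exactly once.  With ``pairing=None`` the input is assumed to already be
    at combined-sensor level and is passed through unchanged.
    """
    power = np.asarray(power)
    if pairing is None:
        return power.copy()
    pairing = np.asarray(pairing)
    if pairing.ndim != 2 or pairing.shape[1] != 2:
        raise DataError("combine_pairs: pairing must be (n_pairs, 2)")
    n_ch = power.shape[1]
    flat = pairing.ravel()
    if n_ch % 2 or len(flat) != n_ch or len(np.unique(flat)) != n_ch:
        raise DataError("combine_pairs: pairing must cover each of the channels exactly once")
    return power[:, pairing[:, 0]] + power[:, pairing[:, 1]]


def power_to_db(power: np.ndarray, eps: float = 1e-30) -> np.ndarray:
    """``10*log10`` transform with a floored argument (warns when flooring)."""
    power = np.asarray(power, dtype=float)
    if np.any(power < eps):
        warnings.warn("power_to_db: flooring non-positive power values", RuntimeWarning)
        power = np.maximum(power, eps)
    return 10.0 * np.log10(power)


def hp_baseline(
    fixation_epochs: EpochSet,
    params: TfrParams = TfrParams(),
    window_ms: tuple[float, float] = (-350.0, -50.0),
    pairing: np.ndarray | None = None,
) -> np.ndarray:
    """Per-sensor baseline (dB) from HP fixation-locked epochs.

    dB-transformed power is averaged over the lattice time points within
    ``window_ms`` and over all trials; one scalar per sensor.  The caller
    is responsible for restricting the epochs to one subject's HP trials.
    """
    if fixation_epochs.n_trials == 0:
        raise DataError("hp_baseline: no HP trials available (subject must be excluded)")
    lattice = valid_center_times_ms(
        fixation_epochs.n_samples, fixation_epochs.sfreq, fixation_epochs.t0_ms, params
    )
    sel = lattice[(lattice >= window_ms[0]) & (lattice <= window_ms[1])]
    if len(sel) == 0:
        raise ConfigError("hp_baseline: baseline window has no supported time points")
    power = multitaper_band_power(
        fixation_epochs.data, fixation_epochs.sfreq, fixation_epochs.t0_ms, sel, params
    )
    db = power_to_db(combine_pairs(power, pairing))
    return db.mean(axis=(0, 2))


@dataclass
class BetaPowerGrid:
    """Baseline-corrected beta power in dB on the 25-ms output lattice."""

    values: np.ndarray  # (trials, sensors, times) dB re baseline
    times_ms: np.ndarray
    baseline_db: np.ndarray  # (sensors,)
    trial_rows: np.ndarray


def compute_beta_power_grid(
    epochs: EpochSet,
    baseline_db: np.ndarray,
    params: TfrParams = TfrParams(),
    times_ms: np.ndarray | None = None,
    pairing: np.ndarray | None = None,
) -> BetaPowerGrid:
    """Multitaper band power -> pair combination -> dB -> baseline subtraction."""
    if times_ms is None:
        times_ms = valid_center_times_ms(epochs.n_samples, epochs.sfreq, epochs.t0_ms, params)
    power = multitaper_band_power(epochs.data, epochs.sfreq, epochs.t0_ms, times_ms, params)
    db = power_to_db(combine_pairs(power, pairing))
    baseline_db = np.asarray(baseline_db, dtype=float)
    if baseline_db.shape != (db.shape[1],):
        raise DataError("compute_beta_power_grid: baseline shape mismatch")
    return BetaPowerGrid(
        values=db - baseline_db[None, :, None],
        times_ms=np.asarray(times_ms, dtype=float),
        baseline_db=baseline_db,
        trial_rows=epochs.trial_rows,
    )
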