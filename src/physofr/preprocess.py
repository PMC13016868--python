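"""Signal conditioning: channel filters, R peaks, epoching, correction, resampling.

The chain mirrors a standard event-locked psychophysiology workflow on
500 Hz recordings: channel-specific zero-phase filtering, trial epoching
on [-1, 14) s around odor onset, baseline correction of respiration and
heart rate, respiration-correction of heart rate by pooled per-participant
regression, block-mean downsampling to 5 Hz, and per-participant unit-SD
normalization.  Every :class:`TrialEpochSet` carries a stage tag and each
operation refuses inputs of the wrong stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

EPOCH_START_S = -1.0
EPOCH_LEN_S = 15.0
STAGES = ("raw", "filtered", "epoched", "corrected", "downsampled", "normalized")


@dataclass
class TrialEpochSet:
    """Per-trial, per-channel sample matrix on a shared uniform grid.

    ``data`` has shape (n_trials, n_channels, n_samples); ``t0`` is the time
    of the first sample relative to odor onset (seconds).
    """

    data: np.ndarray
    trials: pd.DataFrame
    channels: list
    rate_hz: float
    t0: float
    stage: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[0] != len(self.trials):
            raise ValueError("trials table does not match data")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel list does not match data")

    @property
    def grid(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[2]) / self.rate_hz

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise ValueError(f"unknown channel {channel!r}") from None

    def require_stage(self, *stages: str) -> None:
        if self.stage not in stages:
            raise ValueError(f"operation requires stage in {stages}, got {self.stage!r}")

    def replace(self, **kw) -> "TrialEpochSet":
        out = TrialEpochSet(
            data=kw.get("data", self.data),
            trials=kw.get("trials", self.trials),
            channels=kw.get("channels", self.channels),
            rate_hz=kw.get("rate_hz", self.rate_hz),
            t0=kw.get("t0", self.t0),
            stage=kw.get("stage", self.stage),
            meta={**self.meta, **kw.get("meta", {})},
        )
        return out

    def select(self, mask: np.ndarray) -> "TrialEpochSet":
        return self.replace(data=self.data[mask], trials=self.trials.loc[mask].reset_index(drop=True))


def _check_finite(x: np.ndarray) -> None:
    bad = ~np.isfinite(x)
    if bad.any():
        raise ValueError(f"non-finite sample at index {int(np.flatnonzero(bad)[0])}")


def filter_channel(x: np.ndarray, channel: str, rate_hz: float = 500.0, *,
                   envelope_hz: float = 4.0, notch_q: float = 30.0) -> np.ndarray:
    """Apply the channel-specific conditioning chain (zero-phase throughout).

    ECG: 0.5 Hz 5th-order Butterworth high-pass, then 50 Hz notch.
    Respiration: linear detrend, then 2 Hz 5th-order Butterworth low-pass.
    EMG (corrugator/zygomaticus): linear detrend, 20-50 Hz 2nd-order
    Butterworth band-pass, 50 Hz notch, then rectification with a low-pass
    linear envelope (cutoff ``envelope_hz``); the envelope is clipped at
    zero so the output is nonnegative.
    Heart rate (an already-derived beat-rate series): passed through.
    """
    x = np.asarray(x, dtype=float)
    _check_finite(x)
    if channel == "ecg":
        sos = sps.butter(5, 0.5, btype="highpass", fs=rate_hz, output="sos")
        y = sps.sosfiltfilt(sos, x)
        return _notch(y, rate_hz, q=notch_q)
    if channel == "respiration":
        y = sps.detrend(x, type="linear")
        sos = sps.butter(5, 2.0, btype="lowpass", fs=rate_hz, output="sos")
        return sps.sosfiltfilt(sos, y)
    if channel in ("emg_cor", "emg_zyg"):
        y = sps.detrend(x, type="linear")
        sos = sps.butter(2, [20.0, 50.0], btype="bandpass", fs=rate_hz, output="sos")
        y = sps.sosfiltfilt(sos, y)
        y = _notch(y, rate_hz, q=notch_q)
        env_sos = sps.butter(2, envelope_hz, btype="lowpass", fs=rate_hz, output="sos")
        return np.clip(sps.sosfiltfilt(env_sos, np.abs(y)), 0.0, None)
    if channel == "heart_rate":
        return x.copy()
    raise ValueError(f"unknown channel {channel!r}")


def _notch(x: np.ndarray, rate_hz: float, freq: float = 50.0, q: float = 30.0) -> np.ndarray:
    b, a = sps.iirnotch(freq, q, fs=rate_hz)
    return sps.filtfilt(b, a, x)


def filter_epochs(epochs: TrialEpochSet, **kw) -> TrialEpochSet:
    """Apply :func:`filter_channel` trial-wise to a raw epoch set."""
    epochs.require_stage("raw")
    out = np.empty_like(epochs.data)
    for ci, c in enumerate(epochs.channels):
        for i in range(epochs.data.shape[0]):
            out[i, ci] = filter_channel(epochs.data[i, ci], c, epochs.rate_hz, **kw)
    return epochs.replace(data=out, stage="epoched",
                          meta={"filtered": True, "filter_params": dict(kw)})


def detect_r_peaks(ecg: np.ndarray, rate_hz: float = 500.0, *,
                   refractory_s: float = 0.25) -> np.ndarray:
    """Detect R-peak times (s) in a filtered ECG by thresholded local maxima.

    A simple amplitude criterion (half-way between median and maximum) with
    a refractory minimum distance; adequate for the synthetic ECG this
    package generates, not a clinical detector.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size == 0:
        return np.array([])
    rng_amp = ecg.max() - np.median(ecg)
    if rng_amp <= 1e-12:
        warnings.warn("flat ECG signal: no R peaks detected")
        return np.array([])
    height = np.median(ecg) + 0.5 * rng_amp
    idx, _ = sps.find_peaks(ecg, height=height, distance=max(1, int(refractory_s * rate_hz)))
    return idx / rate_hz


def instantaneous_heart_rate(peaks: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Beat-to-beat rate 60/IBI anchored at each interval's closing peak,
    linearly interpolated onto ``grid`` with constant extrapolation."""
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size < 2:
        raise ValueError("need at least 2 R peaks to derive heart rate")
    ibi = np.diff(peaks)
    rates = 60.0 / ibi
    return np.interp(np.asarray(grid, float), peaks[1:], rates,
                     left=rates[0], right=rates[-1])


def epoch(x: np.ndarray, onsets: np.ndarray, rate_hz: float = 500.0):
    """Cut one [-1, 14) s epoch per onset; drop onsets too close to an edge.

    Returns ``(epochs, kept)`` where ``kept`` is a boolean mask over onsets;
    dropped onsets are reported via a warning.
    """
    x = np.asarray(x, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    n_samp = int(round(EPOCH_LEN_S * rate_hz))
    out, kept = [], np.ones(len(onsets), dtype=bool)
    for i, on in enumerate(onsets):
        start = int(round((on + EPOCH_START_S) * rate_hz))
        if start < 0 or start + n_samp > x.size:
            kept[i] = False
            warnings.warn(f"onset {on:.3f}s too close to recording edge; trial dropped")
            continue
        out.append(x[start:start + n_samp])
    return (np.array(out) if out else np.empty((0, n_samp))), kept


def baseline_correct(epochs: TrialEpochSet,
                     channels=("respiration", "heart_rate")) -> TrialEpochSet:
    """Subtract each trial's pre-onset ([-1, 0) s) mean for the listed channels.

    EMG channels are passed through unchanged by default.
    """
    epochs.require_stage("epoched")
    nb = int(round(-epochs.t0 * epochs.rate_hz))
    if nb <= 0:
        raise ValueError("epochs contain no pre-onset baseline")
    data = epochs.data.copy()
    for c in channels:
        ci = epochs.channel_index(c)
        base = data[:, ci, :nb].mean(axis=1, keepdims=True)
        data[:, ci, :] -= base
    return epochs.replace(data=data, stage="corrected",
                          meta={"baseline_channels": list(channels)})


def respiration_correct_hr(epochs: TrialEpochSet, *, lag: int = 1,
                           hr_channel: str = "heart_rate",
                           resp_channel: str = "respiration") -> TrialEpochSet:
    """Replace heart rate by its residual after regressing out respiration.

    Per participant, pooling all of that participant's trials, heart rate at
    sample t is regressed on [1, resp_t, resp_{t-lag}] (edge-held at the
    epoch start) by ordinary least squares; the residual series becomes the
    corrected heart-rate channel.
    """
    epochs.require_stage("corrected")
    if lag < 0:
        raise ValueError("lag must be nonnegative")
    hi = epochs.channel_index(hr_channel)
    ri = epochs.channel_index(resp_channel)
    data = epochs.data.copy()
    for pid in epochs.trials["participant_id"].unique():
        rows = np.flatnonzero((epochs.trials["participant_id"] == pid).to_numpy())
        hr = data[rows, hi, :]
        resp = data[rows, ri, :]
        lagged = np.concatenate([np.repeat(resp[:, :1], lag, axis=1), resp[:, :resp.shape[1] - lag]], axis=1) if lag else resp
        X = np.column_stack([np.ones(hr.size), resp.ravel(), lagged.ravel()])
        coef, *_ = np.linalg.lstsq(X, hr.ravel(), rcond=None)
        data[rows, hi, :] = (hr.ravel() - X @ coef).reshape(hr.shape)
    return epochs.replace(data=data, meta={"resp_corrected": True, "resp_lag": lag})


def downsample(epochs: TrialEpochSet, target_hz: float = 5.0) -> TrialEpochSet:
    """Downsample by non-overlapping block means (alias-safe for all channels).

    The grid is re-anchored to block midpoints, so with 500->5 Hz the first
    post-onset sample summarizes [0, 0.2) s.
    """
    epochs.require_stage("corrected", "epoched")
    ratio = epochs.rate_hz / target_hz
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"rate {epochs.rate_hz} not divisible by target {target_hz}")
    block = int(round(ratio))
    n = epochs.data.shape[2]
    if n % block:
        raise ValueError("epoch length not divisible by the downsampling block")
    data = epochs.data.reshape(*epochs.data.shape[:2], n // block, block).mean(axis=3)
    t0 = epochs.t0 + block / (2 * epochs.rate_hz)  # continuous block midpoint
    return epochs.replace(data=data, rate_hz=target_hz, t0=t0, stage="downsampled")


def normalize_participant(epochs: TrialEpochSet) -> TrialEpochSet:
    """Divide each (participant, channel) by its pooled SD across time and trials."""
    epochs.require_stage("downsampled")
    data = epochs.data.copy()
    consts = {}
    for pid in epochs.trials["participant_id"].unique():
        rows = np.flatnonzero((epochs.trials["participant_id"] == pid).to_numpy())
        for ci, c in enumerate(epochs.channels):
            sd = data[rows, ci, :].std()
            if sd <= 1e-12:
                raise ValueError(f"zero pooled SD for participant {pid!r}, channel {c!r}")
            data[rows, ci, :] /= sd
            consts[(pid, c)] = float(sd)
    return epochs.replace(data=data, stage="normalized", meta={"norm_sd": consts})


def model_window(epochs: TrialEpochSet, start_s: float = 0.0,
                 length_s: float = 6.0) -> np.ndarray:
    """Extract the modeling-window samples as an (n_trials, n_channels, T) array."""
    epochs.require_stage("normalized", "downsampled")
    g = epochs.grid
    mask = (g >= start_s) & (g < start_s + length_s)
    return epochs.data[:, :, mask]
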