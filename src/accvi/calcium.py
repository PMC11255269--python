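"""Trial-aligned fluorescence processing.

Raw traces are min-max mapped to [0, 1] per neuron over the session and
zero-phase low-pass filtered at 5 Hz.  dF/F uses a robust trial baseline:
F0 is the mean of the 2-s pre-stimulus samples lying between the 25th and
75th percentile (inclusive, linear-interpolation percentiles), and
dF/F = (F - F0)/F0.  Event-aligned z-scoring subtracts the mean of the 0.5 s
preceding the event and divides by its sample s.d.

Responsiveness is a paired Wilcoxon signed-rank test of stimulus-window vs
baseline-window trial means (P < 0.05), signed into activated/suppressed by
the median difference.  Response onset is the first post-stimulus frame
(3-frame smoothed) whose across-trial values differ from the pooled per-trial
baseline means at P < 0.01 (rank-sum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import ranksums, wilcoxon

from .config import frame_times


class WindowError(ValueError):
    """Requested window not covered by the recording."""


@dataclass
class DffTensor:
    """Processed fluorescence: (neurons, trials, frames) at ``frame_rate``.

    ``t0_frame`` is the frame of stimulus onset.  ``valid`` flags
    neuron x trial entries with a usable baseline (F0 > 0, s.d. > 0).
    """

    dff: np.ndarray
    zscored: np.ndarray
    frame_rate: float
    t0_frame: int
    valid: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.dff.shape[2]

    def times(self) -> np.ndarray:
        return frame_times(self.n_frames, self.frame_rate, self.t0_frame)


def _window_mask(n_frames: int, frame_rate: float, t0_frame: int, window) -> np.ndarray:
    t = frame_times(n_frames, frame_rate, t0_frame)
    lo, hi = window
    mask = (t >= lo) & (t < hi)
    if not mask.any():
        raise WindowError(f"window {window} contains no frames")
    return mask


def preprocess_trace(F: np.ndarray, frame_rate: float = 30.0, cutoff_hz: float = 5.0) -> np.ndarray:
    """Min-max map each neuron's session trace to [0, 1], then low-pass filter.

    ``F`` is (neurons, trials, frames); the min-max range is taken over the
    whole session, the zero-phase Butterworth filter (order 4, applied
    forward-backward) runs along frames within each trial.  Constant traces
    map to zero with a warning.
    """
    F = np.asarray(F, dtype=float)
    lo = F.min(axis=(1, 2), keepdims=True)
    hi = F.max(axis=(1, 2), keepdims=True)
    span = hi - lo
    flat = span[:, 0, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant traces mapped to zero", stacklevel=2)
    span[span == 0] = 1.0
    mapped = (F - lo) / span
    sos = signal.butter(4, cutoff_hz, btype="low", fs=frame_rate, output="sos")
    return signal.sosfiltfilt(sos, mapped, axis=-1)


def robust_baseline(baseline_samples: np.ndarray) -> float:
    """Mean of samples between the 25th and 75th percentile (inclusive)."""
    x = np.asarray(baseline_samples, dtype=float)
    q25, q75 = np.percentile(x, [25, 75])
    sel = x[(x >= q25) & (x <= q75)]
    return float(sel.mean())


def compute_dff(F: np.ndarray, frame_rate: float, t0_frame: int, baseline_window=(-2.0, 0.0)):
    """dF/F per neuron x trial with the interquartile-mean baseline.

    Returns (dff, valid) where ``valid`` is False wherever F0 <= 0 (those
    entries are set to NaN).
    """
    F = np.asarray(F, dtype=float)
    mask = _window_mask(F.shape[2], frame_rate, t0_frame, baseline_window)
    base = F[:, :, mask]
    q25 = np.percentile(base, 25, axis=2, keepdims=True)
    q75 = np.percentile(base, 75, axis=2, keepdims=True)
    sel = (base >= q25) & (base <= q75)
    f0 = np.sum(base * sel, axis=2) / np.sum(sel, axis=2)
    valid = f0 > 0
    f0_safe = np.where(valid, f0, np.nan)
    dff = (F - f0_safe[:, :, None]) / f0_safe[:, :, None]
    return dff, valid


def zscore_event_aligned(
    dff: np.ndarray,
    frame_rate: float,
    t0_frame: int,
    baseline_window=(-0.5, 0.0),
    event_frames: np.ndarray | None = None,
):
    """z-score each neuron x trial trace against its 0.5-s pre-event baseline.

    ``event_frames`` (per trial) realigns the baseline to non-stimulus events
    such as reward delivery; by default the event is stimulus onset
    (``t0_frame``).  Entries whose baseline s.d. is zero are NaN and flagged
    invalid.
    """
    dff = np.asarray(dff, dtype=float)
    n_neurons, n_trials, n_frames = dff.shape
    if event_frames is None:
        event_frames = np.full(n_trials, t0_frame)
    z = np.empty_like(dff)
    valid = np.ones((n_neurons, n_trials), dtype=bool)
    lo, hi = baseline_window
    for j in range(n_trials):
        f0 = int(event_frames[j])
        mask = _window_mask(n_frames, frame_rate, f0, (lo, hi))
        if mask.sum() < 2:
            raise WindowError("need >= 2 baseline frames for z-scoring")
        base = dff[:, j, mask]
        mu = base.mean(axis=1)
        sd = base.std(axis=1, ddof=1)
        bad = (sd == 0) | ~np.isfinite(sd)
        valid[:, j] = ~bad
        sd = np.where(bad, np.nan, sd)
        z[:, j, :] = (dff[:, j, :] - mu[:, None]) / sd[:, None]
    return z, valid


def window_mean(
    tensor: np.ndarray,
    frame_rate: float,
    t0_frame: int,
    window,
    event_frames: np.ndarray | None = None,
) -> np.ndarray:
    """Mean over frames with start <= t < end, per neuron x trial.

    ``window`` is relative to stimulus onset, or to per-trial ``event_frames``
    when given (e.g. 1-s window after the first lick).
    """
    tensor = np.asarray(tensor, dtype=float)
    n_frames = tensor.shape[2]
    if event_frames is None:
        mask = _window_mask(n_frames, frame_rate, t0_frame, window)
        return tensor[:, :, mask].mean(axis=2)
    out = np.empty(tensor.shape[:2])
    for j, f0 in enumerate(np.asarray(event_frames)):
        if np.isnan(f0):
            out[:, j] = np.nan
            continue
        mask = _window_mask(n_frames, frame_rate, int(f0), window)
        out[:, j] = tensor[:, j, mask].mean(axis=1)
    return out


def process_session(F: np.ndarray, frame_rate: float, t0_frame: int,
                    baseline_dff=(-2.0, 0.0), baseline_z=(-0.5, 0.0), minmax: bool = True):
    """Standard processing chain: raw -> [0,1] map + filter -> dF/F -> z-score.

    Returns (dff, zscored, valid).  ``minmax=False`` skips the session-wide
    normalization/filtering for traces already on a calibrated scale (the
    two-fold and z-scored statistics downstream are scale-invariant either
    way).
    """
    x = preprocess_trace(F, frame_rate) if minmax else np.asarray(F, dtype=float)
    dff, valid = compute_dff(x, frame_rate, t0_frame, baseline_dff)
    z, zvalid = zscore_event_aligned(dff, frame_rate, t0_frame, baseline_z)
    return dff, z, valid & zvalid


def test_responsiveness(
    dff: np.ndarray,
    frame_rate: float,
    t0_frame: int,
    stimulus_window=(0.0, 1.0),
    baseline_window=(-2.0, 0.0),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-neuron paired signed-rank screen of stimulus vs baseline activity.

    Returns a DataFrame with ``p_value`` and ``direction`` in
    {activated, suppressed, none}.
    """
    dff = np.asarray(dff, dtype=float)
    if dff.shape[1] < 6:
        raise ValueError("signed-rank screen needs >= 6 trials")
    stim = window_mean(dff, frame_rate, t0_frame, stimulus_window)
    base = window_mean(dff, frame_rate, t0_frame, baseline_window)
    rows = []
    for i in range(dff.shape[0]):
        diff = stim[i] - base[i]
        diff = diff[np.isfinite(diff)]
        if len(diff) < 6 or np.all(diff == 0):
            rows.append({"p_value": 1.0, "direction": "none"})
            continue
        p = float(wilcoxon(diff).pvalue)
        if p < alpha:
            direction = "activated" if np.median(diff) > 0 else "suppressed"
        else:
            direction = "none"
        rows.append({"p_value": p, "direction": direction})
    out = pd.DataFrame(rows)
    out.index.name = "neuron"
    return out


def detect_onset(
    zscored_trials: np.ndarray,
    frame_rate: float,
    t0_frame: int,
    stimulus_window=(0.0, 1.0),
    baseline_window=(-0.5, 0.0),
    alpha: float = 0.01,
) -> float:
    """Response onset (s) for one neuron from its (trials, frames) z-scores.

    Each trial is smoothed with a 3-frame moving average; each in-window frame
    is rank-sum tested against the pooled per-trial baseline means.  Returns
    the first significant time, or NaN when none exists.
    """
    x = np.asarray(zscored_trials, dtype=float)
    if x.ndim != 2 or x.shape[0] < 6:
        raise ValueError("need a (trials, frames) array with >= 6 trials")
    kernel = np.ones(3) / 3.0
    sm = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), 1, x)
    base_mask = _window_mask(x.shape[1], frame_rate, t0_frame, baseline_window)
    baseline = sm[:, base_mask].mean(axis=1)
    stim_mask = _window_mask(x.shape[1], frame_rate, t0_frame, stimulus_window)
    t = frame_times(x.shape[1], frame_rate, t0_frame)
    for f in np.nonzero(stim_mask)[0]:
        p = ranksums(sm[:, f], baseline).pvalue
        if p < alpha:
            return float(t[f])
    return float("nan")
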