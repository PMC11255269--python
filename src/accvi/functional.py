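"""Functional-neuron classification and go/no-go selectivity.

A neuron passes the two-fold rule when its response in the "surprise" or
"high-value" condition exceeds the reference response by at least its own
magnitude: R_high - R_low > |R_low|.  In the Uncertain session,
outcome-monitoring neurons compare the reward-omission response against the
Hit response (1-s window after the first lick) and value-updating neurons
compare the go-cue response in the early (first 67%) vs late (last 33%)
period.  In the Reversal session, outcome monitoring compares the air-puff
response early (first 15%) vs late (last 85%), and value updating the
no-go-cue (3 kHz) response early vs late.  Dual-function neurons satisfy
both rules.

The selectivity index is SI = (mean_go - mean_nogo) / sigma_p with sigma_p
the pooled standard deviation; significance comes from 1000 label shuffles
(two-sided on |SI|, P < 0.05).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import as_generator
from .calcium import window_mean


@dataclass
class SelectivityResult:
    si: float
    sigma_p: float
    p_perm: float | None = None
    significant: bool | None = None
    n_go: int = 0
    n_nogo: int = 0


def twofold_rule(r_high, r_low) -> bool:
    """True when R_high exceeds R_low by at least two-fold: R_high - R_low > |R_low|."""
    return bool(r_high - r_low > abs(r_low))


def _condition_means(values: np.ndarray, sel: np.ndarray, min_trials: int = 3):
    """Per-neuron mean over selected trials; NaN-aware; None if too few trials."""
    if sel.sum() < min_trials:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(values[:, sel], axis=1)


def classify_functional(
    trials: pd.DataFrame,
    dff: np.ndarray,
    frame_rate: float,
    t0_frame: int,
    session: str | None = None,
    window: float = 1.0,
    responsive: np.ndarray | None = None,
) -> pd.DataFrame:
    """Apply the session-appropriate two-fold rules to every neuron.

    ``dff`` is (neurons, trials, frames) aligned on stimulus onset; outcome
    windows are re-aligned per trial to the first response-window lick.
    Returns per-neuron flags with the window means that produced them.  Pass
    ``responsive`` to restrict classification to a boolean neuron mask
    (default: all neurons).
    """
    session = session or trials["session"].iloc[0]
    period = np.asarray(trials["period"])
    oc = trials["outcome_class"] if "outcome_class" in trials else None
    if oc is None:
        raise ValueError("outcomes must be classified before functional labelling")

    lick_frames = t0_frame + np.floor(trials["first_lick_s"].to_numpy() * frame_rate)

    def outcome_means(label):
        sel = (oc == label).to_numpy()
        frames = np.where(sel, lick_frames, np.nan)
        vals = window_mean(dff, frame_rate, t0_frame, (0.0, window), event_frames=frames)
        return vals, sel

    cue_vals = window_mean(dff, frame_rate, t0_frame, (0.0, window))

    if session == "Uncertain":
        ro_vals, ro_sel = outcome_means("RO")
        hit_vals, hit_sel = outcome_means("Hit")
        mon_high = _condition_means(ro_vals, ro_sel)
        mon_low = _condition_means(hit_vals, hit_sel)
        go_sel = trials["trial_type"].isin(["go", "RO"]).to_numpy()
        upd_high = _condition_means(cue_vals, go_sel & (period == "early"))
        upd_low = _condition_means(cue_vals, go_sel & (period == "late"))
    elif session in ("Reversal", "Re-stable"):
        fa_vals, fa_sel = outcome_means("FA")
        mon_high = _condition_means(fa_vals, fa_sel & (period == "early"))
        mon_low = _condition_means(fa_vals, fa_sel & (period == "late"))
        nogo_sel = (trials["trial_type"] == "nogo").to_numpy()
        upd_high = _condition_means(cue_vals, nogo_sel & (period == "early"))
        upd_low = _condition_means(cue_vals, nogo_sel & (period == "late"))
    else:
        raise ValueError(f"no classification rules defined for session {session!r}")

    n = dff.shape[0]
    out = pd.DataFrame(index=pd.RangeIndex(n, name="neuron"))
    out["session"] = session
    for prefix, high, low in (("mon", mon_high, mon_low), ("upd", upd_high, upd_low)):
        if high is None or low is None:
            warnings.warn(
                f"{session}: fewer than 3 trials in a condition required for "
                f"{prefix} classification; neurons skipped",
                stacklevel=2,
            )
            out[f"{prefix}_r_high"] = np.nan
            out[f"{prefix}_r_low"] = np.nan
            out["outcome_monitoring" if prefix == "mon" else "value_updating"] = False
            continue
        ok = np.isfinite(high) & np.isfinite(low)
        flag = np.zeros(n, dtype=bool)
        flag[ok] = (high - low > np.abs(low))[ok]
        out[f"{prefix}_r_high"] = high
        out[f"{prefix}_r_low"] = low
        out["outcome_monitoring" if prefix == "mon" else "value_updating"] = flag
    if responsive is not None:
        out["outcome_monitoring"] &= responsive
        out["value_updating"] &= responsive
    out["dual"] = out["outcome_monitoring"] & out["value_updating"]
    return out


def venn_summary(n_monitoring: int, n_updating: int, n_dual: int, n_total: int) -> dict:
    """Counts and round-half-up percentages for the functional-class Venn."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")

    def pct(k):
        return int(math.floor(100.0 * k / n_total + 0.5))

    return {
        "n_monitoring": n_monitoring,
        "n_updating": n_updating,
        "n_dual": n_dual,
        "n_total": n_total,
        "pct_monitoring": pct(n_monitoring),
        "pct_updating": pct(n_updating),
        "pct_dual": pct(n_dual),
    }


def selectivity_index(responses_go, responses_nogo) -> SelectivityResult:
    """SI = (mean_go - mean_nogo) / pooled s.d.; positive = go-preferring."""
    a = np.asarray(responses_go, dtype=float)
    b = np.asarray(responses_nogo, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each condition needs >= 2 trials")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na - 1 + nb - 1)
    sigma_p = math.sqrt(pooled_var)
    if sigma_p == 0:
        return SelectivityResult(si=float("nan"), sigma_p=0.0, n_go=na, n_nogo=nb)
    return SelectivityResult(si=float((a.mean() - b.mean()) / sigma_p), sigma_p=sigma_p,
                             n_go=na, n_nogo=nb)


def si_permutation_test(responses_go, responses_nogo, n_perm: int = 1000, seed=None) -> SelectivityResult:
    """Label-shuffle test of the selectivity index (two-sided via |SI|).

    Significant when |SI| exceeds the 95th percentile of the shuffled |SI|
    distribution; ``p_perm`` is the fraction of shuffles at least as extreme.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = as_generator(seed)
    a = np.asarray(responses_go, dtype=float)
    b = np.asarray(responses_nogo, dtype=float)
    if len(a) + len(b) < 10:
        warnings.warn("fewer than 10 trials: permutation p has low resolution", stacklevel=2)
    res = selectivity_index(a, b)
    pooled = np.concatenate([a, b])
    na, nb = len(a), len(b)
    # vectorised shuffles: each row of idx is one permutation of the pooled labels
    idx = np.argsort(rng.random((n_perm, na + nb)), axis=1)
    vals = pooled[idx]
    ga, gb = vals[:, :na], vals[:, na:]
    pooled_var = ((na - 1) * ga.var(axis=1, ddof=1) + (nb - 1) * gb.var(axis=1, ddof=1)) / (
        na + nb - 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        perm = (ga.mean(axis=1) - gb.mean(axis=1)) / np.sqrt(pooled_var)
    abs_perm = np.abs(perm)
    res.p_perm = float(np.mean(abs_perm >= abs(res.si)))
    res.significant = bool(abs(res.si) > np.percentile(abs_perm, 95))
    return res
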