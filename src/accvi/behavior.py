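"""Behavioral performance: outcome classification, d-prime, phase splitting.

Discriminability is d' = norminv(Hit rate) - norminv(FA rate), with
Hit rate = Hit trials / go trials and FA rate = FA trials / no-go trials.
In the Uncertain session a correct lick on a reward-omission (RO) trial is a
correct choice on a go cue, so it counts toward the Hit rate.  Degenerate
rates of 0 or 1 are clipped to 1/(2n) before the inverse normal.  A session
with d' >= 1.5 is marked proficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

PROFICIENCY_DPRIME = 1.5


class DataError(ValueError):
    """Trial data inconsistent with the requested operation."""


@dataclass
class PerformanceSummary:
    scope: str
    hit_rate: float
    fa_rate: float
    miss_rate: float
    cr_rate: float
    dprime: float
    proficient: bool
    n_go: int
    n_nogo: int


@dataclass
class PhaseAssignment:
    phase: list  # per-trial labels T1..Tk
    period: list  # per-trial early/late labels
    boundaries: list  # end index (exclusive) of each phase


def classify_outcomes(trials: pd.DataFrame) -> pd.DataFrame:
    """Label each trial Hit/Miss/FA/CR/RO/UR from its type and action.

    Returns a copy with an ``outcome_class`` column.  RO trials with a lick
    keep the RO label (reward withheld) but are treated as correct go choices
    by :func:`performance_summary`.
    """
    if trials["action"].isna().any():
        raise DataError("actions must be set before classifying outcomes")
    t = trials.copy()
    lick = t["action"] == "lick"
    cls = pd.Series(index=t.index, dtype=object)
    cls[(t["trial_type"] == "go") & lick] = "Hit"
    cls[(t["trial_type"] == "go") & ~lick] = "Miss"
    cls[(t["trial_type"] == "nogo") & lick] = "FA"
    cls[(t["trial_type"] == "nogo") & ~lick] = "CR"
    cls[(t["trial_type"] == "RO") & lick] = "RO"
    cls[(t["trial_type"] == "RO") & ~lick] = "Miss"
    cls[t["trial_type"] == "UR"] = "UR"
    unknown = cls.isna()
    if unknown.any():
        bad = sorted(t.loc[unknown, "trial_type"].unique())
        raise DataError(f"unknown trial types: {bad}")
    t["outcome_class"] = cls
    return t


def compute_dprime(hit_rate: float, fa_rate: float, n_go: int, n_nogo: int):
    """d' with 1/(2n) clipping; returns (dprime, proficient)."""
    if n_go <= 0 or n_nogo <= 0:
        raise DataError("hit/FA rates undefined without go and no-go trials")
    if not (0.0 <= hit_rate <= 1.0 and 0.0 <= fa_rate <= 1.0):
        raise DataError("rates must lie in [0, 1]")
    h = float(np.clip(hit_rate, 1.0 / (2 * n_go), 1.0 - 1.0 / (2 * n_go)))
    f = float(np.clip(fa_rate, 1.0 / (2 * n_nogo), 1.0 - 1.0 / (2 * n_nogo)))
    d = float(norm.ppf(h) - norm.ppf(f))
    return d, d >= PROFICIENCY_DPRIME


def performance_summary(trials: pd.DataFrame, scope: str = "session") -> PerformanceSummary:
    """Hit/FA/miss/CR rates and d' over the given trials.

    Go-cue trials are ``go`` and ``RO`` types; a lick on either counts as a
    Hit.  UR trials (no tone, no choice) are excluded from both denominators.
    """
    t = trials if "outcome_class" in trials else classify_outcomes(trials)
    go = t[t["trial_type"].isin(["go", "RO"])]
    nogo = t[t["trial_type"] == "nogo"]
    n_go, n_nogo = len(go), len(nogo)
    if n_go == 0 or n_nogo == 0:
        raise DataError(f"scope {scope!r} lacks go or no-go trials ({n_go}, {n_nogo})")
    hit = float((go["action"] == "lick").mean())
    fa = float((nogo["action"] == "lick").mean())
    d, prof = compute_dprime(hit, fa, n_go, n_nogo)
    return PerformanceSummary(scope, hit, fa, 1 - hit, 1 - fa, d, prof, n_go, n_nogo)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_phases(n_or_trials, fractions, early_fraction: float | None = None) -> PhaseAssignment:
    """Partition ``n`` trials into contiguous phases T1..Tk.

    Boundary i falls after round_half_up(cumulative_fraction_i * n) trials;
    the last phase absorbs any remainder.  ``early_fraction`` (e.g. 0.67 or
    0.15) sets the early/late period boundary with the same rounding; if
    omitted, the period split reuses the first phase boundary k-2 (i.e. the
    last phase is "late").
    """
    n = len(n_or_trials) if hasattr(n_or_trials, "__len__") else int(n_or_trials)
    fractions = list(fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise DataError("phase fractions must sum to 1")
    if n < len(fractions):
        raise DataError(f"cannot split {n} trials into {len(fractions)} phases")
    bounds = []
    cum = 0.0
    for f in fractions[:-1]:
        cum += f
        bounds.append(_round_half_up(cum * n))
    bounds.append(n)
    labels = []
    start = 0
    for i, b in enumerate(bounds):
        labels.extend([f"T{i + 1}"] * (b - start))
        start = b
    if early_fraction is None:
        early_n = bounds[-2] if len(bounds) > 1 else n
    else:
        early_n = _round_half_up(early_fraction * n)
    period = ["early"] * early_n + ["late"] * (n - early_n)
    return PhaseAssignment(phase=labels, period=period, boundaries=bounds)


def lick_probability(trials: pd.DataFrame, by=("stimulus",)) -> pd.DataFrame:
    """Fraction of trials with a response-window lick, per group."""
    import warnings

    t = trials.copy()
    t["licked"] = (t["action"] == "lick").astype(float)
    grouped = t.groupby(list(by), observed=True)["licked"]
    out = grouped.mean().reset_index().rename(columns={"licked": "p_lick"})
    out["n"] = grouped.size().values
    if (out["n"] == 0).any():
        warnings.warn("empty groups omitted from lick probability", stacklevel=2)
        out = out[out["n"] > 0]
    return out
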