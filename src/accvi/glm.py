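"""Outcome-history and task-variable regression on per-trial responses.

The history model regresses the mean stimulus response f(t) of Hit trials on
the outcomes of the five preceding trials,

    f(t) = intercept + sum_i w_i * O_(t-i),   O = 1 non-reward, 0 reward,

by ordinary least squares; trials without a complete 5-trial history are
dropped.  The task-variable model fits four regressors (stimulus = constant,
cumulative unexpected-outcome history in [0, 1], previous-outcome indicator,
licking rate) with 5-fold cross-validated least squares; each variable's
contribution is the drop in held-out explained variance when it is removed,
on identical folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ranksums, wilcoxon
from sklearn.model_selection import KFold

TASK_VARIABLES = ("stimulus", "cumulative_history", "previous_outcome", "lick_rate")


@dataclass
class GlmFit:
    intercept: float
    weights: np.ndarray
    r2_full: float | None = None
    contributions: dict = field(default_factory=dict)
    rank_deficient: bool = False
    neuron_id: int | None = None


def _ols(X: np.ndarray, y: np.ndarray):
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    return coef, rank < X.shape[1]


def fit_outcome_history(responses, outcomes_nonreward, lags: int = 5) -> GlmFit:
    """OLS of per-trial responses on the ``lags`` preceding outcome indicators.

    ``outcomes_nonreward`` is the full per-trial 0/1 outcome sequence
    (1 = non-reward); ``responses`` the aligned per-trial response values
    (NaN for trials not fitted, e.g. non-Hit trials).  The first ``lags``
    trials are dropped.
    """
    y_all = np.asarray(responses, dtype=float)
    o = np.asarray(outcomes_nonreward, dtype=float)
    if y_all.shape != o.shape:
        raise ValueError("responses and outcomes must align")
    t_idx = np.arange(lags, len(y_all))
    usable = t_idx[np.isfinite(y_all[t_idx])]
    if len(usable) < lags + 2:
        raise ValueError(f"need >= {lags + 2} usable trials after dropping incomplete history")
    X = np.column_stack([np.ones(len(usable))] + [o[usable - i] for i in range(1, lags + 1)])
    coef, deficient = _ols(X, y_all[usable])
    return GlmFit(intercept=float(coef[0]), weights=coef[1:], rank_deficient=deficient)


def build_task_design(trials: pd.DataFrame, stimulus_window=(0.0, 1.0)) -> pd.DataFrame:
    """Four task-variable regressors on the go trials of an Uncertain session."""
    t = trials.reset_index(drop=True)
    unexpected = t["trial_type"].isin(["RO", "UR"]).to_numpy().astype(float)
    cum = np.concatenate([[0.0], np.cumsum(unexpected)[:-1]])
    denom = np.maximum(np.arange(len(t)), 1)
    cumulative = cum / denom
    prev = np.concatenate([[0.0], unexpected[:-1]])
    span = stimulus_window[1] - stimulus_window[0]
    lick_rate = t["n_licks"].to_numpy(dtype=float) / span
    design = pd.DataFrame(
        {
            "stimulus": 1.0,
            "cumulative_history": cumulative,
            "previous_outcome": prev,
            "lick_rate": lick_rate,
        }
    )
    design["is_go"] = t["trial_type"].isin(["go", "RO"]).to_numpy()
    return design


def _cv_r2(X: np.ndarray, y: np.ndarray, folds: int, seed: int = 0) -> float:
    """Held-out explained variance 1 - SSE/SST, SST from the held-out fold."""
    kf = KFold(folds, shuffle=True, random_state=seed)
    r2s = []
    for tr, te in kf.split(X):
        coef, _ = _ols(X[tr], y[tr])
        resid = y[te] - X[te] @ coef
        sst = ((y[te] - y[te].mean()) ** 2).sum()
        r2s.append(1.0 - resid @ resid / sst if sst > 0 else 0.0)
    return float(np.mean(r2s))


def fit_task_variables(responses, design: pd.DataFrame, folds: int = 5, seed: int = 0) -> GlmFit:
    """Cross-validated least squares of responses on the task variables.

    Also fills ``contributions``: per variable, the decrease in held-out
    explained variance when that variable is removed (same folds).
    """
    y = np.asarray(responses, dtype=float)
    cols = [c for c in TASK_VARIABLES if c in design.columns]
    X = design[cols].to_numpy(dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError("responses and design must align")
    ok = np.isfinite(y)
    X, y = X[ok], y[ok]
    coef, deficient = _ols(X, y)
    fit = GlmFit(intercept=float(coef[0]), weights=coef[1:], rank_deficient=deficient)
    fit.r2_full = _cv_r2(X, y, folds, seed)
    for i, name in enumerate(cols):
        keep = [j for j in range(len(cols)) if j != i]
        fit.contributions[name] = fit.r2_full - _cv_r2(X[:, keep], y, folds, seed)
    return fit


def variable_contribution(fit: GlmFit, variable: str) -> float:
    """Drop in held-out explained variance when ``variable`` is removed."""
    if variable not in fit.contributions:
        raise KeyError(f"unknown variable {variable!r}")
    return fit.contributions[variable]


def group_coefficient_test(weights_by_neuron: np.ndarray, lag: int, other: np.ndarray | None = None):
    """Population-level tests of one history-lag coefficient.

    One-sample signed-rank of the per-neuron coefficients against 0; when a
    second session's coefficients are given, also a rank-sum between the two
    sets.  Returns a dict of p-values and medians.
    """
    w = np.asarray(weights_by_neuron, dtype=float)[:, lag]
    if len(w) < 6:
        raise ValueError("need >= 6 neurons")
    if np.all(w == w[0]):
        import warnings

        warnings.warn("degenerate test: identical coefficients", stacklevel=2)
        return {"p_vs_zero": 1.0, "median": float(w[0])}
    out = {"p_vs_zero": float(wilcoxon(w).pvalue), "median": float(np.median(w))}
    if other is not None:
        w2 = np.asarray(other, dtype=float)[:, lag]
        out["p_between"] = float(ranksums(w, w2).pvalue)
    return out
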