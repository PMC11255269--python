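"""Adaptive-learning-rate SARSA model of go/no-go value iteration.

The agent tracks the incentive value of the modelled tone (3 kHz) through two
action values Q(lick), Q(no-lick).  After each trial the chosen action's value
moves toward the received reward by the prediction error

    dr_t = R_t - Q(A_t),        Q(A_t) <- Q(A_t) + alpha_t * dr_t

and the learning rate itself is iterated from the previous trial's error,

    alpha_t = clip(theta_prime * alpha_{t-1} + theta * |dr_{t-1}|, 0, 1),

so that runs of surprising outcomes transiently raise the impact of feedback
while confirmed expectations let it decay geometrically (rate theta_prime).
The first modelled trial uses alpha_0 directly.  Actions are sampled from a
softmax ("QP transformation") over the two values with inverse-temperature
beta.

Only 3 kHz-tone trials are modelled; the 12 kHz tone and un-cued-reward
trials neither sample from the policy nor update Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from ._rng import as_generator

__all__ = [
    "RLParams",
    "AgentTrace",
    "BETA_BY_SESSION",
    "policy_probability",
    "sarsa_update",
    "simulate_session",
    "learning_rate_summary",
    "recover_parameters",
]

#: Softmax scaling derived from task performance: 2.3 for Stable/Uncertain,
#: 1.68 for Reversal (Re-stable behaves like a learned Reversal contingency).
BETA_BY_SESSION = {"Stable": 2.3, "Uncertain": 2.3, "Reversal": 1.68, "Re-stable": 1.68}

#: Reward map: Hit 1, Miss 0.1, RO -0.1 (Stable/Uncertain); FA -2, CR 0.1
#: (Reversal, where the modelled tone is the punished no-go cue).
DEFAULT_REWARD_MAP = {"Hit": 1.0, "Miss": 0.1, "RO": -0.1, "FA": -2.0, "CR": 0.1}


@dataclass(frozen=True)
class RLParams:
    theta_prime: float = 0.6
    theta: float = 0.08
    alpha0: float = 0.1
    q0_lick: float = 0.98
    q0_nolick: float = 0.02
    beta: float = 2.3
    reward_map: dict = field(default_factory=lambda: dict(DEFAULT_REWARD_MAP))
    #: if False, no-lick trials (Miss/CR) leave Q untouched
    update_nolick: bool = True

    def __post_init__(self) -> None:
        if self.theta_prime < 0 or self.theta < 0:
            raise ValueError("theta_prime and theta must be non-negative")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")

    def for_session(self, session: str) -> "RLParams":
        return replace(self, beta=BETA_BY_SESSION[session])


@dataclass
class AgentTrace:
    """Per-trial model state, shaped (n_repeats, n_trials)."""

    q_lick: np.ndarray
    q_nolick: np.ndarray
    alpha: np.ndarray
    delta_r: np.ndarray
    p_lick: np.ndarray
    action: np.ndarray  # bool: True = lick
    outcome: np.ndarray  # unicode labels
    trial_type: np.ndarray

    @property
    def n_repeats(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_trials(self) -> int:
        return self.alpha.shape[1]


def policy_probability(q_lick, q_nolick, beta):
    """Softmax probability of licking, numerically stable for any finite input.

    p = exp(beta*q_lick) / (exp(beta*q_lick) + exp(beta*q_nolick)).
    """
    x = beta * (np.asarray(q_nolick, dtype=float) - np.asarray(q_lick, dtype=float))
    # logistic in the value difference; exp argument clipped only from above
    out = 1.0 / (1.0 + np.exp(np.minimum(x, 700.0)))
    return out if out.ndim else float(out)


def sarsa_update(q_lick, q_nolick, alpha, action_lick, outcome, params: RLParams):
    """One value-iteration step; returns (q_lick, q_nolick, delta_r, next_alpha).

    ``alpha`` is the learning rate applied on *this* trial; ``next_alpha`` is
    the rate the following trial will use, clipped to [0, 1].
    """
    if outcome not in params.reward_map:
        raise KeyError(f"outcome {outcome!r} not in reward map")
    r = params.reward_map[outcome]
    if action_lick:
        delta = r - q_lick
        q_lick = q_lick + alpha * delta
    else:
        delta = r - q_nolick
        if params.update_nolick:
            q_nolick = q_nolick + alpha * delta
    next_alpha = float(np.clip(params.theta_prime * alpha + params.theta * abs(delta), 0.0, 1.0))
    return q_lick, q_nolick, delta, next_alpha


def _modelled_trial_types(session: str, n_trials: int) -> tuple[np.ndarray, float]:
    """Types of the 3 kHz-tone trials of an ``n_trials``-trial session.

    Returns (base type array before shuffling, count). In Stable/Uncertain the
    3 kHz tone is the go cue (Uncertain: 1 in 5 modelled trials is an RO
    trial); in Reversal/Re-stable it is the no-go cue.
    """
    from .synthetic import largest_remainder_counts

    if session in ("Stable",):
        n = largest_remainder_counts([0.5], n_trials)[0]
        return np.array(["go"] * n), n
    if session == "Uncertain":
        n_go, n_ro = largest_remainder_counts([0.40, 0.10], n_trials)[:2]
        return np.array(["go"] * n_go + ["RO"] * n_ro), n_go + n_ro
    if session in ("Reversal", "Re-stable"):
        n = largest_remainder_counts([0.5], n_trials)[0]
        return np.array(["nogo"] * n), n
    raise ValueError(f"unknown session {session!r}")


def _outcome_for(trial_type: np.ndarray, lick: np.ndarray) -> np.ndarray:
    """Vectorised action-outcome rule on modelled (3 kHz) trials."""
    out = np.empty(trial_type.shape, dtype="<U4")
    is_go = trial_type == "go"
    is_ro = trial_type == "RO"
    is_nogo = trial_type == "nogo"
    out[is_go & lick] = "Hit"
    out[is_go & ~lick] = "Miss"
    out[is_ro & lick] = "RO"
    out[is_ro & ~lick] = "Miss"
    out[is_nogo & lick] = "FA"
    out[is_nogo & ~lick] = "CR"
    return out


def simulate_session(
    session: str,
    params: RLParams | None = None,
    n_trials: int = 80,
    n_repeats: int = 3000,
    seed=None,
) -> AgentTrace:
    """Simulate the modelled-tone trials of a session, vectorised over repeats.

    ``n_trials`` is the full session length; only its 3 kHz trials are
    iterated.  Each repeat reshuffles the trial-type order (Uncertain) and
    resamples actions from the policy.
    """
    rng = as_generator(seed)
    if params is None:
        params = RLParams().for_session(session)
    base_types, n_mod = _modelled_trial_types(session, n_trials)
    if n_mod == 0:
        raise ValueError(f"session {session!r} has no modelled 3 kHz trials")

    # per-repeat independent shuffles of the modelled trial types
    order = np.argsort(rng.random((n_repeats, n_mod)), axis=1)
    types = np.broadcast_to(base_types, (n_repeats, n_mod))
    types = np.take_along_axis(types, order, axis=1)

    q_l = np.full(n_repeats, params.q0_lick)
    q_n = np.full(n_repeats, params.q0_nolick)
    alpha = np.full(n_repeats, params.alpha0)
    rmap = params.reward_map

    tr = AgentTrace(
        q_lick=np.empty((n_repeats, n_mod)),
        q_nolick=np.empty((n_repeats, n_mod)),
        alpha=np.empty((n_repeats, n_mod)),
        delta_r=np.empty((n_repeats, n_mod)),
        p_lick=np.empty((n_repeats, n_mod)),
        action=np.empty((n_repeats, n_mod), dtype=bool),
        outcome=np.empty((n_repeats, n_mod), dtype="<U4"),
        trial_type=types.copy(),
    )

    for t in range(n_mod):
        p = policy_probability(q_l, q_n, params.beta)
        lick = rng.random(n_repeats) < p
        outcome = _outcome_for(types[:, t], lick)
        r = np.vectorize(rmap.__getitem__, otypes=[float])(outcome)
        q_chosen = np.where(lick, q_l, q_n)
        delta = r - q_chosen
        upd = alpha * delta
        q_l = np.where(lick, q_l + upd, q_l)
        if params.update_nolick:
            q_n = np.where(lick, q_n, q_n + upd)
        tr.q_lick[:, t] = q_l
        tr.q_nolick[:, t] = q_n
        tr.alpha[:, t] = alpha
        tr.delta_r[:, t] = delta
        tr.p_lick[:, t] = p
        tr.action[:, t] = lick
        tr.outcome[:, t] = outcome
        alpha = np.clip(params.theta_prime * alpha + params.theta * np.abs(delta), 0.0, 1.0)
    return tr


def learning_rate_summary(trace: AgentTrace, fractions=(1 / 3, 1 / 3, 1 / 3)):
    """Mean learning rate per phase across repeats, with a 95% sampling CI."""
    import pandas as pd

    from .behavior import split_phases

    labels = split_phases(trace.n_trials, fractions).phase
    rows = []
    for k, lab in enumerate(dict.fromkeys(labels)):
        sel = np.asarray(labels) == lab
        per_repeat = trace.alpha[:, sel].mean(axis=1)
        m = per_repeat.mean()
        half = 1.96 * per_repeat.std(ddof=1) / np.sqrt(len(per_repeat)) if len(per_repeat) > 1 else 0.0
        rows.append({"phase": lab, "mean_alpha": m, "ci_low": m - half, "ci_high": m + half})
    return pd.DataFrame(rows)


def _negloglik(free_vals, free_names, fixed: RLParams, actions, outcomes_r):
    """Negative Bernoulli log-likelihood of lick choices, vectorised over sessions.

    ``actions``: bool (n_sessions, n_trials); ``outcomes_r``: float rewards of
    the realised outcomes, same shape.
    """
    p = {name: v for name, v in zip(free_names, free_vals)}
    theta_prime = p.get("theta_prime", fixed.theta_prime)
    theta = p.get("theta", fixed.theta)
    beta = p.get("beta", fixed.beta)
    if theta_prime < 0 or theta < 0 or beta <= 0:
        return np.inf
    n_sessions, n_trials = actions.shape
    q_l = np.full(n_sessions, fixed.q0_lick)
    q_n = np.full(n_sessions, fixed.q0_nolick)
    alpha = np.full(n_sessions, fixed.alpha0)
    ll = 0.0
    for t in range(n_trials):
        p_lick = policy_probability(q_l, q_n, beta)
        lick = actions[:, t]
        pr = np.where(lick, p_lick, 1.0 - p_lick)
        ll += np.log(np.clip(pr, 1e-12, None)).sum()
        q_chosen = np.where(lick, q_l, q_n)
        delta = outcomes_r[:, t] - q_chosen
        upd = alpha * delta
        q_l = np.where(lick, q_l + upd, q_l)
        if fixed.update_nolick:
            q_n = np.where(lick, q_n, q_n + upd)
        alpha = np.clip(theta_prime * alpha + theta * np.abs(delta), 0.0, 1.0)
    return -ll


def recover_parameters(
    actions: np.ndarray,
    outcomes: np.ndarray,
    fixed: RLParams | None = None,
    free: tuple[str, ...] = ("theta_prime", "theta", "beta"),
    grid_size: int = 7,
):
    """Fit free SARSA parameters to observed choice sequences by maximum likelihood.

    Parameters
    ----------
    actions : bool array (n_sessions, n_trials)
        Lick choices on the modelled 3 kHz trials of equal-length sessions.
    outcomes : str array, same shape
        Realised outcome labels (keys of the reward map).
    fixed : RLParams
        Values for the parameters held fixed (Q0, alpha0, reward map, and any
        of theta_prime/theta/beta not in ``free``).
    free : names of the parameters to estimate.

    Returns a dict with the estimates and ``loglik``.  A coarse grid search
    seeds a Nelder-Mead refinement.
    """
    if len(free) == 0:
        raise ValueError("at least one parameter must be free")
    fixed = fixed or RLParams()
    actions = np.asarray(actions, dtype=bool)
    if actions.ndim != 2 or actions.shape[1] < 1:
        raise ValueError("actions must be (n_sessions, n_trials)")
    if actions.all() or (~actions).all():
        import warnings

        warnings.warn("degenerate action sequence: all choices identical", stacklevel=2)
    rmap = fixed.reward_map
    outcomes_r = np.vectorize(rmap.__getitem__, otypes=[float])(np.asarray(outcomes))

    grids = {
        "theta_prime": np.linspace(0.05, 0.95, grid_size),
        "theta": np.linspace(0.01, 0.25, grid_size),
        "beta": np.linspace(0.8, 4.0, grid_size),
    }
    mesh = np.meshgrid(*[grids[name] for name in free], indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    best = None
    for row in pts:
        nll = _negloglik(row, free, fixed, actions, outcomes_r)
        if best is None or nll < best[0]:
            best = (nll, row)
    res = optimize.minimize(
        _negloglik,
        best[1],
        args=(free, fixed, actions, outcomes_r),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 2000},
    )
    out = {name: float(v) for name, v in zip(free, res.x)}
    out["loglik"] = -float(res.fun)
    return out
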