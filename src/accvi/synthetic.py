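"""Synthetic go/no-go sessions with ground-truth calcium population structure.

The generator emulates the auditory discrimination task: a 1-s pure tone
(3 kHz or 12 kHz), a 2-s response window, and a 4-6 s inter-trial interval.
Session compositions are 50/50 go/no-go (Stable, Re-stable), 40/40/10/10
go/no-go/RO/UR (Uncertain), and reversed 50/50 (Reversal).  Choices on the
modelled 3 kHz tone come from the adaptive-learning-rate SARSA agent; the
other tone licks with a fixed per-session probability.

Each neuron's fluorescence is a baseline plus event-locked transients
(single-exponential kernel, GCaMP6f-like tau = 0.4 s) whose amplitudes carry
the planted structure the downstream analyses look for: outcome-monitoring
neurons respond to surprising outcomes (RO, early air-puff) at >= 2x their
expected-outcome response; value-updating neurons halve their 3 kHz-cue
response from the early to the late period; planted history weights couple
the go-cue amplitude to recent non-reward outcomes; everything else is
multiplicative amplitude jitter and additive Gaussian frame noise.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import as_generator
from .behavior import classify_outcomes, split_phases
from .config import (
    DEFAULT_EARLY_FRACTIONS,
    DEFAULT_PHASE_FRACTIONS,
    DEFAULT_SESSION_DESIGNS,
    ConfigError,
    RunConfig,
)
from .sarsa import RLParams, policy_probability, sarsa_update

#: tone played for each trial type, per session
STIMULUS_MAPS = {
    "Stable": {"go": "3kHz", "nogo": "12kHz"},
    "Uncertain": {"go": "3kHz", "nogo": "12kHz", "RO": "3kHz", "UR": "none"},
    "Reversal": {"go": "12kHz", "nogo": "3kHz"},
    "Re-stable": {"go": "12kHz", "nogo": "3kHz"},
}

#: fixed lick probability on the tone not modelled by the agent.  Proficient
#: mice rarely false-alarm on the 12 kHz no-go cue; in Reversal/Re-stable the
#: 12 kHz tone is the rewarded cue and is mostly licked.
DEFAULT_NONTONE_LICK_P = {"Stable": 0.10, "Uncertain": 0.10, "Reversal": 0.80, "Re-stable": 0.90}

#: outcome labels mapped to the trial-table vocabulary
OUTCOME_TO_CSV = {"Hit": "reward", "Miss": "none", "FA": "punishment", "CR": "none",
                  "RO": "omission", "UR": "reward"}


@dataclass
class SessionDesign:
    name: str
    n_trials: int = 100
    proportions: dict = None
    stimulus_map: dict = None
    phase_fractions: tuple = None
    early_fraction: float = None

    def __post_init__(self):
        if self.name not in STIMULUS_MAPS:
            raise ConfigError(f"unknown session name: {self.name!r}")
        if self.proportions is None:
            self.proportions = dict(DEFAULT_SESSION_DESIGNS[self.name])
        if self.stimulus_map is None:
            self.stimulus_map = dict(STIMULUS_MAPS[self.name])
        if self.phase_fractions is None:
            self.phase_fractions = DEFAULT_PHASE_FRACTIONS[self.name]
        if self.early_fraction is None:
            self.early_fraction = DEFAULT_EARLY_FRACTIONS[self.name]
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise ConfigError(f"proportions for {self.name} must sum to 1")


def largest_remainder_counts(fractions, n: int) -> list[int]:
    """Integer counts from fractions: round-half-up each, remainder absorbed
    by the largest fraction so a complete set sums exactly to ``n``."""
    fractions = list(fractions)
    counts = [int(math.floor(f * n + 0.5)) for f in fractions]
    if abs(sum(fractions) - 1.0) < 1e-9:
        counts[int(np.argmax(fractions))] += n - sum(counts)
    return counts


def generate_session_trials(design: SessionDesign, seed=None) -> pd.DataFrame:
    """Trial table with types in exact design proportions, uniformly shuffled.

    Actions and outcomes are left unset; inter-trial intervals are uniform on
    [4, 6] s.
    """
    if design.n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    rng = as_generator(seed)
    types = sorted(design.proportions)  # stable ordering for reproducibility
    counts = largest_remainder_counts([design.proportions[t] for t in types], design.n_trials)
    seq = np.repeat(types, counts)
    rng.shuffle(seq)
    fractions = design.phase_fractions
    if design.n_trials < len(fractions):  # degenerate tiny sessions: one phase
        fractions = (1.0,)
    phases = split_phases(design.n_trials, fractions, design.early_fraction)
    return pd.DataFrame(
        {
            "session": design.name,
            "trial_index": np.arange(design.n_trials),
            "phase": phases.phase,
            "period": phases.period,
            "stimulus": [design.stimulus_map[t] for t in seq],
            "trial_type": seq,
            "action": pd.Series([pd.NA] * design.n_trials, dtype=object),
            "outcome": pd.Series([pd.NA] * design.n_trials, dtype=object),
            "first_lick_s": np.nan,
            "n_licks": 0,
            "iti_s": rng.uniform(4.0, 6.0, design.n_trials),
        }
    )


def simulate_agent_behavior(
    trials: pd.DataFrame,
    params: RLParams | None = None,
    seed=None,
    nontone_lick_p: float | None = None,
) -> pd.DataFrame:
    """Fill actions/outcomes: SARSA policy on 3 kHz trials, fixed rule elsewhere.

    Per-trial ground truth (q_lick, q_nolick, alpha, delta_r, p_lick) is
    recorded for the modelled trials.  Simulated lick times are a modeling
    convenience (uniform on [1.05, 1.8] s) and carry no task structure.
    """
    rng = as_generator(seed)
    session = trials["session"].iloc[0]
    if params is None:
        params = RLParams().for_session(session)
    if nontone_lick_p is None:
        nontone_lick_p = DEFAULT_NONTONE_LICK_P[session]
    unknown = set(trials["trial_type"]) - {"go", "nogo", "RO", "UR"}
    if unknown:
        raise ValueError(f"unknown trial types: {sorted(unknown)}")

    t = trials.copy()
    for col in ("q_lick", "q_nolick", "alpha", "delta_r", "p_lick"):
        t[col] = np.nan
    q_l, q_n, alpha = params.q0_lick, params.q0_nolick, params.alpha0

    actions, outcomes = [], []
    for _, row in t.iterrows():
        ttype = row["trial_type"]
        if row["stimulus"] == "3kHz":
            p = policy_probability(q_l, q_n, params.beta)
            lick = rng.random() < p
            outcome = _rule_outcome(ttype, lick)
            t.loc[row.name, ["p_lick", "alpha"]] = (p, alpha)
            q_l, q_n, delta, alpha = sarsa_update(q_l, q_n, alpha, lick, outcome, params)
            t.loc[row.name, ["q_lick", "q_nolick", "delta_r"]] = (q_l, q_n, delta)
        elif ttype == "UR":
            lick, outcome = False, "UR"
        else:
            lick = rng.random() < nontone_lick_p
            outcome = _rule_outcome(ttype, lick)
        actions.append("lick" if lick else "nolick")
        outcomes.append(outcome)

    t["action"] = actions
    t["outcome_class"] = outcomes
    t["outcome"] = [OUTCOME_TO_CSV[o] for o in outcomes]
    licked = np.array(actions) == "lick"
    t.loc[licked, "first_lick_s"] = rng.uniform(1.05, 1.8, int(licked.sum()))
    t.loc[licked, "n_licks"] = rng.poisson(5, int(licked.sum())) + 1
    return t


def _rule_outcome(trial_type: str, lick: bool) -> str:
    if trial_type == "go":
        return "Hit" if lick else "Miss"
    if trial_type == "nogo":
        return "FA" if lick else "CR"
    if trial_type == "RO":
        return "RO" if lick else "Miss"
    if trial_type == "UR":
        return "UR"
    raise ValueError(f"unknown trial type {trial_type!r}")


@dataclass
class EffectSpec:
    """Amplitude/weight ranges for the planted population structure."""

    cue_amp_range: tuple = (0.3, 0.8)
    outcome_amp_range: tuple = (0.3, 0.8)
    twofold_ratio_range: tuple = (2.6, 3.6)  # planted surprise/decay ratio
    null_ratio_range: tuple = (0.85, 1.15)  # unplanted condition ratios
    history_fraction: float = 0.3
    history_base: tuple = (-0.3, -0.15, -0.05, 0.0, 0.0)
    noise_sd: float = 0.1
    amp_cv: float = 0.2
    kernel_tau: float = 0.4
    unresponsive_fraction: float = 0.05
    baseline_f_range: tuple = (0.5, 2.0)


@dataclass
class NeuronGroundTruth:
    """Planted per-neuron parameters and class flags.

    ``cue_amp[stim]`` and ``outcome_amp[label]`` are (n_neurons, 2) arrays of
    mean event amplitudes in the early/late periods (dF/F units).
    """

    flags: pd.DataFrame
    cue_amp: dict
    outcome_amp: dict
    history_weights: np.ndarray
    noise_sd: np.ndarray
    amp_cv: float
    kernel_tau: float
    baseline_f: np.ndarray

    @property
    def n_neurons(self) -> int:
        return len(self.flags)

    def to_json(self, path) -> None:
        payload = {
            "flags": {c: self.flags[c].astype(bool).tolist() for c in self.flags.columns},
            "cue_amp": {k: v.tolist() for k, v in self.cue_amp.items()},
            "outcome_amp": {k: v.tolist() for k, v in self.outcome_amp.items()},
            "history_weights": self.history_weights.tolist(),
            "noise_sd": self.noise_sd.tolist(),
            "amp_cv": self.amp_cv,
            "kernel_tau": self.kernel_tau,
            "baseline_f": self.baseline_f.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


DEFAULT_CLASS_MIX = {"monitoring": 0.33, "updating": 0.21, "dual": 0.07}


def generate_population(
    n_neurons: int,
    class_mix: dict | None = None,
    effect_spec: EffectSpec | None = None,
    seed=None,
) -> NeuronGroundTruth:
    """Draw a population with planted functional classes.

    ``class_mix`` gives fractions of outcome-monitoring, value-updating and
    dual-function neurons (dual is a subset of both); counts use the
    largest-remainder rounding so fixtures are exactly reproducible.
    """
    mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    spec = effect_spec or EffectSpec()
    if spec.noise_sd < 0 or spec.kernel_tau <= 0:
        raise ConfigError("noise_sd must be >= 0 and kernel_tau > 0")
    if not all(0.0 <= v <= 1.0 for v in mix.values()):
        raise ConfigError("class_mix fractions must lie in [0, 1]")
    if mix["dual"] > min(mix["monitoring"], mix["updating"]) + 1e-12:
        raise ConfigError("dual fraction cannot exceed monitoring or updating fraction")
    rng = as_generator(seed)

    n_mon = int(math.floor(mix["monitoring"] * n_neurons + 0.5))
    n_upd = int(math.floor(mix["updating"] * n_neurons + 0.5))
    n_dual = int(math.floor(mix["dual"] * n_neurons + 0.5))
    if n_dual > min(n_mon, n_upd):
        raise ConfigError("infeasible class mix after rounding")

    monitoring = np.zeros(n_neurons, dtype=bool)
    updating = np.zeros(n_neurons, dtype=bool)
    order = rng.permutation(n_neurons)
    monitoring[order[:n_mon]] = True
    updating[order[:n_dual]] = True  # dual = first block of monitoring neurons
    updating[order[n_mon : n_mon + (n_upd - n_dual)]] = True
    plain = ~(monitoring | updating)
    n_unresp = int(math.floor(spec.unresponsive_fraction * n_neurons + 0.5))
    unresp_pool = order[np.isin(order, np.nonzero(plain)[0])]
    unresponsive = np.zeros(n_neurons, dtype=bool)
    unresponsive[unresp_pool[:n_unresp]] = True
    responsive = ~unresponsive

    def u(lo_hi, size=n_neurons):
        return rng.uniform(*lo_hi, size)

    cue_late_3k = u(spec.cue_amp_range)
    upd_ratio = np.where(updating, u(spec.twofold_ratio_range), u(spec.null_ratio_range))
    cue_amp = {
        "3kHz": np.stack([cue_late_3k * upd_ratio, cue_late_3k], axis=1),
        "12kHz": np.repeat(u(spec.cue_amp_range)[:, None], 2, axis=1),
    }
    hit = u(spec.outcome_amp_range)
    mon_ratio = np.where(monitoring, u(spec.twofold_ratio_range), u(spec.null_ratio_range))
    fa_late = u(spec.outcome_amp_range)
    outcome_amp = {
        "Hit": np.repeat(hit[:, None], 2, axis=1),
        "RO": np.repeat((hit * mon_ratio)[:, None], 2, axis=1),
        "UR": np.repeat((hit * mon_ratio)[:, None], 2, axis=1),
        "FA": np.stack([fa_late * mon_ratio, fa_late], axis=1),
        "CR": np.repeat(u((0.02, 0.10))[:, None], 2, axis=1),
        "Miss": np.zeros((n_neurons, 2)),
    }
    for amp in list(cue_amp.values()) + list(outcome_amp.values()):
        amp[unresponsive] = 0.0

    history_weights = np.zeros((n_neurons, 5))
    has_hist = rng.random(n_neurons) < spec.history_fraction
    scale = rng.uniform(0.5, 1.5, n_neurons)
    history_weights[has_hist] = np.outer(scale[has_hist], np.asarray(spec.history_base))

    flags = pd.DataFrame(
        {
            "outcome_monitoring": monitoring,
            "value_updating": updating,
            "dual": monitoring & updating,
            "responsive": responsive,
        }
    )
    flags.index.name = "neuron"
    return NeuronGroundTruth(
        flags=flags,
        cue_amp=cue_amp,
        outcome_amp=outcome_amp,
        history_weights=history_weights,
        noise_sd=np.full(n_neurons, float(spec.noise_sd)),
        amp_cv=spec.amp_cv,
        kernel_tau=spec.kernel_tau,
        baseline_f=u(spec.baseline_f_range),
    )


def render_fluorescence(
    trials: pd.DataFrame,
    truth: NeuronGroundTruth,
    config: RunConfig | None = None,
    seed=None,
    frame_window=(-2.0, 4.0),
):
    """Render raw fluorescence (neurons, trials, frames) from the ground truth.

    Each trial is baseline * (1 + transients + noise): a cue transient at
    stimulus onset and an outcome transient at reward/omission/punishment
    delivery (the first response-window lick; un-cued rewards at +1 s), each
    an exponential-decay kernel scaled by the planted condition/period
    amplitude, with go-cue amplitudes shifted by the planted outcome-history
    weights.
    """
    from .io import FluorescenceTensor

    config = config or RunConfig()
    rng = as_generator(seed)
    rate = config.frame_rate
    lo, hi = frame_window
    if lo > config.baseline_dff[0]:
        raise ConfigError("frame window too short to contain the dF/F baseline")
    n_frames = int(round((hi - lo) * rate))
    t0 = int(round(-lo * rate))
    n_neurons = truth.n_neurons
    n_trials = len(trials)
    if "outcome_class" not in trials:
        trials = classify_outcomes(trials)

    tau_frames = truth.kernel_tau * rate
    decay = np.exp(-np.arange(n_frames) / tau_frames)
    period_idx = (np.asarray(trials["period"]) == "late").astype(int)

    # O = 1 for non-rewarded outcomes, lag matrix over the session
    o = (~trials["outcome_class"].isin(["Hit", "UR"])).astype(float).to_numpy()
    sig = np.zeros((n_neurons, n_trials, n_frames))

    def add_event(j, frame, amp):
        jit = np.maximum(amp * (1.0 + truth.amp_cv * rng.standard_normal(n_neurons)), 0.0)
        span = n_frames - frame
        sig[:, j, frame:] += jit[:, None] * decay[:span][None, :]

    for j, row in enumerate(trials.itertuples(index=False)):
        per = period_idx[j]
        if row.stimulus != "none":
            amp = truth.cue_amp[row.stimulus][:, per].copy()
            if row.trial_type in ("go", "RO"):
                hist = sum(
                    truth.history_weights[:, i - 1] * o[j - i] for i in range(1, 6) if j - i >= 0
                )
                amp = amp + hist
            add_event(j, t0, amp)
        oc = row.outcome_class
        if oc in ("Hit", "RO", "FA"):
            ev = t0 + int(math.floor(row.first_lick_s * rate))
            add_event(j, ev, truth.outcome_amp[oc][:, per])
        elif oc == "UR":
            add_event(j, t0 + int(round(1.0 * rate)), truth.outcome_amp["UR"][:, per])

    noise = truth.noise_sd[:, None, None] * rng.standard_normal((n_neurons, n_trials, n_frames))
    F = truth.baseline_f[:, None, None] * (1.0 + sig + noise)
    return FluorescenceTensor(F=F, frame_rate=rate, t0_frame=t0)


def generate_dataset(config: RunConfig | None = None, seed=None, sessions=None):
    """Full synthetic study: one tracked population across all sessions."""
    from .io import Dataset

    config = config or RunConfig()
    rng = as_generator(config.seed if seed is None else seed)
    sessions = sessions or list(config.session_designs)
    truth = generate_population(config.n_neurons, seed=rng)
    trials, fluo = {}, {}
    for name in sessions:
        design = SessionDesign(
            name,
            n_trials=config.n_trials,
            proportions=dict(config.session_designs[name]),
            phase_fractions=config.phase_fractions[name],
        )
        t = generate_session_trials(design, seed=rng)
        t = simulate_agent_behavior(t, seed=rng)
        trials[name] = t
        fluo[name] = render_fluorescence(t, truth, config, seed=rng)
    ds = Dataset(trials=trials, fluorescence=fluo, neuron_ids=list(range(config.n_neurons)))
    ds.ground_truth = truth
    return ds
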