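import math

import numpy as np
import pandas as pd
import pytest

from accvi.config import ConfigError, RunConfig
from accvi.synthetic import (
    EffectSpec,
    SessionDesign,
    generate_population,
    generate_session_trials,
    largest_remainder_counts,
    render_fluorescence,
    simulate_agent_behavior,
)


class TestTrialGeneration:
    def test_uncertain_composition_exact(self):
        t = generate_session_trials(SessionDesign("Uncertain", n_trials=100), seed=0)
        counts = t["trial_type"].value_counts()
        assert counts["go"] == 40 and counts["nogo"] == 40
        assert counts["RO"] == 10 and counts["UR"] == 10

    def test_smallest_balanced_stable(self):
        t = generate_session_trials(SessionDesign("Stable", n_trials=2), seed=0)
        assert sorted(t["trial_type"]) == ["go", "nogo"]

    def test_counts_exact_at_awkward_n(self):
        for n in (37, 61, 99):
            t = generate_session_trials(SessionDesign("Uncertain", n_trials=n), seed=1)
            assert len(t) == n
            counts = [
                int((t["trial_type"] == k).sum()) for k in ("RO", "UR", "go", "nogo")
            ]
            expected = largest_remainder_counts([0.1, 0.1, 0.4, 0.4], n)
            # both orderings feed the same largest-remainder rule
            assert sorted(counts) == sorted(expected)

    def test_same_seed_same_order(self):
        a = generate_session_trials(SessionDesign("Reversal", n_trials=80), seed=7)
        b = generate_session_trials(SessionDesign("Reversal", n_trials=80), seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_iti_in_range(self):
        t = generate_session_trials(SessionDesign("Stable", n_trials=50), seed=3)
        assert t["iti_s"].between(4.0, 6.0).all()

    def test_bad_proportions_rejected(self):
        with pytest.raises(ConfigError):
            SessionDesign("Stable", proportions={"go": 0.6, "nogo": 0.6})


class TestAgentBehavior:
    def test_initial_lick_probability_matches_softmax(self):
        """The first modelled trial's P(lick) is the softmax of Q0."""
        t = generate_session_trials(SessionDesign("Stable", n_trials=60), seed=2)
        t = simulate_agent_behavior(t, seed=3)
        first = t.dropna(subset=["p_lick"]).iloc[0]
        assert first["p_lick"] == pytest.approx(0.90097, abs=1e-4)

    def test_infinite_beta_always_licks_modelled_tone(self):
        from accvi.sarsa import RLParams

        t = generate_session_trials(SessionDesign("Stable", n_trials=40), seed=2)
        t = simulate_agent_behavior(t, params=RLParams(beta=1e6), seed=3)
        tone = t[t["stimulus"] == "3kHz"]
        assert (tone["action"] == "lick").all()

    def test_deterministic_under_seed(self):
        t = generate_session_trials(SessionDesign("Uncertain", n_trials=60), seed=4)
        a = simulate_agent_behavior(t, seed=5)
        b = simulate_agent_behavior(t, seed=5)
        assert (a["action"] == b["action"]).all()
        assert np.allclose(a["q_lick"], b["q_lick"], equal_nan=True)

    def test_outcome_rule(self):
        t = generate_session_trials(SessionDesign("Uncertain", n_trials=100), seed=6)
        t = simulate_agent_behavior(t, seed=7)
        licked = t["action"] == "lick"
        assert (t.loc[(t.trial_type == "go") & licked, "outcome_class"] == "Hit").all()
        assert (t.loc[(t.trial_type == "RO") & licked, "outcome_class"] == "RO").all()
        assert (t.loc[t.trial_type == "UR", "outcome_class"] == "UR").all()


class TestPopulation:
    def test_class_counts_at_reference_mix(self):
        truth = generate_population(549, seed=0)
        assert truth.flags["outcome_monitoring"].sum() == 181  # round(.33 * 549)
        assert truth.flags["value_updating"].sum() == 115  # round(.21 * 549)
        assert truth.flags["dual"].sum() == 38  # round(.07 * 549)

    def test_single_neuron_all_zero_effects_unresponsive(self):
        spec = EffectSpec(unresponsive_fraction=1.0)
        truth = generate_population(1, class_mix={"monitoring": 0, "updating": 0, "dual": 0},
                                    effect_spec=spec, seed=1)
        assert not truth.flags["responsive"].iloc[0]
        assert truth.cue_amp["3kHz"][0].sum() == 0.0

    def test_infeasible_mix_rejected(self):
        with pytest.raises(ConfigError):
            generate_population(100, class_mix={"monitoring": 0.1, "updating": 0.1, "dual": 0.2})

    def test_planted_inequalities_hold_in_expectation(self):
        truth = generate_population(200, seed=2)
        mon = truth.flags["outcome_monitoring"].to_numpy()
        upd = truth.flags["value_updating"].to_numpy()
        ro, hit = truth.outcome_amp["RO"][:, 0], truth.outcome_amp["Hit"][:, 0]
        assert (ro[mon] - hit[mon] > hit[mon]).all()  # two-fold margin planted
        early, late = truth.cue_amp["3kHz"].T
        assert (early[upd] - late[upd] > late[upd]).all()
        resp = truth.flags["responsive"].to_numpy()
        assert not (ro[~mon & resp] - hit[~mon & resp] > hit[~mon & resp]).any()

    def test_deterministic_under_seed(self):
        a = generate_population(50, seed=9)
        b = generate_population(50, seed=9)
        assert np.array_equal(a.cue_amp["3kHz"], b.cue_amp["3kHz"])
        assert a.flags.equals(b.flags)


class TestRendering:
    def _one_trial(self, lick=False):
        t = pd.DataFrame(
            {
                "session": "Stable",
                "trial_index": [0],
                "phase": "T1",
                "period": "early",
                "stimulus": "3kHz",
                "trial_type": "go",
                "action": "lick" if lick else "nolick",
                "first_lick_s": 1.2 if lick else np.nan,
                "n_licks": 5 if lick else 0,
            }
        )
        return t

    def test_zero_amplitude_zero_noise_constant(self, noiseless_spec):
        import dataclasses

        spec = dataclasses.replace(noiseless_spec, cue_amp_range=(0.0, 0.0),
                                   outcome_amp_range=(0.0, 0.0), unresponsive_fraction=1.0)
        truth = generate_population(3, class_mix={"monitoring": 0, "updating": 0, "dual": 0},
                                    effect_spec=spec, seed=0)
        tensor = render_fluorescence(self._one_trial(), truth, seed=1)
        # each neuron's trace is flat at its own baseline level
        assert np.ptp(tensor.F, axis=2).max() == pytest.approx(0.0, abs=1e-14)

    def test_single_event_matches_exponential_kernel(self, noiseless_spec):
        truth = generate_population(1, class_mix={"monitoring": 0, "updating": 0, "dual": 0},
                                    effect_spec=noiseless_spec, seed=0)
        tensor = render_fluorescence(self._one_trial(), truth, seed=1)
        trace = tensor.F[0, 0] / truth.baseline_f[0] - 1.0
        t0 = tensor.t0_frame
        amp = truth.cue_amp["3kHz"][0, 0]
        frames = np.arange(tensor.F.shape[2] - t0)
        expected = amp * np.exp(-frames / (0.4 * tensor.frame_rate))
        assert np.allclose(trace[t0:], expected, atol=1e-12)
        assert np.allclose(trace[:t0], 0.0, atol=1e-12)

    def test_planted_monitoring_neuron_two_fold_in_generator(self):
        """Monte-Carlo on the generator: RO response > 2x Hit response."""
        design = SessionDesign("Uncertain", n_trials=200)
        trials = simulate_agent_behavior(generate_session_trials(design, seed=0), seed=1)
        truth = generate_population(30, class_mix={"monitoring": 1.0, "updating": 0.0, "dual": 0.0},
                                    seed=2)
        tensor = render_fluorescence(trials, truth, seed=3)
        from accvi.calcium import window_mean

        lick_frames = tensor.t0_frame + np.floor(trials["first_lick_s"].to_numpy() * tensor.frame_rate)
        dff_proxy = tensor.F / truth.baseline_f[:, None, None] - 1.0
        vals = window_mean(dff_proxy, tensor.frame_rate, tensor.t0_frame, (0, 1),
                           event_frames=lick_frames)
        ro = np.nanmean(vals[:, (trials["outcome_class"] == "RO").to_numpy()], axis=1)
        hit = np.nanmean(vals[:, (trials["outcome_class"] == "Hit").to_numpy()], axis=1)
        assert ((ro - hit) > hit).mean() > 0.95

    def test_frame_window_must_cover_baseline(self, noiseless_spec):
        truth = generate_population(1, effect_spec=noiseless_spec, seed=0)
        with pytest.raises(ConfigError):
            render_fluorescence(self._one_trial(), truth, seed=1, frame_window=(-1.0, 4.0))

    def test_rendering_deterministic(self, uncertain_session):
        trials, tensor, truth = uncertain_session
        again = render_fluorescence(trials, truth, RunConfig(), seed=14)
        assert np.array_equal(tensor.F, again.F)
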