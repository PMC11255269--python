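import numpy as np
import pandas as pd
import pytest

from accvi.geometry import (
    bootstrap_trajectory_metric,
    build_condition_matrix,
    compute_geometry,
    embed_trajectories,
    population_correlation,
    trajectory_distance,
    trajectory_length,
)

RATE, T0 = 30.0, 60


def brute_length(pts):
    return sum(
        np.sqrt(sum((pts[i + 1][d] - pts[i][d]) ** 2 for d in range(len(pts[0]))))
        for i in range(len(pts) - 1)
    )


def brute_distance(a, b):
    return sum(
        np.sqrt(sum((a[i][d] - b[i][d]) ** 2 for d in range(len(a[0]))))
        for i in range(len(a))
    )


def make_session(rng, n_neurons=20, n_trials=30, drift=0.0):
    trials = pd.DataFrame(
        {
            "trial_type": rng.permutation(["go"] * (n_trials // 2) + ["nogo"] * (n_trials // 2)),
        }
    )
    z = rng.normal(0, 0.3, (n_neurons, n_trials, 120))
    go = (trials["trial_type"] == "go").to_numpy()
    amp = rng.uniform(0.5, 1.5, n_neurons)
    z[:, go, T0:] += amp[:, None, None]
    z[:, ~go, T0:] += (amp + drift)[:, None, None]
    return trials, z


class TestConditionMatrix:
    def test_shape_and_centering(self, rng):
        trials, z = make_session(rng, n_neurons=10)
        conds = {"go": (trials.trial_type == "go").to_numpy(),
                 "nogo": (trials.trial_type == "nogo").to_numpy()}
        mat, times, n_t = build_condition_matrix(z, trials, conds, RATE, T0)
        assert mat.shape == (2 * n_t, 10)
        assert n_t == 45  # [-0.5, 1) s at 30 frames/s
        assert np.allclose(mat.mean(axis=0), 0.0, atol=1e-12)

    def test_empty_condition_named_in_error(self, rng):
        trials, z = make_session(rng)
        with pytest.raises(ValueError, match="phantom"):
            build_condition_matrix(z, trials, {"phantom": np.zeros(len(trials), bool)}, RATE, T0)

    def test_identical_conditions_identical_blocks(self, rng):
        trials, z = make_session(rng)
        sel = (trials.trial_type == "go").to_numpy()
        mat, _, n_t = build_condition_matrix(z, trials, {"a": sel, "b": sel}, RATE, T0)
        assert np.allclose(mat[:n_t], mat[n_t:])


class TestEmbedding:
    def test_line_data_single_component(self):
        t = np.linspace(0, 1, 40)
        mat = np.outer(t, np.ones(6))  # rank 1 after centering
        res = embed_trajectories(mat - mat.mean(0), ["a"], t)
        assert res.explained_variance[0] == pytest.approx(1.0)

    def test_rotation_invariance(self, rng):
        mat = rng.normal(size=(50, 8))
        q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
        ev1 = embed_trajectories(mat, ["a"], np.arange(50)).explained_variance
        ev2 = embed_trajectories(mat @ q, ["a"], np.arange(50)).explained_variance
        assert np.allclose(ev1, ev2, atol=1e-10)


class TestMetrics:
    def test_static_trajectory_zero_length(self):
        times = np.linspace(0, 0.9, 10)
        assert trajectory_length(np.ones((10, 3)), times) == 0.0

    def test_two_points_distance_three(self):
        times = np.array([0.0, 0.5])
        pts = np.array([[0, 0, 0], [3, 0, 0]], float)
        assert trajectory_length(pts, times) == pytest.approx(3.0)

    def test_constant_offset_distance(self):
        times = np.linspace(0, 0.9, 10)
        a = np.zeros((10, 3))
        b = a + np.array([0.3, 0.4, 0.0])  # offset norm 0.5
        assert trajectory_distance(a, b, times) == pytest.approx(10 * 0.5)
        assert trajectory_distance(b, a, times) == trajectory_distance(a, b, times)

    def test_brute_force_oracles(self, rng):
        times = np.linspace(0, 0.99, 25)
        a = rng.normal(size=(25, 3))
        b = rng.normal(size=(25, 3))
        assert trajectory_length(a, times) == pytest.approx(brute_length(a.tolist()), abs=1e-12)
        assert trajectory_distance(a, b, times) == pytest.approx(
            brute_distance(a.tolist(), b.tolist()), abs=1e-12
        )

    def test_detour_no_shorter_than_endpoint_distance(self, rng):
        times = np.linspace(0, 0.9, 12)
        pts = rng.normal(size=(12, 3))
        endpoint = np.linalg.norm(pts[-1] - pts[0])
        assert trajectory_length(pts, times) >= endpoint - 1e-12

    def test_identical_conditions_zero_distance(self, rng):
        trials, z = make_session(rng)
        sel = (trials.trial_type == "go").to_numpy()
        res = compute_geometry(z, trials, {"a": sel, "b": sel}, RATE, T0)
        assert res.pairwise_distance[("a", "b")] == pytest.approx(0.0, abs=1e-9)

    def test_neuron_permutation_invariance(self, rng):
        trials, z = make_session(rng, drift=0.5)
        conds = {"go": (trials.trial_type == "go").to_numpy(),
                 "nogo": (trials.trial_type == "nogo").to_numpy()}
        res1 = compute_geometry(z, trials, conds, RATE, T0)
        perm = rng.permutation(z.shape[0])
        res2 = compute_geometry(z[perm], trials, conds, RATE, T0)
        assert res1.path_length["go"] == pytest.approx(res2.path_length["go"], rel=1e-9)
        assert res1.pairwise_distance[("go", "nogo")] == pytest.approx(
            res2.pairwise_distance[("go", "nogo")], rel=1e-9
        )


class TestBootstrap:
    def test_deterministic_under_seed(self, rng):
        trials, z = make_session(rng, n_neurons=50, drift=0.5)
        conds = {"go": (trials.trial_type == "go").to_numpy(),
                 "nogo": (trials.trial_type == "nogo").to_numpy()}
        kw = dict(metric="distance", n_iter=20, subset_size=10)
        a = bootstrap_trajectory_metric(z, trials, conds, RATE, T0, seed=3, **kw)
        b = bootstrap_trajectory_metric(z, trials, conds, RATE, T0, seed=3, **kw)
        assert np.array_equal(a, b)

    def test_population_smaller_than_subset_errors(self, rng):
        trials, z = make_session(rng, n_neurons=5)
        conds = {"go": (trials.trial_type == "go").to_numpy(),
                 "nogo": (trials.trial_type == "nogo").to_numpy()}
        with pytest.raises(ValueError):
            bootstrap_trajectory_metric(z, trials, conds, RATE, T0, subset_size=40, n_iter=2)

    def test_distance_shrinks_with_effect(self, rng):
        out = {}
        for drift in (0.05, 1.0):
            trials, z = make_session(np.random.default_rng(0), n_neurons=60, drift=drift)
            conds = {"go": (trials.trial_type == "go").to_numpy(),
                     "nogo": (trials.trial_type == "nogo").to_numpy()}
            boot = bootstrap_trajectory_metric(
                z, trials, conds, RATE, T0, metric="distance", n_iter=30, subset_size=20, seed=1
            )
            out[drift] = boot.mean()
        assert out[0.05] < out[1.0]


class TestPopulationCorrelation:
    def test_self_and_negation(self, rng):
        v = rng.normal(size=40)
        mat = population_correlation({"a": v, "b": -v})
        assert mat.loc["a", "a"] == pytest.approx(1.0)
        assert mat.loc["a", "b"] == pytest.approx(-1.0)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)

    def test_planted_drift_decorrelates(self, rng):
        base = rng.uniform(0.5, 2.0, 80)
        groups = {f"T{k}": base * (1 - 0.3 * k) + rng.normal(0, 0.3 * k + 1e-6, 80) for k in range(3)}
        mat = population_correlation(groups)
        assert mat.loc["T0", "T1"] > mat.loc["T0", "T2"]

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            mat = population_correlation({"a": np.ones(10), "b": np.arange(10.0)})
        assert np.isnan(mat.loc["a", "b"])
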