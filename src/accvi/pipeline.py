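"""End-to-end pipeline: behavior -> calcium -> classification -> geometry ->
decoding -> GLM -> SARSA, with per-stage tabular outputs and a JSON summary.

All randomness flows from ``RunConfig.seed`` through named substreams
(``synthetic``, ``geometry``, ``decoding``, ``sarsa``, ...), so the same
configuration reproduces byte-identical summaries.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .behavior import classify_outcomes, lick_probability, performance_summary, split_phases
from .calcium import process_session, test_responsiveness, window_mean
from .config import DEFAULT_EARLY_FRACTIONS, RunConfig
from .decoding import decode
from .functional import classify_functional, venn_summary
from .geometry import bootstrap_trajectory_metric, compute_geometry
from .glm import build_task_design, fit_outcome_history, fit_task_variables
from .io import Dataset, write_tensors
from .sarsa import learning_rate_summary, simulate_session
from .synthetic import generate_dataset

STAGES = ("behavior", "calcium", "classify", "geometry", "decode", "glm", "sarsa")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig, dataset: Dataset | None = None, stages=STAGES) -> dict:
    """Execute the pipeline, writing outputs under ``config.output_dir``.

    With no dataset, a synthetic one is generated from the configuration.
    Returns the summary dict (also written as ``summary.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if dataset is None:
        dataset = generate_dataset(config, seed=substream(config.seed, "synthetic"))
    summary: dict = {"seed": config.seed, "sessions": dataset.sessions}

    processed = {}
    try:
        stage = "behavior"
        perf_rows, phase_rows = [], []
        for name in dataset.sessions:
            t = classify_outcomes(dataset.trials[name])
            dataset.trials[name] = t
            s = performance_summary(t, scope=name)
            perf_rows.append(vars(s))
            for lab, grp in t.groupby("phase", sort=False):
                try:
                    p = performance_summary(grp, scope=f"{name}/{lab}")
                    perf_rows.append(vars(p))
                except Exception:
                    pass  # a phase can lack go or no-go trials at small n
            phase_rows.append(lick_probability(t, by=("session", "stimulus")))
        perf = pd.DataFrame(perf_rows)
        perf.to_csv(out / "performance.csv", index=False)
        pd.concat(phase_rows).to_csv(out / "lick_probability.csv", index=False)
        summary["behavior"] = {
            r["scope"]: {"dprime": r["dprime"], "hit_rate": r["hit_rate"], "fa_rate": r["fa_rate"]}
            for r in perf_rows
        }
        if "behavior" == stages[-1]:
            raise StopIteration

        stage = "calcium"
        resp_rows = []
        for name in dataset.sessions:
            tensor = dataset.fluorescence[name]
            dff, z, valid = process_session(
                tensor.F, tensor.frame_rate, tensor.t0_frame, config.baseline_dff, config.baseline_z
            )
            processed[name] = {"dff": dff, "z": z, "valid": valid, "tensor": tensor}
            write_tensors(out / f"processed_{name}.h5", dff=np.nan_to_num(dff), zscored=np.nan_to_num(z))
            resp = test_responsiveness(
                dff, tensor.frame_rate, tensor.t0_frame, config.stimulus_window, config.baseline_dff
            )
            resp["session"] = name
            resp_rows.append(resp)
        resp_all = pd.concat(resp_rows)
        resp_all.to_csv(out / "responsiveness.csv")
        summary["calcium"] = {
            name: {"n_responsive": int((r["direction"] != "none").sum())}
            for name, r in zip(dataset.sessions, resp_rows)
        }

        stage = "classify"
        labels = {}
        for name in dataset.sessions:
            if name in ("Uncertain", "Reversal"):
                p = processed[name]
                lab = classify_functional(
                    dataset.trials[name], p["dff"], p["tensor"].frame_rate, p["tensor"].t0_frame, name
                )
                labels[name] = lab
        if labels:
            pd.concat(labels.values()).to_csv(out / "functional_labels.csv")
            summary["classify"] = {
                name: venn_summary(
                    int(lab["outcome_monitoring"].sum()),
                    int(lab["value_updating"].sum()),
                    int(lab["dual"].sum()),
                    len(lab),
                )
                for name, lab in labels.items()
            }

        stage = "geometry"
        geo_rows = []
        rng_geo = substream(config.seed, "geometry")
        for name in dataset.sessions:
            p = processed[name]
            t = dataset.trials[name]
            conditions = {
                "go": t["trial_type"].isin(["go", "RO"]).to_numpy(),
                "nogo": (t["trial_type"] == "nogo").to_numpy(),
            }
            res = compute_geometry(p["z"], t, conditions, p["tensor"].frame_rate, p["tensor"].t0_frame)
            boot = bootstrap_trajectory_metric(
                p["z"], t, conditions, p["tensor"].frame_rate, p["tensor"].t0_frame,
                metric="distance", n_iter=200, subset_size=min(40, p["z"].shape[0]), seed=rng_geo,
            )
            geo_rows.append(
                {
                    "session": name,
                    "length_go": res.path_length["go"],
                    "length_nogo": res.path_length["nogo"],
                    "distance_go_nogo": res.pairwise_distance[("go", "nogo")],
                    "boot_distance_mean": float(boot.mean()),
                    "boot_distance_sd": float(boot.std(ddof=1)),
                    "ev_top3": float(res.explained_variance[:3].sum()),
                }
            )
        geo = pd.DataFrame(geo_rows)
        geo.to_csv(out / "geometry_metrics.csv", index=False)
        summary["geometry"] = geo.set_index("session").to_dict("index")

        stage = "decode"
        rng_dec = substream(config.seed, "decoding")
        dec_rows = []
        for name in dataset.sessions:
            p = processed[name]
            t = dataset.trials[name]
            feats = window_mean(p["z"], p["tensor"].frame_rate, p["tensor"].t0_frame, config.stimulus_window)
            tone = t["stimulus"].isin(["3kHz", "12kHz"]).to_numpy()
            res = decode(
                feats[:, tone], t.loc[tone, "stimulus"].to_numpy(),
                folds=3, n_repeats=20, n_pseudo=30, seed=rng_dec, train_scope=name,
            )
            dec_rows.append(
                {"train_scope": name, "test_scope": name, "mean_accuracy": res.mean_accuracy,
                 "ci_low": res.ci()[0], "ci_high": res.ci()[1], "n_repeats": res.n_repeats}
            )
        dec = pd.DataFrame(dec_rows)
        dec.to_csv(out / "decoding.csv", index=False)
        summary["decode"] = dec.set_index("train_scope")["mean_accuracy"].to_dict()

        stage = "glm"
        glm_rows = []
        for name in dataset.sessions:
            p = processed[name]
            t = dataset.trials[name]
            feats = window_mean(p["z"], p["tensor"].frame_rate, p["tensor"].t0_frame, config.stimulus_window)
            o = (~t["outcome_class"].isin(["Hit", "UR"])).astype(float).to_numpy()
            resp = np.where((t["outcome_class"] == "Hit").to_numpy()[None, :], feats, np.nan)
            for i in range(feats.shape[0]):
                try:
                    fit = fit_outcome_history(resp[i], o)
                except ValueError:
                    continue
                glm_rows.append(
                    {"neuron_id": i, "session": name, "intercept": fit.intercept,
                     **{f"w{k + 1}": fit.weights[k] for k in range(5)}}
                )
        glm = pd.DataFrame(glm_rows)
        glm.to_csv(out / "glm_history.csv", index=False)
        if len(glm):
            summary["glm"] = {
                name: {f"w{k}": float(g[f"w{k}"].median()) for k in range(1, 6)}
                for name, g in glm.groupby("session")
            }
        # task-variable GLM on the Uncertain session
        if "Uncertain" in dataset.sessions:
            t = dataset.trials["Uncertain"]
            p = processed["Uncertain"]
            feats = window_mean(p["z"], p["tensor"].frame_rate, p["tensor"].t0_frame, config.stimulus_window)
            design = build_task_design(t, config.stimulus_window)
            go = design.pop("is_go").to_numpy()
            contrib = []
            for i in range(min(feats.shape[0], 50)):
                fit = fit_task_variables(feats[i, go], design[go], seed=config.seed)
                contrib.append({"neuron_id": i, "r2_full": fit.r2_full, **fit.contributions})
            pd.DataFrame(contrib).to_csv(out / "glm_contributions.csv", index=False)

        stage = "sarsa"
        rng_rl = substream(config.seed, "sarsa")
        rl_rows = []
        for name in ("Stable", "Uncertain", "Reversal"):
            tr = simulate_session(name, n_trials=config.n_trials, n_repeats=500, seed=rng_rl)
            s = learning_rate_summary(tr, config.phase_fractions[name])
            s.insert(0, "session", name)
            rl_rows.append(s)
        rl = pd.concat(rl_rows, ignore_index=True)
        rl.to_csv(out / "learning_rate_summary.csv", index=False)
        summary["sarsa"] = {
            f"{r.session}/{r.phase}": r.mean_alpha for r in rl.itertuples(index=False)
        }
    except StopIteration:
        pass
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - reported with stage context
        raise StageError(stage, exc) from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(_round_floats(summary), fh, indent=2, sort_keys=True)
    return summary
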