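"""Linear decoding of stimulus, outcome, and session period from population activity.

Features are per-trial window means of z-scored dF/F.  Because neurons are
pooled across animals (not recorded simultaneously), pseudo-trials are
assembled by sampling, for each neuron, one of its same-label trials with
replacement.  The classifier is a linear maximum-margin SVM (C = 1) with
features standardized on the training split only; accuracy is the zero-one
score.  Within-scope decoding uses k-fold cross-validation (default 3-fold,
500 repeats); cross-scope decoding trains on the full source scope and
evaluates every test-scope pseudo-trial.  Subpopulation comparisons draw
matched 200-neuron cohorts (5-fold, 1000 repeats).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from ._rng import as_generator


@dataclass
class DecodingResult:
    train_scope: str
    test_scope: str
    accuracy_samples: np.ndarray
    n_repeats: int
    n_neurons_used: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy_samples))

    def ci(self, level: float = 0.95):
        lo = (1 - level) / 2 * 100
        return tuple(np.percentile(self.accuracy_samples, [lo, 100 - lo]))


def _svm():
    # fixed random_state: the dual solver shuffles internally and must not
    # introduce randomness outside the named substreams
    return make_pipeline(StandardScaler(), LinearSVC(C=1.0, dual=True, max_iter=5000, random_state=0))


def build_pseudo_trials(features: np.ndarray, labels: np.ndarray, n_pseudo: int, seed=None):
    """Assemble balanced pseudo-trials from non-simultaneous neurons.

    ``features`` is (neurons, trials) of window means, ``labels`` the per-trial
    class labels.  For each of the ``n_pseudo`` pseudo-trials per class, each
    neuron contributes one of its same-class trials sampled with replacement.
    Returns (X, y) with X of shape (n_pseudo * n_classes, neurons).
    """
    rng = as_generator(seed)
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    n_neurons = features.shape[0]
    X, y = [], []
    for c in classes:
        cols = np.nonzero(labels == c)[0]
        vals = features[:, cols]
        ok = np.isfinite(vals)
        if not ok.all():
            dropped = (~ok.all(axis=1)).sum()
            warnings.warn(f"{dropped} neurons have invalid trials for class {c!r}", stacklevel=2)
        pick = rng.integers(0, len(cols), size=(n_pseudo, n_neurons))
        X.append(vals[np.arange(n_neurons)[None, :], pick])
        y.extend([c] * n_pseudo)
    return np.vstack(X), np.asarray(y)


def _class_folds(labels: np.ndarray, folds: int, rng) -> list[np.ndarray]:
    """Random per-class partition of trial indices into ``folds`` groups.

    Splitting *real* trials (not pseudo-trials) keeps held-out evaluation
    honest: pseudo-trials resample trial noise, so train and test sets must
    draw from disjoint trials.
    """
    parts = [[] for _ in range(folds)]
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        if len(idx) < folds:
            raise ValueError(f"class {c!r} has {len(idx)} trials, fewer than {folds} folds")
        idx = rng.permutation(idx)
        for f, chunk in enumerate(np.array_split(idx, folds)):
            parts[f].extend(chunk)
    return [np.asarray(sorted(p)) for p in parts]


def decode(
    features: np.ndarray,
    labels: np.ndarray,
    scheme: str = "within",
    test_features: np.ndarray | None = None,
    test_labels: np.ndarray | None = None,
    folds: int = 3,
    n_repeats: int = 500,
    n_pseudo: int = 30,
    seed=None,
    train_scope: str = "train",
    test_scope: str | None = None,
) -> DecodingResult:
    """Decode class labels from per-trial population features.

    ``within``: per repeat, split real trials into ``folds`` class-balanced
    groups, build training pseudo-trials from the training trials and test
    pseudo-trials from the held-out trials, and average the zero-one accuracy
    over folds.  ``cross``: per repeat, train on pseudo-trials of the full
    source scope and evaluate on pseudo-trials of (``test_features``,
    ``test_labels``).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training scope has a single class")
    if scheme not in ("within", "cross"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "cross" and (test_features is None or test_labels is None):
        raise ValueError("cross-scheme decoding needs test features and labels")
    rng = as_generator(seed)
    acc = np.empty(n_repeats)
    for k in range(n_repeats):
        if scheme == "within":
            parts = _class_folds(labels, folds, rng)
            scores = []
            for f in range(folds):
                te = parts[f]
                tr = np.concatenate([parts[g] for g in range(folds) if g != f])
                X, y = build_pseudo_trials(features[:, tr], labels[tr], n_pseudo, seed=rng)
                Xt, yt = build_pseudo_trials(features[:, te], labels[te], n_pseudo, seed=rng)
                clf = _svm().fit(X, y)
                scores.append(np.mean(clf.predict(Xt) == yt))
            acc[k] = np.mean(scores)
        else:
            X, y = build_pseudo_trials(features, labels, n_pseudo, seed=rng)
            Xt, yt = build_pseudo_trials(test_features, test_labels, n_pseudo, seed=rng)
            clf = _svm().fit(X, y)
            acc[k] = np.mean(clf.predict(Xt) == yt)
    return DecodingResult(
        train_scope=train_scope,
        test_scope=test_scope or train_scope,
        accuracy_samples=acc,
        n_repeats=n_repeats,
        n_neurons_used=np.asarray(features).shape[0],
    )


def compare_subpopulations(
    features: np.ndarray,
    labels: np.ndarray,
    exclude: np.ndarray,
    n_neurons: int = 200,
    folds: int = 5,
    n_repeats: int = 1000,
    n_pseudo: int = 30,
    seed=None,
):
    """Decoding with matched-size cohorts drawn from all vs all-minus-excluded.

    ``exclude`` is a boolean mask of neurons (e.g. planted dual-function
    neurons).  Returns a pair of DecodingResult: (all, without-excluded).
    """
    rng = as_generator(seed)
    features = np.asarray(features, dtype=float)
    total = features.shape[0]
    keep_idx = np.nonzero(~np.asarray(exclude, dtype=bool))[0]
    if total < n_neurons or len(keep_idx) < n_neurons:
        raise ValueError(
            f"cohorts ({total}, {len(keep_idx)}) smaller than n_neurons ({n_neurons})"
        )
    labels = np.asarray(labels)
    accs = {"all": np.empty(n_repeats), "without": np.empty(n_repeats)}
    for k in range(n_repeats):
        for name, pool in (("all", np.arange(total)), ("without", keep_idx)):
            idx = rng.choice(pool, size=n_neurons, replace=False)
            parts = _class_folds(labels, folds, rng)
            scores = []
            for f in range(folds):
                te = parts[f]
                tr = np.concatenate([parts[g] for g in range(folds) if g != f])
                X, y = build_pseudo_trials(features[idx][:, tr], labels[tr], n_pseudo, seed=rng)
                Xt, yt = build_pseudo_trials(features[idx][:, te], labels[te], n_pseudo, seed=rng)
                clf = _svm().fit(X, y)
                scores.append(np.mean(clf.predict(Xt) == yt))
            accs[name][k] = np.mean(scores)
    mk = lambda name, a: DecodingResult(name, name, a, n_repeats, n_neurons)
    return mk("all", accs["all"]), mk("without_excluded", accs["without"])
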