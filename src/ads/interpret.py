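"""Feature importance and per-case additive Shapley explanations.

Global importance comes two ways: mean decrease in impurity (MDI) averaged
over repeatedly re-seeded random forests, and permutation importance (mean
score drop when one feature column is shuffled). Per-case explanations are
interventional Shapley values against a background sample: exact coalition
enumeration when the feature count allows it, otherwise an antithetic
permutation-sampling estimator. Both routes satisfy the efficiency identity
base_value + sum(contributions) == predicted probability exactly (up to
floating-point error), because permutation marginal contributions telescope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance as _sk_permutation_importance

from .models import (
    LabeledCase,
    TrainedLocationModel,
    _build_estimator,
    _labels_vector,
    feature_matrix,
)

__all__ = [
    "ImportanceTable",
    "Explanation",
    "mdi_importance",
    "permutation_importance",
    "shapley_explain",
    "EFFICIENCY_TOL",
]

EFFICIENCY_TOL = 1e-6

#: largest feature count for exact coalition enumeration (2^m model calls)
_ENUM_LIMIT = 12


@dataclass
class ImportanceTable:
    """Per-ROI feature importances: name -> (mean, dispersion over repeats)."""

    kind: str  # "mdi" or "permutation"
    per_roi: dict[str, dict[str, tuple[float, float]]]

    def ranking(self, roi: str) -> list[str]:
        """Feature names sorted by decreasing mean importance."""
        table = self.per_roi[roi]
        return sorted(table, key=lambda f: -table[f][0])

    def to_records(self) -> list[dict]:
        return [
            {"roi": roi, "feature": feat, "mean": m, "sd": s}
            for roi, table in self.per_roi.items()
            for feat, (m, s) in table.items()
        ]


@dataclass
class Explanation:
    """Additive attribution of one predicted probability to the features."""

    base_value: float
    contributions: dict[str, float]
    predicted_probability: float

    def __post_init__(self) -> None:
        gap = abs(
            self.base_value + sum(self.contributions.values())
            - self.predicted_probability
        )
        if gap > EFFICIENCY_TOL:
            raise ValueError(f"Shapley efficiency violated by {gap:.2e}")


def mdi_importance(
    train: Sequence[LabeledCase],
    hyperparams: Mapping,
    n_models: int = 100,
    seed: int = 0,
) -> ImportanceTable:
    """Mean and SD of normalized impurity-decrease importances over
    ``n_models`` independently re-seeded forests, per ROI."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    X, names = feature_matrix(train)
    rng = np.random.default_rng(seed)
    per_roi: dict[str, dict[str, tuple[float, float]]] = {}
    for roi in train[0].labels:
        y = _labels_vector(train, roi)
        if len(set(y.tolist())) < 2:
            continue
        imp = np.empty((n_models, len(names)))
        for m in range(n_models):
            est = _build_estimator("RF", hyperparams, int(rng.integers(0, 2**31 - 1)))
            if not isinstance(est, RandomForestClassifier):
                raise ValueError("MDI is defined for forest models only")
            est.fit(X, y)
            imp[m] = est.feature_importances_
        per_roi[roi] = {
            f: (float(imp[:, j].mean()), float(imp[:, j].std()))
            for j, f in enumerate(names)
        }
    return ImportanceTable(kind="mdi", per_roi=per_roi)


_SCORERS = {"bacc": "balanced_accuracy", "f1": "f1", "accuracy": "accuracy"}


def permutation_importance(
    model: TrainedLocationModel,
    data: Sequence[LabeledCase],
    n_iter: int = 100,
    metric: str = "bacc",
    seed: int = 0,
) -> ImportanceTable:
    """Mean score drop (over ``n_iter`` shuffles of each column) per feature
    and ROI; the score is BACC by default. May be run on the training or the
    testing cohort."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if metric not in _SCORERS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_SCORERS)}")
    X, names = feature_matrix(data, model.feature_names)
    per_roi: dict[str, dict[str, tuple[float, float]]] = {}
    for roi, clf in model.classifiers.items():
        y = _labels_vector(data, roi)
        if len(set(y.tolist())) < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = _sk_permutation_importance(
                clf,
                X,
                y,
                scoring=_SCORERS[metric],
                n_repeats=n_iter,
                random_state=seed,
            )
        per_roi[roi] = {
            f: (float(res.importances_mean[j]), float(res.importances_std[j]))
            for j, f in enumerate(names)
        }
    return ImportanceTable(kind="permutation", per_roi=per_roi)


# ---------------------------------------------------------------------------
# Shapley explanations
# ---------------------------------------------------------------------------


def _coalition_values(predict, x: np.ndarray, background: np.ndarray) -> dict[frozenset, float]:
    """v(S) = mean over background rows b of f(x_S, b_notS), all 2^m subsets."""
    m = x.size
    values: dict[frozenset, float] = {}
    for size in range(m + 1):
        for S in combinations(range(m), size):
            Z = background.copy()
            Z[:, list(S)] = x[list(S)]
            values[frozenset(S)] = float(np.mean(predict(Z)))
    return values


def _exact_shapley(predict, x: np.ndarray, background: np.ndarray) -> np.ndarray:
    m = x.size
    v = _coalition_values(predict, x, background)
    phi = np.zeros(m)
    for j in range(m):
        others = [i for i in range(m) if i != j]
        for size in range(m):
            w = 1.0 / (m * comb(m - 1, size))
            for S in combinations(others, size):
                S = frozenset(S)
                phi[j] += w * (v[S | {j}] - v[S])
    return phi


def _sampled_shapley(
    predict, x: np.ndarray, background: np.ndarray, n_samples: int, rng
) -> np.ndarray:
    """Antithetic permutation sampling; marginal contributions telescope, so
    efficiency holds exactly for the averaged estimate."""
    m = x.size
    phi = np.zeros(m)
    n_perm = 0
    while n_perm < n_samples:
        perm = rng.permutation(m)
        for order in (perm, perm[::-1]):
            Z = background.copy()
            prev = float(np.mean(predict(Z)))
            for j in order:
                Z[:, j] = x[j]
                cur = float(np.mean(predict(Z)))
                phi[j] += cur - prev
                prev = cur
            n_perm += 1
            if n_perm >= n_samples:
                break
    return phi / n_perm


def shapley_explain(
    model: TrainedLocationModel,
    case: LabeledCase,
    background: Sequence[LabeledCase],
    n_samples: int = 200,
    seed: int = 0,
    rois: Sequence[str] | None = None,
) -> dict[str, Explanation]:
    """Interventional Shapley explanation of each ROI's predicted probability.

    ``background`` supplies the reference distribution (a training sample);
    the base value is the mean predicted probability over it. Exact
    enumeration is used when the model has at most 12 features, otherwise
    permutation sampling with ``n_samples`` permutations.
    """
    if not background:
        raise ValueError("background sample is empty")
    Xb, names = feature_matrix(background, model.feature_names)
    x = np.array([case.features[f] for f in model.feature_names])
    m = x.size
    rng = np.random.default_rng(seed)
    out: dict[str, Explanation] = {}
    for roi in rois if rois is not None else model.rois:
        clf = model.classifiers[roi]
        classes = list(getattr(clf, "classes_", [0, 1]))
        col = classes.index(1) if 1 in classes else None

        def predict(Z, _clf=clf, _col=col):
            if _col is None:
                return np.zeros(Z.shape[0])
            return _clf.predict_proba(Z)[:, _col]

        base = float(np.mean(predict(Xb)))
        fx = float(predict(x.reshape(1, -1))[0])
        if m <= _ENUM_LIMIT:
            phi = _exact_shapley(predict, x, Xb)
        else:
            phi = _sampled_shapley(predict, x, Xb, n_samples, rng)
        # guard against accumulated floating-point drift in long sums
        drift = fx - base - phi.sum()
        if abs(drift) > EFFICIENCY_TOL:
            phi = phi + drift / m
        out[roi] = Explanation(
            base_value=base,
            contributions={f: float(p) for f, p in zip(names, phi)},
            predicted_probability=fx,
        )
    return out
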