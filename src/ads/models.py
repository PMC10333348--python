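"""Per-ROI binary classifiers for infarct location and hydrocephalus.

Seven model families are supported: the binary-threshold model (BT), which
classifies a region as injured when its own QFV component reaches a
threshold, and six standard learners (LDA, QDA, RF, KNN, SVM, MLP). Each
region gets an independent binary classifier over the full concatenated
feature vector (both atlas schemes + log volume + ventricular ratios).

Hyperparameters are chosen by the two-stage protocol: a single 5-fold CV
over the whole grid scored by BACC + F1, then 10-repeat 5-fold CV over the
top three, the winner taken from the repeats. Folds are stratified on the
ROI label so severely imbalanced regions still split sanely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    balanced_accuracy_score,
    cohen_kappa_score,
    f1_score,
    precision_score,
    recall_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .hydro import HydroFeatures
from .qfv import QFVector

__all__ = [
    "MODEL_FAMILIES",
    "FEATURE_VOLUME",
    "FEATURE_GAMMA_OLVR",
    "FEATURE_GAMMA_ILVR",
    "HYDRO_FEATURES",
    "DEFAULT_THRESHOLD_GRID",
    "DEFAULT_GRIDS",
    "LabeledCase",
    "make_case",
    "feature_matrix",
    "BTModel",
    "ConstantPredictor",
    "ThresholdClassifier",
    "TrainedLocationModel",
    "RegionPredictionSet",
    "MetricsRow",
    "fit_binary_threshold",
    "select_hyperparameters",
    "fit_model",
    "predict_regions",
    "classification_metrics",
    "icc3",
    "save_model",
    "load_model",
    "cases_to_frame",
    "cases_from_frame",
]

MODEL_FAMILIES = ("BT", "LDA", "QDA", "RF", "KNN", "SVM", "MLP")

FEATURE_VOLUME = "log_volume_ml"
FEATURE_GAMMA_OLVR = "gamma_olvr"
FEATURE_GAMMA_ILVR = "gamma_ilvr"
#: feature set of the hydrocephalus classifier
HYDRO_FEATURES = (FEATURE_GAMMA_OLVR, FEATURE_GAMMA_ILVR, FEATURE_VOLUME)

DEFAULT_THRESHOLD_GRID: tuple[float, ...] = tuple(
    np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
)

#: default hyperparameter grids per family (the harness accepts any grid)
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "BT": [{}],
    "LDA": [{}],
    "QDA": [{"reg_param": 0.0}, {"reg_param": 0.1}],
    "RF": [
        {"n_estimators": 200, "max_depth": None},
        {"n_estimators": 200, "max_depth": 8},
        {"n_estimators": 400, "max_depth": None},
    ],
    "KNN": [{"n_neighbors": k} for k in (3, 5, 11, 21)],
    "SVM": [{"kernel": "rbf", "C": c} for c in (0.5, 1.0, 10.0)],
    "MLP": [
        {"hidden_layer_sizes": (32,), "max_iter": 1000},
        {"hidden_layer_sizes": (64, 32), "max_iter": 1000},
    ],
}


# ---------------------------------------------------------------------------
# Cases and feature vectors
# ---------------------------------------------------------------------------


@dataclass
class LabeledCase:
    """One training case: ordered feature map plus expert binary labels.

    Feature keys are scheme-qualified ROI names (``"arterial:MCA"``) plus the
    log-volume and ventricular-ratio features; label keys use the same
    qualified names.
    """

    features: dict[str, float]
    labels: dict[str, int]
    hydrocephalus: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for roi, y in self.labels.items():
            if y not in (0, 1):
                raise ValueError(f"label for {roi!r} must be 0/1, got {y}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.features)


def make_case(
    qfvs: Sequence[QFVector],
    labels: Mapping[str, int] | None = None,
    hydro: HydroFeatures | None = None,
    hydrocephalus: int | None = None,
) -> LabeledCase:
    """Assemble a LabeledCase from one or more scheme QFVs (+ hydro features)."""
    features: dict[str, float] = {}
    for q in qfvs:
        for roi, frac in q.fractions.items():
            features[f"{q.scheme}:{roi}"] = frac
    features[FEATURE_VOLUME] = qfvs[0].lesion_volume_log_ml
    if hydro is not None:
        features[FEATURE_GAMMA_OLVR] = hydro.gamma_olvr
        features[FEATURE_GAMMA_ILVR] = hydro.gamma_ilvr
    return LabeledCase(
        features=features, labels=dict(labels or {}), hydrocephalus=hydrocephalus
    )


def feature_matrix(
    cases: Sequence[LabeledCase], feature_names: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Stack cases into an (n_cases, n_features) array with a fixed order."""
    if not cases:
        raise ValueError("no cases")
    names = list(feature_names) if feature_names is not None else cases[0].feature_names
    X = np.empty((len(cases), len(names)), dtype=float)
    for i, c in enumerate(cases):
        for j, name in enumerate(names):
            try:
                X[i, j] = c.features[name]
            except KeyError:
                raise ValueError(f"case {i} lacks feature {name!r}") from None
    return X, names


def _labels_vector(cases: Sequence[LabeledCase], roi: str) -> np.ndarray:
    return np.array([c.labels[roi] for c in cases], dtype=int)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


class ThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Decision stump on one feature column: ``x >= threshold -> 1``.

    Thin sklearn-style wrapper so BT regions interoperate with the shared
    prediction/importance machinery. Probabilities are the hard labels.
    """

    def __init__(self, column: int = 0, threshold: float = 0.5):
        self.column = column
        self.threshold = threshold

    def fit(self, X, y=None):
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return (X[:, self.column] >= self.threshold).astype(int)

    def predict_proba(self, X):
        p1 = self.predict(X).astype(float)
        return np.column_stack([1.0 - p1, p1])

    def score(self, X, y):
        return balanced_accuracy_score(y, self.predict(X))


class ConstantPredictor(BaseEstimator, ClassifierMixin):
    """Degenerate-class fallback: predicts the training prevalence."""

    def __init__(self, probability: float = 0.0):
        self.probability = probability

    def fit(self, X, y=None):
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X):
        n = np.asarray(X).shape[0]
        return np.full(n, int(self.probability >= 0.5))

    def predict_proba(self, X):
        n = np.asarray(X).shape[0]
        return np.column_stack(
            [np.full(n, 1.0 - self.probability), np.full(n, self.probability)]
        )

    def score(self, X, y):
        return balanced_accuracy_score(y, self.predict(X))


@dataclass
class BTModel:
    """Per-ROI thresholds of the binary-threshold family."""

    thresholds: dict[str, float]

    def __post_init__(self) -> None:
        for roi, t in self.thresholds.items():
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"threshold for {roi!r} outside [0, 1]")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricsRow:
    bacc: float
    f1: float
    precision: float
    sensitivity: float
    kappa: float


def classification_metrics(truth: Iterable[int], pred: Iterable[int]) -> MetricsRow:
    """BACC, F1, precision, sensitivity and Cohen's kappa for binary labels.

    Undefined ratios (e.g. precision with no positive predictions, kappa with
    no chance disagreement) are reported as 0 with a warning.
    """
    y_true = np.asarray(list(truth), dtype=int)
    y_pred = np.asarray(list(pred), dtype=int)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("truth and pred must be equal-length, non-empty")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bacc = balanced_accuracy_score(y_true, y_pred)
        f1 = f1_score(y_true, y_pred, zero_division=0)
        precision = precision_score(y_true, y_pred, zero_division=0)
        sensitivity = recall_score(y_true, y_pred, zero_division=0)
        kappa = cohen_kappa_score(y_true, y_pred)
    if np.isnan(kappa):
        warnings.warn("kappa undefined (no chance disagreement); reporting 0")
        kappa = 0.0
    if (y_pred == 1).sum() == 0 or (y_true == 1).sum() == 0:
        warnings.warn("a class is absent; undefined ratios reported as 0")
    return MetricsRow(
        bacc=float(bacc),
        f1=float(f1),
        precision=float(precision),
        sensitivity=float(sensitivity),
        kappa=float(kappa),
    )


def _bacc_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(
            balanced_accuracy_score(y_true, y_pred)
            + f1_score(y_true, y_pred, zero_division=0)
        )


def icc3(ratings: np.ndarray) -> float:
    """Two-way mixed, single-rater, consistency intraclass correlation.

    ``ratings`` is n_subjects x k_raters with no missing cells. From the
    two-way ANOVA decomposition:

        ICC3 = (MS_rows - MS_error) / (MS_rows + (k - 1) * MS_error)

    where MS_rows is the between-subject and MS_error the residual mean
    square after removing the rater (column) effect.
    """
    R = np.asarray(ratings, dtype=float)
    if R.ndim != 2:
        raise ValueError("ratings must be a 2D matrix")
    n, k = R.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if not np.all(np.isfinite(R)):
        raise ValueError("ratings contain missing cells")
    grand = R.mean()
    row_means = R.mean(axis=1)
    col_means = R.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((R - grand) ** 2).sum()
    ss_error = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_error = ss_error / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_error
    if denom <= 1e-15:
        raise ValueError("ICC3 undefined: no between-subject or residual variance")
    return float((ms_rows - ms_error) / denom)


# ---------------------------------------------------------------------------
# Binary-threshold fitting
# ---------------------------------------------------------------------------


def _stratified_folds(
    y: np.ndarray, folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-label stratified CV splits; degrades to a resubstitution 'split'
    when a class is too small to populate 2 folds."""
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    n_splits = min(folds, n_pos, n_neg)
    if n_splits < 2:
        idx = np.arange(y.size)
        return [(idx, idx)]
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(y.size), y))


def fit_binary_threshold(
    cases: Sequence[LabeledCase],
    roi: str,
    grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Choose the BT threshold for one ROI.

    Returns the smallest grid value maximizing the mean cross-validated
    BACC + F1 of the rule ``fraction >= threshold -> injured``.
    """
    grid = list(grid)
    if grid != sorted(grid):
        raise ValueError("threshold grid must be sorted ascending")
    y = _labels_vector(cases, roi)
    if len(set(y.tolist())) < 2:
        raise ValueError(f"ROI {roi!r} has a single label class; BT undefined")
    X, _ = feature_matrix(cases, [roi])
    x = X[:, 0]
    splits = _stratified_folds(y, folds, seed)
    mean_scores = np.empty(len(grid))
    for gi, t in enumerate(grid):
        fold_scores = [
            _bacc_f1(y[val], (x[val] >= t).astype(int)) for _, val in splits
        ]
        mean_scores[gi] = np.mean(fold_scores)
    best = mean_scores.max()
    # smallest threshold achieving the maximum
    return float(grid[int(np.argmax(mean_scores >= best - 1e-12))])


# ---------------------------------------------------------------------------
# Family construction + hyperparameter selection
# ---------------------------------------------------------------------------


def _build_estimator(family: str, hyperparams: Mapping, seed: int) -> BaseEstimator:
    hp = dict(hyperparams)
    if family == "LDA":
        return LinearDiscriminantAnalysis(**hp)
    if family == "QDA":
        return QuadraticDiscriminantAnalysis(**hp)
    if family == "RF":
        return RandomForestClassifier(random_state=seed, **hp)
    if family == "KNN":
        return KNeighborsClassifier(**hp)
    if family == "SVM":
        hp.setdefault("probability", True)
        return SVC(random_state=seed, **hp)
    if family == "MLP":
        return MLPClassifier(random_state=seed, **hp)
    raise ValueError(f"unknown model family {family!r}")


def _cv_score_roi(
    family: str,
    hyperparams: Mapping,
    X: np.ndarray,
    y: np.ndarray,
    folds: int,
    seed: int,
    roi_column: int | None = None,
) -> float:
    """Mean BACC+F1 over stratified folds for one ROI's classifier."""
    splits = _stratified_folds(y, folds, seed)
    scores = []
    for tr, val in splits:
        if len(set(y[tr].tolist())) < 2:
            pred = np.full(val.size, int(y[tr].mean() >= 0.5))
        elif family == "BT":
            x = X[:, roi_column]
            sub = [_FakeCase(x[i], y[i]) for i in tr]
            t = fit_binary_threshold(sub, "_roi", folds=folds, seed=seed)
            pred = (x[val] >= t).astype(int)
        else:
            est = _build_estimator(family, hyperparams, seed)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(X[tr], y[tr])
                    pred = est.predict(X[val])
            except Exception:
                # infeasible grid point for this fold size (e.g. KNN k larger
                # than the training fold): score it out of contention
                return float("-inf")
        scores.append(_bacc_f1(y[val], pred))
    return float(np.mean(scores))


class _FakeCase:
    """Single-feature adapter so BT inner CV reuses fit_binary_threshold."""

    def __init__(self, x: float, y: int):
        self.features = {"_roi": float(x)}
        self.labels = {"_roi": int(y)}
        self.feature_names = ["_roi"]


def select_hyperparameters(
    family: str,
    grid: Sequence[Mapping],
    train: Sequence[LabeledCase],
    seed: int = 0,
    roi: str | None = None,
    folds: int = 5,
    repeats: int = 10,
) -> dict:
    """Two-stage grid selection: 5-fold CV over the grid scored by BACC+F1,
    then ``repeats``-repeat 5-fold CV over the top three; ties go to the
    earliest grid entry."""
    grid = [dict(g) for g in grid]
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if len(grid) == 1:
        return grid[0]
    rois = [roi] if roi is not None else list(train[0].labels)
    X, names = feature_matrix(train)
    ys = {r: _labels_vector(train, r) for r in rois}
    cols = {r: names.index(r) if r in names else None for r in rois}

    def score(hp: Mapping, fold_seed: int) -> float:
        per_roi = []
        for r in rois:
            y = ys[r]
            if len(set(y.tolist())) < 2:
                continue
            per_roi.append(
                _cv_score_roi(family, hp, X, y, folds, fold_seed, cols[r])
            )
        if not per_roi:
            raise ValueError("all ROIs degenerate; grid search impossible")
        return float(np.mean(per_roi))

    stage1 = np.array([score(hp, seed) for hp in grid])
    top3 = list(np.argsort(-stage1, kind="stable")[:3])

    stage2 = []
    for gi in top3:
        rep_scores = [score(grid[gi], seed + 1 + rep) for rep in range(repeats)]
        stage2.append(np.mean(rep_scores))
    winner = top3[int(np.argmax(stage2))]  # argmax keeps first (grid-order) tie
    return grid[winner]


# ---------------------------------------------------------------------------
# Full-model fit / predict
# ---------------------------------------------------------------------------


@dataclass
class TrainedLocationModel:
    family: str
    feature_names: list[str]
    classifiers: dict[str, BaseEstimator]
    hyperparams: dict
    seed: int
    bt: BTModel | None = None
    hydro_classifier: BaseEstimator | None = None
    constant_rois: list[str] = field(default_factory=list)
    decision_cut: float = 0.5

    @property
    def rois(self) -> list[str]:
        return list(self.classifiers)

    def card(self) -> dict:
        """Model card: family, hyperparameters and degenerate-ROI flags."""
        return {
            "family": self.family,
            "hyperparams": self.hyperparams,
            "seed": self.seed,
            "features": self.feature_names,
            "rois": self.rois,
            "constant_rois": list(self.constant_rois),
            "bt_thresholds": dict(self.bt.thresholds) if self.bt else None,
            "has_hydro_classifier": self.hydro_classifier is not None,
        }


@dataclass
class RegionPredictionSet:
    """Per-ROI binary call + probability (+ optional Shapley contributions)."""

    labels: dict[str, int]
    probabilities: dict[str, float]
    hydrocephalus_label: int | None = None
    hydrocephalus_probability: float | None = None
    contributions: dict | None = None
    decision_cut: float = 0.5

    def __post_init__(self) -> None:
        for roi, p in self.probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {roi!r} outside [0, 1]")
            if self.labels[roi] != int(p >= self.decision_cut):
                raise ValueError(f"label/probability mismatch for {roi!r}")

    @property
    def rois(self) -> list[str]:
        return list(self.labels)

    def for_scheme(self, scheme: str) -> dict[str, tuple[int, float]]:
        """(label, probability) for the ROIs of one scheme, unqualified names."""
        out: dict[str, tuple[int, float]] = {}
        for roi in self.rois:
            if roi.startswith(scheme + ":"):
                out[roi.split(":", 1)[1]] = (self.labels[roi], self.probabilities[roi])
        return out

    def to_records(self) -> list[dict]:
        rows = []
        for roi in self.rois:
            scheme, _, name = roi.partition(":")
            row = {
                "scheme": scheme if name else "",
                "roi": name or roi,
                "label": self.labels[roi],
                "probability": self.probabilities[roi],
            }
            expl = (self.contributions or {}).get(roi)
            if expl is not None:
                row["shapley_base"] = expl.base_value
                for feat, phi in expl.contributions.items():
                    row[f"shap:{feat}"] = phi
            rows.append(row)
        if self.hydrocephalus_label is not None:
            rows.append(
                {
                    "scheme": "hydro",
                    "roi": "hydrocephalus",
                    "label": self.hydrocephalus_label,
                    "probability": self.hydrocephalus_probability,
                }
            )
        return rows


def fit_model(
    family: str,
    hyperparams: Mapping,
    train: Sequence[LabeledCase],
    seed: int = 0,
) -> TrainedLocationModel:
    """Fit one binary classifier per ROI (and a hydrocephalus head for
    non-BT families) over the full feature vector."""
    if family not in MODEL_FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    X, names = feature_matrix(train)
    rois = list(train[0].labels)
    rng = np.random.default_rng(seed)
    classifiers: dict[str, BaseEstimator] = {}
    constant_rois: list[str] = []
    bt_thresholds: dict[str, float] = {}

    for roi in rois:
        y = _labels_vector(train, roi)
        if len(set(y.tolist())) < 2 or (family != "BT" and min(
            (y == 1).sum(), (y == 0).sum()
        ) < 2):
            clf = ConstantPredictor(probability=float(y.mean())).fit(X, y)
            constant_rois.append(roi)
        elif family == "BT":
            if roi not in names:
                raise ValueError(f"BT needs the ROI's own QFV component for {roi!r}")
            t = fit_binary_threshold(train, roi, folds=5, seed=seed)
            bt_thresholds[roi] = t
            clf = ThresholdClassifier(column=names.index(roi), threshold=t).fit(X, y)
        else:
            est_seed = int(rng.integers(0, 2**31 - 1))
            clf = _build_estimator(family, hyperparams, est_seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(X, y)
        classifiers[roi] = clf

    hydro_clf = None
    y_hydro = np.array(
        [c.hydrocephalus if c.hydrocephalus is not None else -1 for c in train]
    )
    if (
        family != "BT"  # BT has no hydrocephalus QFV component to threshold
        and np.all(y_hydro >= 0)
        and len(set(y_hydro.tolist())) == 2
        and all(f in names for f in HYDRO_FEATURES)
    ):
        cols = [names.index(f) for f in HYDRO_FEATURES]
        hydro_clf = _build_estimator(
            family, hyperparams, int(rng.integers(0, 2**31 - 1))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hydro_clf.fit(X[:, cols], y_hydro)

    return TrainedLocationModel(
        family=family,
        feature_names=names,
        classifiers=classifiers,
        hyperparams=dict(hyperparams),
        seed=seed,
        bt=BTModel(thresholds=bt_thresholds) if family == "BT" else None,
        hydro_classifier=hydro_clf,
        constant_rois=constant_rois,
    )


def _proba_one(clf: BaseEstimator, x_row: np.ndarray) -> float:
    proba = clf.predict_proba(x_row.reshape(1, -1))
    classes = list(getattr(clf, "classes_", [0, 1]))
    if 1 not in classes:
        return 0.0
    return float(proba[0, classes.index(1)])


def save_model(model: TrainedLocationModel, path) -> None:
    """Serialize to a versioned archive: the JSON-able model card plus the
    fitted per-ROI estimators."""
    import joblib

    joblib.dump(
        {
            "format_version": 1,
            "card": model.card(),
            "classifiers": model.classifiers,
            "hydro_classifier": model.hydro_classifier,
            "decision_cut": model.decision_cut,
        },
        path,
    )


def load_model(path) -> TrainedLocationModel:
    import joblib

    blob = joblib.load(path)
    if blob.get("format_version") != 1:
        raise ValueError("unsupported model archive version")
    card = blob["card"]
    return TrainedLocationModel(
        family=card["family"],
        feature_names=list(card["features"]),
        classifiers=blob["classifiers"],
        hyperparams=dict(card["hyperparams"]),
        seed=card["seed"],
        bt=BTModel(thresholds=card["bt_thresholds"]) if card["bt_thresholds"] else None,
        hydro_classifier=blob["hydro_classifier"],
        constant_rois=list(card["constant_rois"]),
        decision_cut=blob["decision_cut"],
    )


def cases_to_frame(cases: Sequence[LabeledCase]):
    """Tabulate a cohort: feature columns plus ``label:``-prefixed columns."""
    import pandas as pd

    rows = []
    for c in cases:
        row = dict(c.features)
        for roi, y in c.labels.items():
            row[f"label:{roi}"] = y
        if c.hydrocephalus is not None:
            row["label:hydrocephalus"] = c.hydrocephalus
        rows.append(row)
    return pd.DataFrame(rows)


def cases_from_frame(df) -> list[LabeledCase]:
    feat_cols = [c for c in df.columns if not c.startswith("label:")]
    label_cols = [c for c in df.columns if c.startswith("label:")]
    cases = []
    for _, row in df.iterrows():
        labels = {
            c[len("label:"):]: int(row[c])
            for c in label_cols
            if c != "label:hydrocephalus"
        }
        hydro = int(row["label:hydrocephalus"]) if "label:hydrocephalus" in df else None
        cases.append(
            LabeledCase(
                features={c: float(row[c]) for c in feat_cols},
                labels=labels,
                hydrocephalus=hydro,
            )
        )
    return cases


def predict_regions(
    model: TrainedLocationModel,
    qfv: QFVector | Sequence[QFVector] | LabeledCase,
    hydro: HydroFeatures | None = None,
) -> RegionPredictionSet:
    """Per-ROI probabilities and thresholded labels for a new case."""
    if isinstance(qfv, LabeledCase):
        case = qfv
    else:
        qfvs = [qfv] if isinstance(qfv, QFVector) else list(qfv)
        case = make_case(qfvs, hydro=hydro)
    missing = [f for f in model.feature_names if f not in case.features]
    if missing:
        raise ValueError(f"case lacks model features {missing}")
    x = np.array([case.features[f] for f in model.feature_names])

    labels: dict[str, int] = {}
    probs: dict[str, float] = {}
    for roi, clf in model.classifiers.items():
        p = _proba_one(clf, x)
        probs[roi] = p
        labels[roi] = int(p >= model.decision_cut)

    h_label = h_prob = None
    if model.hydro_classifier is not None:
        cols = [model.feature_names.index(f) for f in HYDRO_FEATURES]
        h_prob = _proba_one(model.hydro_classifier, x[cols])
        h_label = int(h_prob >= model.decision_cut)

    return RegionPredictionSet(
        labels=labels,
        probabilities=probs,
        hydrocephalus_label=h_label,
        hydrocephalus_probability=h_prob,
        decision_cut=model.decision_cut,
    )
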