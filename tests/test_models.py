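"""Classifier families, the BT threshold search and its brute-force oracle,
the two-stage CV protocol, performance metrics, and ICC3."""

import numpy as np
import pytest

from ads.models import (
    DEFAULT_THRESHOLD_GRID,
    LabeledCase,
    MODEL_FAMILIES,
    _stratified_folds,
    cases_from_frame,
    cases_to_frame,
    classification_metrics,
    feature_matrix,
    fit_binary_threshold,
    fit_model,
    icc3,
    load_model,
    predict_regions,
    save_model,
    select_hyperparameters,
)


def toy_cases(n, n_features=3, seed=0, noise=0.0, rule_tau=0.5):
    """Separable tabular cohort: label_i = (feature_i >= rule_tau), noised."""
    rng = np.random.default_rng(seed)
    X = rng.random((n, n_features))
    cases = []
    for row in X:
        feats = {f"structural:roi_{j}": float(v) for j, v in enumerate(row)}
        feats["log_volume_ml"] = float(np.log(1 + row.sum()))
        labels = {}
        for j, v in enumerate(row):
            y = int(v >= rule_tau)
            if rng.random() < noise:
                y = 1 - y
            labels[f"structural:roi_{j}"] = y
        cases.append(LabeledCase(features=feats, labels=labels))
    return cases


# ---------------------------------------------------------------------------
# Binary threshold model
# ---------------------------------------------------------------------------


def bt_oracle(x, y, grid, splits):
    """Independent exhaustive grid evaluation with hand-rolled BACC+F1."""

    def bacc_f1(yv, pred):
        tp = int(((pred == 1) & (yv == 1)).sum())
        fp = int(((pred == 1) & (yv == 0)).sum())
        fn = int(((pred == 0) & (yv == 1)).sum())
        tn = int(((pred == 0) & (yv == 0)).sum())
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
        return (sens + spec) / 2 + f1

    means = []
    for t in grid:
        means.append(
            np.mean([bacc_f1(y[val], (x[val] >= t).astype(int)) for _, val in splits])
        )
    best = max(means)
    for t, m in zip(grid, means):
        if m >= best - 1e-12:
            return t
    raise AssertionError


class TestBinaryThreshold:
    def test_separable_gap(self):
        # positives >= 0.30, negatives <= 0.09: minimal perfect threshold
        cases = []
        for v, y in [(0.31, 1), (0.5, 1), (0.9, 1), (0.30, 1),
                     (0.09, 0), (0.02, 0), (0.0, 0), (0.05, 0)]:
            cases.append(
                LabeledCase(features={"structural:r": v}, labels={"structural:r": y})
            )
        t = fit_binary_threshold(cases, "structural:r", folds=2, seed=0)
        assert 0.09 < t <= 0.30

    def test_single_class_rejected(self):
        cases = [
            LabeledCase(features={"structural:r": v}, labels={"structural:r": 1})
            for v in (0.2, 0.4, 0.9)
        ]
        with pytest.raises(ValueError, match="single label class"):
            fit_binary_threshold(cases, "structural:r")

    def test_unsorted_grid_rejected(self):
        cases = toy_cases(20, 1)
        with pytest.raises(ValueError, match="sorted"):
            fit_binary_threshold(cases, "structural:roi_0", grid=[0.5, 0.1])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        cases = toy_cases(60, 2, seed=seed, noise=0.1)
        roi = "structural:roi_0"
        X, _ = feature_matrix(cases, [roi])
        y = np.array([c.labels[roi] for c in cases])
        splits = _stratified_folds(y, 5, seed=seed)
        expected = bt_oracle(X[:, 0], y, list(DEFAULT_THRESHOLD_GRID), splits)
        assert fit_binary_threshold(cases, roi, folds=5, seed=seed) == expected

    def test_oracle_identity_on_phantom_rois(self, cohort_split):
        train, _ = cohort_split
        sub = train[:120]
        for roi in list(sub[0].labels)[:4]:
            X, _ = feature_matrix(sub, [roi])
            y = np.array([c.labels[roi] for c in sub])
            splits = _stratified_folds(y, 5, seed=7)
            expected = bt_oracle(X[:, 0], y, list(DEFAULT_THRESHOLD_GRID), splits)
            assert fit_binary_threshold(sub, roi, folds=5, seed=7) == expected


# ---------------------------------------------------------------------------
# Hyperparameter selection
# ---------------------------------------------------------------------------


class TestSelectHyperparameters:
    def test_singleton_grid_short_circuits(self):
        cases = toy_cases(40, 2)
        chosen = select_hyperparameters("RF", [{"n_estimators": 10}], cases, seed=0)
        assert chosen == {"n_estimators": 10}

    def test_knn_prefers_small_k_on_separable_cohort(self):
        cases = toy_cases(60, 2, seed=4)
        grid = [{"n_neighbors": k} for k in (1, 5, 51)]
        chosen = select_hyperparameters(
            "KNN", grid, cases, seed=0, roi="structural:roi_0"
        )
        assert chosen["n_neighbors"] in (1, 5)

    def test_protocol_deterministic(self):
        cases = toy_cases(50, 2, seed=2, noise=0.1)
        grid = [{"n_neighbors": k} for k in (1, 3, 5, 9)]
        a = select_hyperparameters("KNN", grid, cases, seed=11)
        b = select_hyperparameters("KNN", grid, cases, seed=11)
        assert a == b

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_hyperparameters("RF", [], toy_cases(30), seed=0)


# ---------------------------------------------------------------------------
# Full model fit / predict
# ---------------------------------------------------------------------------


class TestFitModel:
    def test_bt_family_delegates_to_threshold_fit(self):
        cases = toy_cases(60, 2, seed=3, noise=0.05)
        model = fit_model("BT", {}, cases, seed=5)
        for roi, t in model.bt.thresholds.items():
            assert t == fit_binary_threshold(cases, roi, folds=5, seed=5)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown model family"):
            fit_model("GBM", {}, toy_cases(30), seed=0)

    def test_constant_label_roi_predicts_prevalence(self):
        cases = toy_cases(30, 2, seed=1)
        for c in cases:
            c.labels["structural:roi_0"] = 1  # degenerate ROI
        model = fit_model("RF", {"n_estimators": 20}, cases, seed=0)
        assert "structural:roi_0" in model.constant_rois
        preds = predict_regions(model, cases[0])
        assert preds.probabilities["structural:roi_0"] == 1.0

    @pytest.mark.parametrize("family", [f for f in MODEL_FAMILIES if f != "BT"])
    def test_all_families_fit_and_predict(self, family):
        hp = {
            "RF": {"n_estimators": 20},
            "KNN": {"n_neighbors": 3},
            "SVM": {},
            "MLP": {"hidden_layer_sizes": (8,), "max_iter": 300},
            "LDA": {},
            "QDA": {"reg_param": 0.1},
        }[family]
        cases = toy_cases(50, 2, seed=6, noise=0.05)
        model = fit_model(family, hp, cases, seed=2)
        preds = predict_regions(model, cases[0])
        assert set(preds.rois) == set(cases[0].labels)
        for roi, p in preds.probabilities.items():
            assert 0.0 <= p <= 1.0
            assert preds.labels[roi] == int(p >= 0.5)

    def test_bt_boundary_classified_positive(self):
        cases = toy_cases(40, 1, seed=8)
        model = fit_model("BT", {}, cases, seed=0)
        roi = "structural:roi_0"
        t = model.bt.thresholds[roi]
        case = LabeledCase(
            features={roi: t, "log_volume_ml": 0.5}, labels={}
        )
        preds = predict_regions(model, case)
        assert preds.labels[roi] == 1  # fraction exactly at threshold -> injured

    def test_probability_range_on_random_inputs(self, rng):
        cases = toy_cases(50, 2, seed=9)
        model = fit_model("RF", {"n_estimators": 20}, cases, seed=1)
        for _ in range(200):
            feats = {f: float(rng.random()) for f in model.feature_names}
            preds = predict_regions(model, LabeledCase(features=feats, labels={}))
            assert all(0.0 <= p <= 1.0 for p in preds.probabilities.values())

    def test_feature_mismatch_rejected(self):
        model = fit_model("RF", {"n_estimators": 10}, toy_cases(30, 2), seed=0)
        with pytest.raises(ValueError, match="lacks model features"):
            predict_regions(model, LabeledCase(features={"x": 0.1}, labels={}))

    def test_seeded_fit_is_reproducible(self):
        cases = toy_cases(60, 2, seed=12, noise=0.1)
        a = fit_model("RF", {"n_estimators": 30}, cases, seed=7)
        b = fit_model("RF", {"n_estimators": 30}, cases, seed=7)
        for c in cases:
            pa = predict_regions(a, c).probabilities
            pb = predict_regions(b, c).probabilities
            assert pa == pb  # bit-identical

    def test_save_load_roundtrip(self, tmp_path):
        cases = toy_cases(40, 2, seed=13)
        model = fit_model("RF", {"n_estimators": 15}, cases, seed=4)
        save_model(model, tmp_path / "model.joblib")
        back = load_model(tmp_path / "model.joblib")
        assert back.card() == model.card()
        for c in cases[:5]:
            assert (
                predict_regions(back, c).probabilities
                == predict_regions(model, c).probabilities
            )

    def test_cohort_frame_roundtrip(self):
        cases = toy_cases(25, 2, seed=14)
        back = cases_from_frame(cases_to_frame(cases))
        assert [c.features for c in back] == [c.features for c in cases]
        assert [c.labels for c in back] == [c.labels for c in cases]


def test_hydro_head_trained_for_rf_only_with_labels(cohort_split):
    train, test = cohort_split
    model = fit_model("RF", {"n_estimators": 50}, train[:80], seed=2)
    assert model.hydro_classifier is not None
    preds = predict_regions(model, test[0])
    assert preds.hydrocephalus_label in (0, 1)
    bt = fit_model("BT", {}, train[:80], seed=2)
    assert bt.hydro_classifier is None  # no QFV component to threshold


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


class TestClassificationMetrics:
    def test_hand_computed_contingency(self):
        # TP=3, FP=1, FN=1, TN=5
        truth = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        pred = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
        m = classification_metrics(truth, pred)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.precision == pytest.approx(0.75)
        assert m.bacc == pytest.approx((0.75 + 5 / 6) / 2)  # 0.7917
        assert m.f1 == pytest.approx(0.75)
        # kappa: p_o = 0.8, p_e = (4*4 + 6*6)/100 = 0.52
        assert m.kappa == pytest.approx((0.8 - 0.52) / (1 - 0.52))  # 0.5833

    def test_perfect_prediction(self):
        m = classification_metrics([0, 1, 1, 0], [0, 1, 1, 0])
        assert (m.bacc, m.f1, m.precision, m.sensitivity, m.kappa) == (1, 1, 1, 1, 1)

    def test_all_negative_predictor_on_balanced_truth(self):
        with pytest.warns(UserWarning):
            m = classification_metrics([0, 1] * 10, [0] * 20)
        assert m.bacc == pytest.approx(0.5)
        assert m.f1 == 0.0

    def test_random_predictor_chance_level(self):
        rng = np.random.default_rng(99)
        n = 10000
        truth = rng.integers(0, 2, n)
        pred = rng.integers(0, 2, n)
        m = classification_metrics(truth, pred)
        se = 1 / (2 * np.sqrt(n / 2))  # per-class rate SE, conservative
        assert abs(m.bacc - 0.5) < 3 * se
        assert abs(m.kappa) < 3 * 2 * se  # independence -> kappa ~ 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([1, 0], [1])


class TestICC3:
    def test_identical_raters(self):
        ratings = np.array([[1.0, 1.0], [2.0, 2.0], [3.5, 3.5]])
        assert icc3(ratings) == pytest.approx(1.0)

    def test_antipattern_is_minus_one(self):
        assert icc3(np.array([[1.0, 2.0], [2.0, 1.0]])) == pytest.approx(-1.0)

    def test_consistency_form_shift_invariant(self, rng):
        ratings = rng.normal(0, 1, (8, 3))
        shifted = ratings.copy()
        shifted[:, 1] += 2.7  # rater bias leaves consistency ICC unchanged
        assert icc3(shifted) == pytest.approx(icc3(ratings))

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        ratings = rng.normal(0, 1, (10, 3)) + rng.normal(0, 1, (10, 1))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(10), 3),
                "rater": np.tile(np.arange(3), 10),
                "score": ratings.ravel(),
            }
        )
        table = pg.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        )
        # two-way mixed, single rater, consistency: pingouin's ICC(C,1)
        expected = float(table.set_index("Type").loc["ICC(C,1)", "ICC"])
        assert icc3(ratings) == pytest.approx(expected, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            icc3(np.array([[1.0, 1.0]]))  # single subject
        with pytest.raises(ValueError, match="undefined"):
            icc3(np.full((4, 3), 2.0))  # no variance anywhere


def test_make_case_concatenates_schemes(cohort):
    case = cohort[0]
    names = case.feature_names
    assert names[-1] == "gamma_ilvr"
    assert "log_volume_ml" in names
    art = [n for n in names if n.startswith("arterial:")]
    struct = [n for n in names if n.startswith("structural:")]
    assert art and struct and names[: len(art)] == art
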