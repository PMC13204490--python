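"""Emotion ensemble: base learners, SHAP attributions, weights, losses."""

import numpy as np
import pandas as pd
import pytest

from s2cfl.errors import (
    ConfigurationError,
    DegenerateAttributionError,
    InvalidArgumentError,
    LabelError,
    UnsupportedModelError,
)
from s2cfl.fgecn import (
    AttributionMatrix,
    BaseLearnerConfig,
    LABEL_COLUMN,
    ensemble_predict,
    ensemble_weights,
    explainability_loss,
    fit_base_learners,
    select_configuration,
    shap_attributions,
    split_xy,
)


def make_table(n=120, n_features=6, n_classes=3, seed=0, separable=True):
    """Synthetic feature table; when separable, feature 0 determines the class."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    classes = [f"class_{k}" for k in range(n_classes)]
    if separable:
        y = np.array(classes)[np.clip((X[:, 0] * 1.2 + 1.5).astype(int), 0, n_classes - 1)]
    else:
        y = rng.choice(classes, size=n)
    table = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)])
    table[LABEL_COLUMN] = y
    return table


@pytest.fixture(scope="module")
def fitted():
    table = make_table()
    models, classes = fit_base_learners(table, config=BaseLearnerConfig(seed=1))
    return table, models, classes


class TestBaseLearners:
    def test_probabilities_sum_to_one(self, fitted):
        from s2cfl.fgecn import predict_proba

        table, models, classes = fitted
        X, _, _ = split_xy(table)
        for p in predict_proba(models, X[:20]).values():
            assert p.shape == (20, len(classes))
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_separable_table_fits_well(self, fitted):
        from s2cfl.fgecn import predict_proba

        table, models, classes = fitted
        X, y, _ = split_xy(table)
        enc = {c: i for i, c in enumerate(classes)}
        yi = np.array([enc[v] for v in y])
        for name, p in predict_proba(models, X).items():
            acc = (np.argmax(p, axis=1) == yi).mean()
            assert acc >= 0.95, name

    def test_fixed_seed_reproducibility(self):
        from s2cfl.fgecn import predict_proba

        table = make_table(seed=3)
        X, _, _ = split_xy(table)
        m1, _ = fit_base_learners(table, config=BaseLearnerConfig(seed=9))
        m2, _ = fit_base_learners(table, config=BaseLearnerConfig(seed=9))
        p1, p2 = predict_proba(m1, X), predict_proba(m2, X)
        for name in p1:
            assert np.allclose(p1[name], p2[name], atol=0)

    def test_single_class_rejected(self):
        table = make_table(n=20, separable=False, seed=4)
        table[LABEL_COLUMN] = "only"
        with pytest.raises(LabelError):
            fit_base_learners(table)


class TestAttributions:
    def test_local_accuracy_additivity(self, fitted):
        table, models, _ = fitted
        X, _, feats = split_xy(table)
        for name, model in models.items():
            att = shap_attributions(name, model, X[:25], feats)
            recon = att.values.sum(axis=1) + att.base
            assert np.allclose(recon, att.output, atol=1e-4), name

    def test_constant_feature_gets_zero_attribution(self):
        table = make_table(seed=5)
        table["f5"] = 2.5  # constant column
        models, _ = fit_base_learners(table, config=BaseLearnerConfig(seed=2))
        X, _, feats = split_xy(table)
        for name, model in models.items():
            att = shap_attributions(name, model, X[:20], feats)
            assert np.allclose(att.values[:, 5], 0.0, atol=1e-10), name

    def test_planted_relevance_dominates(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(150, 2))
        y = np.where(X[:, 0] > 0, "pos", "neg")
        table = pd.DataFrame(X, columns=["f0", "f1"])
        table[LABEL_COLUMN] = y
        models, _ = fit_base_learners(table, config=BaseLearnerConfig(seed=3))
        Xa, _, feats = split_xy(table)
        for name, model in models.items():
            att = shap_attributions(name, model, Xa[:40], feats)
            mean_abs = att.mean_abs()
            assert mean_abs[0] > mean_abs[1], name

    def test_unsupported_model_rejected(self):
        from sklearn.linear_model import LogisticRegression

        with pytest.raises(UnsupportedModelError):
            shap_attributions("svm", LogisticRegression(), np.zeros((2, 2)), ["a", "b"])


def _att(name, values):
    values = np.asarray(values, dtype=float)
    return AttributionMatrix(
        model=name,
        values=values,
        base=np.zeros(values.shape[0]),
        output=values.sum(axis=1),
        feature_names=[f"f{i}" for i in range(values.shape[1])],
    )


class TestEnsembleWeights:
    def test_equal_mass_gives_uniform_weights(self):
        atts = {k: _att(k, np.ones((4, 3))) for k in ("gbdt", "xgb", "rf")}
        w = ensemble_weights(atts)
        assert all(np.isclose(v, 1 / 3, atol=1e-12) for v in w.weights.values())

    def test_two_one_one_mass_gives_half_quarter_quarter(self):
        atts = {
            "gbdt": _att("gbdt", 2.0 * np.ones((2, 5))),
            "xgb": _att("xgb", np.ones((2, 5))),
            "rf": _att("rf", -np.ones((2, 5))),  # absolute values count
        }
        w = ensemble_weights(atts)
        assert w.weights == pytest.approx({"gbdt": 0.5, "xgb": 0.25, "rf": 0.25})

    def test_zero_mass_model_gets_zero_weight(self):
        atts = {
            "gbdt": _att("gbdt", np.ones((2, 2))),
            "xgb": _att("xgb", np.zeros((2, 2))),
            "rf": _att("rf", np.ones((2, 2))),
        }
        assert ensemble_weights(atts).weights["xgb"] == 0.0

    def test_all_zero_requires_explicit_fallback(self):
        atts = {k: _att(k, np.zeros((2, 2))) for k in ("gbdt", "xgb", "rf")}
        with pytest.raises(DegenerateAttributionError):
            ensemble_weights(atts)
        w = ensemble_weights(atts, uniform_fallback=True)
        assert all(np.isclose(v, 1 / 3) for v in w.weights.values())

    def test_simplex_property_on_random_triples(self, rng):
        for _ in range(200):
            atts = {
                k: _att(k, rng.normal(size=(3, 4)) * rng.uniform(0, 5))
                for k in ("gbdt", "xgb", "rf")
            }
            w = ensemble_weights(atts, uniform_fallback=True)
            vals = np.array(list(w.weights.values()))
            assert np.all(vals >= 0)
            assert np.isclose(vals.sum(), 1.0, atol=1e-9)


class TestEnsemblePredict:
    def test_single_model_limit(self, fitted):
        from s2cfl.fgecn import EnsembleWeights, predict_proba

        table, models, _ = fitted
        X, _, _ = split_xy(table)
        w = EnsembleWeights({"gbdt": 1.0, "xgb": 0.0, "rf": 0.0})
        out = ensemble_predict(models, w, X[:10])
        assert np.allclose(out, predict_proba(models, X[:10])["gbdt"], atol=0)

    def test_matches_bruteforce_convex_combination(self, fitted):
        from s2cfl.fgecn import EnsembleWeights, predict_proba

        table, models, _ = fitted
        X, _, _ = split_xy(table)
        w = EnsembleWeights({"gbdt": 0.5, "xgb": 0.3, "rf": 0.2})
        out = ensemble_predict(models, w, X[:15])
        per_model = predict_proba(models, X[:15])
        brute = 0.5 * per_model["gbdt"] + 0.3 * per_model["xgb"] + 0.2 * per_model["rf"]
        assert np.allclose(out, brute, atol=1e-12)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)

    def test_model_weight_mismatch_rejected(self, fitted):
        _, models, _ = fitted
        from s2cfl.fgecn import EnsembleWeights

        w = EnsembleWeights({"gbdt": 0.5, "xgb": 0.5})
        with pytest.raises(ConfigurationError):
            ensemble_predict(models, w, np.zeros((1, 6)))


class TestExplainabilityLoss:
    def test_zero_penalty_weight_is_plain_cross_entropy(self):
        probs = np.array([[0.8, 0.2], [0.3, 0.7]])
        labels = np.array([0, 1])
        atts = {"a": _att("a", np.ones((2, 2))), "b": _att("b", np.zeros((2, 2)))}
        total, ce, pen = explainability_loss(probs, labels, atts, N=0.0)
        assert pen == 0.0
        assert total == ce == pytest.approx(-np.mean(np.log([0.8, 0.7])))

    def test_zero_deviation_gives_zero_penalty(self):
        probs = np.array([[0.6, 0.4]])
        atts = {k: _att(k, np.full((1, 3), 0.5)) for k in ("a", "b")}
        _, _, pen = explainability_loss(probs, np.array([0]), atts, N=2.0)
        assert pen == 0.0

    def test_penalty_is_homogeneous_in_deviation(self):
        probs = np.array([[0.6, 0.4]])
        labels = np.array([0])
        base = np.ones((1, 3))
        atts1 = {"a": _att("a", base), "b": _att("b", -base)}
        atts2 = {"a": _att("a", 2 * base), "b": _att("b", -2 * base)}
        _, _, pen1 = explainability_loss(probs, labels, atts1, N=1.0)
        _, _, pen2 = explainability_loss(probs, labels, atts2, N=1.0)
        assert pen2 == pytest.approx(2.0 * pen1)

    def test_negative_penalty_weight_rejected(self):
        with pytest.raises(InvalidArgumentError):
            explainability_loss(np.array([[1.0, 0.0]]), np.array([0]), {}, N=-1.0)


class TestSelectConfiguration:
    def _folds(self, n, k=2, seed=0):
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        parts = np.array_split(order, k)
        return [
            (np.concatenate([p for j, p in enumerate(parts) if j != i]), parts[i])
            for i in range(k)
        ]

    def test_singleton_grid_returned(self):
        table = make_table(n=60, seed=7)
        cfg = BaseLearnerConfig(seed=1)
        best, report = select_configuration([cfg], table, self._folds(60))
        assert best is cfg
        assert len(report) == 2  # 1 config x 2 folds

    def test_report_bookkeeping_and_argmin(self):
        table = make_table(n=80, seed=8)
        good = BaseLearnerConfig(seed=1)
        crippled = BaseLearnerConfig(
            gbdt={"n_estimators": 1, "num_leaves": 2, "learning_rate": 1e-5},
            xgb={"n_estimators": 1, "max_depth": 1, "learning_rate": 1e-5},
            rf={"n_estimators": 1, "max_depth": 1},
            seed=1,
        )
        best, report = select_configuration([good, crippled], table, self._folds(80), N=0.0)
        assert len(report) == 4  # 2 configs x 2 folds
        by_cfg = report.groupby("config")["loss"].mean()
        assert by_cfg[0] < by_cfg[1]
        assert best is good

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            select_configuration([], make_table(n=30), self._folds(30))
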