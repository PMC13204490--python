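"""Fine-grained emotion classification: attribution-weighted tree ensemble.

Stage 2 of the pipeline.  A feature table is assembled per episode (raw-branch
fused latent, DSQ scores, per-image summary statistics, self-report vector)
and three heterogeneous tree learners are trained on the 10-class emotion
label: a gradient-boosted decision tree ensemble (LightGBM), XGBoost, and a
random forest.  Per-model SHAP attribution matrices are computed (native
contribution outputs for the boosters, the package's own path-dependent
TreeSHAP for the forest); ensemble weights are the normalized absolute
attribution masses

    w_k = sum|A^k| / sum_k sum|A^k|,

forming a probability simplex, and the ensemble prediction is the weighted
sum of the per-model class-probability vectors.  An explainability-regularized
loss (classification cross-entropy plus an L1 penalty on the deviation of
attributions from their cross-model mean) serves as the model-selection
criterion; tree-fitting APIs cannot minimize attribution penalties directly,
so the penalty steers selection, not gradient updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateAttributionError,
    DependencyError,
    InvalidArgumentError,
    LabelError,
    UnsupportedModelError,
)
from .treeshap import forest_shap
from .types import EMOTIONS

MODEL_NAMES = ("gbdt", "xgb", "rf")
LABEL_COLUMN = "emotion"


@dataclass
class BaseLearnerConfig:
    gbdt: dict = field(
        default_factory=lambda: {"n_estimators": 60, "num_leaves": 15, "learning_rate": 0.15}
    )
    xgb: dict = field(
        default_factory=lambda: {"n_estimators": 60, "max_depth": 4, "learning_rate": 0.3}
    )
    rf: dict = field(default_factory=lambda: {"n_estimators": 50, "max_depth": 6})
    seed: int = 0


@dataclass
class AttributionMatrix:
    """Per-row, per-feature attribution of each row's predicted class."""

    model: str
    values: np.ndarray  # (n_rows, n_features)
    base: np.ndarray  # (n_rows,)
    output: np.ndarray  # (n_rows,) model output the attributions decompose
    feature_names: list[str]

    def mass(self) -> float:
        """Total absolute attribution mass (the ensemble-weight numerator)."""
        return float(np.abs(self.values).sum())

    def mean_abs(self) -> np.ndarray:
        return np.abs(self.values).mean(axis=0)


@dataclass
class EnsembleWeights:
    """Normalized contribution shares of the three base learners (a simplex)."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.weights.values()))
        if (vals < 0).any() or not np.isclose(vals.sum(), 1.0, atol=1e-9):
            raise ConfigurationError("ensemble weights must be a probability simplex")

    def as_array(self, names=MODEL_NAMES) -> np.ndarray:
        return np.array([self.weights[n] for n in names])


# ---------------------------------------------------------------------------
# Feature-table assembly


def _image_entropy(grid: np.ndarray) -> float:
    total = grid.sum()
    if total <= 0:
        return 0.0
    p = grid[grid > 0] / total
    return float(-(p * np.log(p)).sum())


def build_feature_table(
    records,
    tpedn_model,
    dc2ptn_model,
    image_stacks: dict[str, np.ndarray],
    channel_names: list[str],
    taps: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Assemble the stage-2 feature table (one row per episode).

    Columns: fused latent of the raw branch, the three DSQ scores of the image
    branch, (mean, max, entropy) per image channel, and the self-report
    vector; plus the emotion label column.  Deterministic given the models.
    """
    from .tpedn import signals_to_arrays

    if tpedn_model is None or dc2ptn_model is None:
        raise DependencyError("both stage-1 models are required to build the feature table")
    xs = signals_to_arrays(records, tpedn_model.config)
    from .nn import Tensor

    fused, _, _ = tpedn_model.forward_trunk({m: Tensor(v) for m, v in xs.items()})
    fused = fused.data
    probs = tpedn_model.predict_proba(xs)
    pos = np.stack([probs["depression"][:, 1], probs["valence"][:, 1], probs["arousal"][:, 1]], 1)
    if taps is None and dc2ptn_model.config.use_fusion:
        taps = tpedn_model.encoder_taps(xs)
    stacks = np.stack([image_stacks[r.episode_id] for r in records])
    dsq = dc2ptn_model.predict_scores(stacks, pos, taps)

    rows = {}
    for j in range(fused.shape[1]):
        rows[f"latent_{j:03d}"] = fused[:, j]
    for t, name in zip(range(3), ("dep", "val", "aro")):
        rows[f"dsq_{name}"] = dsq[:, t]
    for c, cname in enumerate(channel_names):
        rows[f"img_{cname}_mean"] = stacks[:, c].mean(axis=(1, 2))
        rows[f"img_{cname}_max"] = stacks[:, c].max(axis=(1, 2))
        rows[f"img_{cname}_entropy"] = [_image_entropy(stacks[i, c]) for i in range(len(records))]
    sr_dim = 0 if records[0].self_report is None else len(records[0].self_report)
    for j in range(sr_dim):
        rows[f"sr_{j}"] = [r.self_report[j] for r in records]
    table = pd.DataFrame(rows, index=[r.episode_id for r in records])
    table[LABEL_COLUMN] = [r.labels.emotion for r in records]
    if table.drop(columns=[LABEL_COLUMN]).isna().any().any():
        raise ConfigurationError("feature table contains missing values after assembly")
    return table


def split_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    feats = [c for c in table.columns if c != LABEL_COLUMN]
    X = table[feats].to_numpy(dtype=float)
    y = table[LABEL_COLUMN].to_numpy()
    return X, y, feats


# ---------------------------------------------------------------------------
# Base learners


def fit_base_learners(
    table: pd.DataFrame,
    train_idx: np.ndarray | None = None,
    config: BaseLearnerConfig | None = None,
) -> tuple[dict, np.ndarray]:
    """Fit the three tree learners; returns (models, class list).

    Labels are encoded onto the sorted class set of the training rows; all
    three models share that encoding.
    """
    from lightgbm import LGBMClassifier
    from sklearn.ensemble import RandomForestClassifier
    from xgboost import XGBClassifier

    config = config or BaseLearnerConfig()
    X, y, _ = split_xy(table)
    if train_idx is not None:
        X, y = X[train_idx], y[train_idx]
    classes = np.array(sorted(set(y)))
    if classes.shape[0] < 2:
        raise LabelError("training rows contain a single class")
    enc = {c: i for i, c in enumerate(classes)}
    yi = np.array([enc[v] for v in y])
    models = {
        "gbdt": LGBMClassifier(
            random_state=config.seed, deterministic=True, n_jobs=1, verbose=-1, **config.gbdt
        ),
        "xgb": XGBClassifier(
            random_state=config.seed, n_jobs=1, tree_method="exact", **config.xgb
        ),
        "rf": RandomForestClassifier(random_state=config.seed, n_jobs=1, **config.rf),
    }
    for model in models.values():
        model.fit(X, yi)
    return models, classes


def _model_input(model, X: np.ndarray):
    """Match the estimator's recorded feature names (LightGBM registers
    synthetic names even for array fits and warns on every array predict)."""
    names = getattr(model, "feature_names_in_", None)
    if names is None:
        return X
    return pd.DataFrame(np.asarray(X, dtype=float), columns=list(names))


def predict_proba(models: dict, X: np.ndarray) -> dict[str, np.ndarray]:
    return {name: model.predict_proba(_model_input(model, X)) for name, model in models.items()}


# ---------------------------------------------------------------------------
# SHAP attributions


def shap_attributions(name: str, model, X: np.ndarray, feature_names: list[str]) -> AttributionMatrix:
    """Attribution of each row's predicted class, per feature.

    Boosters attribute their margin (raw score); the random forest attributes
    the predicted-class probability.  Local accuracy holds in each model's own
    output space: values.sum(row) + base == output[row].
    """
    if name not in MODEL_NAMES:
        raise UnsupportedModelError(f"no attribution backend for model {name!r}")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    pred = np.argmax(model.predict_proba(_model_input(model, X)), axis=1)
    if name == "xgb":
        import xgboost as xgb

        booster = model.get_booster()
        dm = xgb.DMatrix(X)
        contribs = booster.predict(dm, pred_contribs=True)  # (n, k, m+1) or (n, m+1)
        margins = booster.predict(dm, output_margin=True)
        if contribs.ndim == 3:
            rows = contribs[np.arange(n), pred]
            out = margins[np.arange(n), pred]
        else:
            rows = contribs
            out = margins
        values, base = rows[:, :-1], rows[:, -1]
    elif name == "gbdt":
        Xin = _model_input(model, X)
        contribs = model.predict(Xin, pred_contrib=True)
        raw = model.predict(Xin, raw_score=True)
        m = X.shape[1]
        k = contribs.shape[1] // (m + 1)
        contribs = contribs.reshape(n, k, m + 1)
        if raw.ndim == 1:
            raw = np.stack([-raw, raw], axis=1)  # binary: symmetric margins
            pred_k = pred
        else:
            pred_k = pred
        rows = contribs[np.arange(n), pred_k if k > 1 else 0]
        out = raw[np.arange(n), pred]
        values, base = rows[:, :-1], rows[:, -1]
    elif name == "rf":
        values, base = forest_shap(model, X, class_indices=pred)
        out = model.predict_proba(X)[np.arange(n), pred]
    else:
        raise UnsupportedModelError(f"no attribution backend for model {name!r}")
    return AttributionMatrix(
        model=name,
        values=np.asarray(values, dtype=float),
        base=np.asarray(base, dtype=float),
        output=np.asarray(out, dtype=float),
        feature_names=list(feature_names),
    )


# ---------------------------------------------------------------------------
# Ensemble weighting and prediction


def ensemble_weights(
    attributions: dict[str, AttributionMatrix], uniform_fallback: bool = False
) -> EnsembleWeights:
    """Normalized absolute contribution sums: w_k = sum|A^k| / sum_k sum|A^k|."""
    masses = {name: att.mass() for name, att in attributions.items()}
    total = sum(masses.values())
    if total == 0:
        if not uniform_fallback:
            raise DegenerateAttributionError(
                "all attribution mass is zero; pass uniform_fallback=True to accept equal weights"
            )
        k = len(masses)
        return EnsembleWeights({name: 1.0 / k for name in masses})
    return EnsembleWeights({name: mass / total for name, mass in masses.items()})


def ensemble_predict(models: dict, weights: EnsembleWeights, X: np.ndarray) -> np.ndarray:
    """Weighted sum of per-model class-probability vectors."""
    if set(models) != set(weights.weights):
        raise ConfigurationError("model set and weight set disagree")
    out = None
    for name, model in models.items():
        p = model.predict_proba(_model_input(model, np.asarray(X, dtype=float)))
        term = weights.weights[name] * p
        out = term if out is None else out + term
    sums = out.sum(axis=1, keepdims=True)
    if np.abs(sums - 1.0).max() > 1e-9:  # weights sum to 1, so this is float dust
        out = out / sums
    return out


def explainability_loss(
    pred_probs: np.ndarray,
    labels: np.ndarray,
    attributions: dict[str, AttributionMatrix],
    expected: np.ndarray | None = None,
    N: float = 0.1,
) -> tuple[float, float, float]:
    """Cross-entropy plus N * L1 deviation of attributions from expectation.

    ``expected`` defaults to the cross-model mean attribution per (row,
    feature).  Returns (total, classification term, penalty term).
    """
    if N < 0:
        raise InvalidArgumentError("penalty weight N must be nonnegative")
    pred_probs = np.asarray(pred_probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != pred_probs.shape[0]:
        raise InvalidArgumentError("predictions and labels disagree in length")
    p_true = np.clip(pred_probs[np.arange(labels.shape[0]), labels], 1e-12, 1.0)
    ce = float(-np.log(p_true).mean())
    stack = np.stack([att.values for att in attributions.values()])
    if expected is None:
        expected = stack.mean(axis=0)
    penalty = float(np.abs(stack - expected[None]).sum())
    return ce + N * penalty, ce, N * penalty


def select_configuration(
    grid: list[BaseLearnerConfig],
    table: pd.DataFrame,
    folds: list[tuple[np.ndarray, np.ndarray]],
    N: float = 0.1,
) -> tuple[BaseLearnerConfig, pd.DataFrame]:
    """Grid search scored by the explainability-regularized loss on validation
    folds; returns (argmin configuration, per-(configuration, fold) report)."""
    if not grid:
        raise ConfigurationError("empty hyperparameter grid")
    X, y, feats = split_xy(table)
    classes = np.array(sorted(set(y)))
    enc = {c: i for i, c in enumerate(classes)}
    yi = np.array([enc[v] for v in y])
    rows = []
    for gi, cfg in enumerate(grid):
        for fi, (tr, va) in enumerate(folds):
            models, _ = fit_base_learners(table, train_idx=tr, config=cfg)
            atts = {
                name: shap_attributions(name, model, X[va], feats)
                for name, model in models.items()
            }
            w = ensemble_weights(atts, uniform_fallback=True)
            probs = ensemble_predict(models, w, X[va])
            total, ce, pen = explainability_loss(probs, yi[va], atts, N=N)
            rows.append(
                {"config": gi, "fold": fi, "loss": total, "ce": ce, "penalty": pen}
            )
    report = pd.DataFrame(rows)
    mean_loss = report.groupby("config")["loss"].mean()
    best = int(mean_loss.idxmin())
    return grid[best], report
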