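"""Evaluation: confusion metrics, grouped stratified CV, paired tests, ablations.

Classification metrics are computed in exact rational arithmetic and converted
to float at the end; zero-denominator cases follow a documented convention
(the metric is reported as 0 and flagged as degenerate rather than NaN).

Cross-validation folds are subject-independent (every subject's episodes share
one fold) and stratified best-effort by a greedy assignment: subjects are
ordered by episode count and label composition, then each is placed in the
fold that minimizes the deviation of fold class proportions from the global
proportions.  Stratification and subject grouping can conflict; the achieved
deviation is recorded instead of being silently ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .errors import DegenerateTestError, InvalidArgumentError, SplitError

TASKS = ("depression", "valence", "arousal")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(truth, predicted, positive_class) -> ConfusionCounts:
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise InvalidArgumentError("truth and prediction lengths differ")
    t_pos = truth == positive_class
    p_pos = predicted == positive_class
    return ConfusionCounts(
        tp=int(np.sum(t_pos & p_pos)),
        tn=int(np.sum(~t_pos & ~p_pos)),
        fp=int(np.sum(~t_pos & p_pos)),
        fn=int(np.sum(t_pos & ~p_pos)),
    )


@dataclass
class MetricValues:
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    degenerate: set = field(default_factory=set)

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.sensitivity + self.specificity)


def metrics(counts: ConfusionCounts) -> MetricValues:
    """accuracy, sensitivity (recall), specificity, F1 from exact counts."""

    degenerate: set = set()

    def ratio(num: int, den: int, name: str) -> Fraction:
        if den == 0:
            degenerate.add(name)
            return Fraction(0)
        return Fraction(num, den)

    acc = ratio(counts.tp + counts.tn, counts.total, "accuracy")
    sens = ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    spec = ratio(counts.tn, counts.tn + counts.fp, "specificity")
    prec = ratio(counts.tp, counts.tp + counts.fp, "precision")
    if prec + sens == 0:
        degenerate.add("f1")
        f1 = Fraction(0)
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return MetricValues(float(acc), float(sens), float(spec), float(f1), degenerate)


def macro_f1(truth, predicted, classes=None) -> float:
    """Unweighted mean of one-vs-rest F1 over classes present in the truth."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if classes is None:
        classes = np.unique(truth)
    scores = [metrics(confusion_counts(truth, predicted, c)).f1 for c in classes]
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Subject-independent stratified folds


@dataclass
class FoldSplit:
    assignments: np.ndarray  # fold index per episode
    k: int
    subject_folds: dict[str, int]
    stratification_deviation: float  # achieved L1 deviation from global props

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.where(self.assignments == fold)[0]
        train = np.where(self.assignments != fold)[0]
        return train, test

    def fold_hash(self) -> int:
        return hash(self.assignments.tobytes())


def make_folds(labels, subject_ids, k: int = 5, seed: int = 0) -> FoldSplit:
    """Greedy group-stratified assignment of subjects to k folds."""
    labels = np.asarray(labels)
    subject_ids = np.asarray(subject_ids)
    subjects = list(dict.fromkeys(subject_ids))  # stable order
    if len(subjects) < k:
        raise SplitError(f"need at least {k} subjects for {k} folds, got {len(subjects)}")
    classes = np.unique(labels)
    global_counts = np.array([(labels == c).sum() for c in classes], dtype=float)
    global_props = global_counts / global_counts.sum()

    comp = {}
    for s in subjects:
        mask = subject_ids == s
        comp[s] = np.array([(labels[mask] == c).sum() for c in classes], dtype=float)
    rng = np.random.default_rng(seed)
    order = sorted(
        rng.permutation(subjects).tolist(),
        key=lambda s: (-comp[s].sum(), tuple(-comp[s])),
    )

    # greedy assignment minimizing the cross-fold spread of per-class counts
    # (normalized by class frequency), which balances fold sizes and class
    # mixes simultaneously; per-fold objectives can starve or overfill folds
    fold_counts = np.zeros((k, len(classes)))
    norm = np.where(global_counts > 0, global_counts, 1.0)
    subject_folds: dict[str, int] = {}
    for s in order:
        best, best_key = None, None
        for f in range(k):
            trial = fold_counts.copy()
            trial[f] += comp[s]
            spread = float((trial / norm[None]).std(axis=0).mean())
            key = (spread, fold_counts[f].sum(), f)
            if best_key is None or key < best_key:
                best, best_key = f, key
        subject_folds[s] = best
        fold_counts[best] += comp[s]

    assignments = np.array([subject_folds[s] for s in subject_ids])
    tots = fold_counts.sum(axis=1, keepdims=True)
    dev = float(np.abs(fold_counts / tots - global_props[None]).sum(axis=1).mean())
    return FoldSplit(assignments, k, subject_folds, dev)


# ---------------------------------------------------------------------------
# Paired t-test


def paired_ttest(fold_scores_a, fold_scores_b) -> tuple[float, float]:
    """Two-sided paired t on per-fold metric differences (df = k - 1)."""
    from scipy import stats

    a = np.asarray(fold_scores_a, dtype=float)
    b = np.asarray(fold_scores_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise InvalidArgumentError("need two equal-length score vectors of size >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateTestError("zero-variance differences; paired t undefined")
    t = d.mean() / (sd / np.sqrt(d.size))
    p = 2.0 * stats.t.sf(abs(t), df=d.size - 1)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Cross-validation harness


@dataclass
class MetricsReport:
    fold_rows: pd.DataFrame  # task, fold, metric columns
    predictions: pd.DataFrame  # episode_id, fold, task, truth, pred, prob

    def aggregate(self) -> pd.DataFrame:
        cols = ["accuracy", "sensitivity", "specificity", "f1", "balanced_accuracy"]
        agg = self.fold_rows.groupby("task")[cols].agg(["mean", "std"])
        return agg

    def fold_scores(self, task: str, metric: str = "accuracy") -> np.ndarray:
        rows = self.fold_rows[self.fold_rows["task"] == task].sort_values("fold")
        return rows[metric].to_numpy()


def crossval_run(
    pipeline_factory,
    records,
    k: int = 5,
    seed: int = 0,
    stratify_task: str = "arousal",
    tasks=TASKS,
    folds: FoldSplit | None = None,
) -> MetricsReport:
    """Train/evaluate a pipeline per fold and aggregate metrics.

    ``pipeline_factory(seed)`` must return an object with ``fit(records)`` and
    ``predict(records) -> {task: (n,) probability of the high class}``.
    """
    records = list(records)
    if folds is None:
        labels = np.array([getattr(r.labels, stratify_task) for r in records])
        subject_ids = np.array([r.subject_id for r in records])
        folds = make_folds(labels, subject_ids, k=k, seed=seed)
    fold_rows, pred_rows = [], []
    for f in range(folds.k):
        train_idx, test_idx = folds.fold_indices(f)
        train = [records[i] for i in train_idx]
        test = [records[i] for i in test_idx]
        pipeline = pipeline_factory(seed)
        pipeline.fit(train)
        probs = pipeline.predict(test)
        for task in tasks:
            truth = np.array([getattr(r.labels, task) for r in test])
            p = np.asarray(probs[task])
            pred = (p >= 0.5).astype(int)
            mv = metrics(confusion_counts(truth, pred, positive_class=1))
            fold_rows.append(
                {
                    "task": task,
                    "fold": f,
                    "n": len(test),
                    "accuracy": mv.accuracy,
                    "sensitivity": mv.sensitivity,
                    "specificity": mv.specificity,
                    "f1": mv.f1,
                    "balanced_accuracy": mv.balanced_accuracy,
                    "degenerate": ";".join(sorted(mv.degenerate)),
                }
            )
            for rec, pi, ti in zip(test, p, truth):
                pred_rows.append(
                    {
                        "episode_id": rec.episode_id,
                        "fold": f,
                        "task": task,
                        "truth": int(ti),
                        "prob": float(pi),
                    }
                )
    return MetricsReport(pd.DataFrame(fold_rows), pd.DataFrame(pred_rows))


ABLATION_VARIANTS = ("tp_edn_only", "dc2_ptn_only", "both_no_fusion", "plus_fusion", "full")


def ablation_suite(
    records,
    variant_factory,
    variants=ABLATION_VARIANTS,
    seeds=(0, 1, 2),
    k: int = 2,
    stratify_task: str = "arousal",
    tasks=("arousal",),
) -> pd.DataFrame:
    """Run cross-validation per variant with shared folds and seeds.

    ``variant_factory(variant, seed)`` returns a pipeline (fit/predict as in
    :func:`crossval_run`).  Emits one row per (variant, seed, task) with mean
    fold metrics, the shared fold hash, and a paired t-test against the full
    variant where both are present.
    """
    from .errors import ConfigurationError

    for v in variants:
        if v not in ABLATION_VARIANTS:
            raise ConfigurationError(f"unknown ablation variant {v!r}")
    records = list(records)
    rows = []
    fold_scores: dict[tuple[str, int, str], np.ndarray] = {}
    for seed in seeds:
        labels = np.array([getattr(r.labels, stratify_task) for r in records])
        subject_ids = np.array([r.subject_id for r in records])
        folds = make_folds(labels, subject_ids, k=k, seed=seed)  # shared per seed
        for variant in variants:
            report = crossval_run(
                lambda s, v=variant: variant_factory(v, s),
                records,
                seed=seed,
                tasks=tasks,
                folds=folds,
            )
            for task in tasks:
                scores = report.fold_scores(task)
                fold_scores[(variant, seed, task)] = scores
                rows.append(
                    {
                        "variant": variant,
                        "seed": seed,
                        "task": task,
                        "accuracy": float(scores.mean()),
                        "accuracy_sd": float(scores.std(ddof=1)) if len(scores) > 1 else 0.0,
                        "fold_hash": folds.fold_hash(),
                    }
                )
    table = pd.DataFrame(rows)
    # paired test vs the full variant on concatenated fold scores
    if "full" in variants:
        pvals = {}
        for variant in variants:
            if variant == "full":
                continue
            for task in tasks:
                a = np.concatenate([fold_scores[("full", s, task)] for s in seeds])
                b = np.concatenate([fold_scores[(variant, s, task)] for s in seeds])
                try:
                    _, p = paired_ttest(a, b)
                except DegenerateTestError:
                    p = np.nan
                pvals[(variant, task)] = p
        table["p_vs_full"] = [
            pvals.get((r.variant, r.task), np.nan) for r in table.itertuples()
        ]
    return table
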