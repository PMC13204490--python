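"""End-to-end orchestration: variants, staged runs, caching, reporting.

Two layers:

- :class:`AffectPipeline` — a fit/predict estimator over episodes used by the
  cross-validation and ablation harnesses.  Its ``variant`` selects which
  branches are active (raw-signal branch only, image branch only, both without
  fusion, with fusion, or the full model with CBAM attention).
- :func:`run_pipeline` — the staged workflow (simulate -> preprocess ->
  transform -> pretrain -> finetune -> image-branch training -> feature table
  -> emotion ensemble -> evaluation), each stage writing versioned outputs and
  a manifest entry keyed by a configuration hash so unchanged stages are
  skipped on re-runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import dc2ptn as dc2
from . import evalcv, fgecn, synthetic, tpedn
from .dc2ptn import GridConfig
from .errors import ConfigurationError, DataError
from .preprocess import PreprocessConfig, preprocess_cohort
from .sig2img import STACK_MODALITIES, STACK_TRANSFORMS, episode_image_stack, stack_channel_names
from .tpedn import TPEDNConfig
from .types import CohortConfig, Modality


@dataclass
class PreparedCohort:
    """Preprocessed episodes plus their image stacks, shared across folds."""

    records: list
    stacks: dict[str, np.ndarray]
    channel_names: list[str]

    def subset(self, records) -> list:
        by_id = {r.episode_id: r for r in self.records}
        return [by_id[r.episode_id] for r in records]


def prepare_cohort(
    records,
    pre_config: PreprocessConfig | None = None,
    image_size: tuple[int, int] = (32, 32),
    n_scales: int = 2,
    wpt_levels: int = 5,
) -> PreparedCohort:
    """Filter, condition and render image stacks for a cohort (done once)."""
    processed, _ = preprocess_cohort(records, pre_config)
    if not processed:
        raise DataError("no episodes survive filtering")
    stacks = {
        rec.episode_id: episode_image_stack(
            rec, size=image_size, levels=wpt_levels, n_scales=n_scales
        )
        for rec in processed
    }
    return PreparedCohort(processed, stacks, stack_channel_names())


_VARIANT_FLAGS = {
    # (use_conditioning, use_fusion, use_cbam)
    "dc2_ptn_only": (False, False, True),
    "both_no_fusion": (True, False, False),
    "plus_fusion": (True, True, False),
    "full": (True, True, True),
}


@dataclass
class PipelineConfig:
    tpedn: TPEDNConfig = field(default_factory=TPEDNConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    variant: str = "full"
    affect_source: str = "auto"  # dsq | tpedn | mean | auto
    ssl_epochs: int = 0  # 0 skips SSL pretraining inside fit (CV speed)
    tpedn_epochs: int = 8
    dc2_epochs: int = 6

    def __post_init__(self) -> None:
        if self.variant not in ("tp_edn_only",) + tuple(_VARIANT_FLAGS):
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.affect_source not in ("dsq", "tpedn", "mean", "auto"):
            raise ConfigurationError(f"unknown affect source {self.affect_source!r}")


class AffectPipeline:
    """fit/predict wrapper around the two branches for one variant.

    ``tpedn_cache`` (optional dict) memoizes the trained raw-signal branch per
    (seed, training set): ablation variants share it, so the harness trains it
    once per fold instead of once per variant.
    """

    def __init__(
        self,
        config: PipelineConfig,
        prepared: PreparedCohort,
        seed: int = 0,
        tpedn_cache: dict | None = None,
    ):
        self.config = config
        self.prepared = prepared
        self.seed = seed
        self.tpedn_cache = tpedn_cache
        self.tpedn_model: tpedn.TPEDN | None = None
        self.dc2_model: dc2.DC2PTN | None = None

    # which probability stream scores the affect tasks: with both branches
    # active, the DSQ complements (rather than replaces) the softmax heads,
    # so the default combined score is their mean
    def _source(self) -> str:
        if self.config.affect_source != "auto":
            return self.config.affect_source
        if self.config.variant == "tp_edn_only":
            return "tpedn"
        if self.config.variant == "dc2_ptn_only":
            return "dsq"
        return "mean"

    def _grid_config(self) -> GridConfig:
        cond, fus, cbam = _VARIANT_FLAGS[self.config.variant]
        base = self.config.grid.__dict__ | {
            "use_conditioning": cond,
            "use_fusion": fus,
            "use_cbam": cbam,
            "seed": self.seed,
        }
        if self.tpedn_model is not None:  # tap widths follow the raw branch
            base["tap_dims"] = self.tpedn_model.tap_dims
        return GridConfig(**base)

    def fit(self, records) -> "AffectPipeline":
        recs = self.prepared.subset(records)
        cfg = self.config
        tp_cfg = TPEDNConfig(**{**cfg.tpedn.__dict__, "seed": self.seed})
        if cfg.variant != "dc2_ptn_only":
            cache_key = None
            if self.tpedn_cache is not None:
                cache_key = (
                    self.seed,
                    cfg.ssl_epochs,
                    cfg.tpedn_epochs,
                    repr(tp_cfg),
                    tuple(sorted(r.episode_id for r in recs)),
                )
            if cache_key is not None and cache_key in self.tpedn_cache:
                self.tpedn_model = self.tpedn_cache[cache_key]
            else:
                state = None
                if cfg.ssl_epochs > 0:
                    ssl_cfg = TPEDNConfig(**{**tp_cfg.__dict__, "epochs": cfg.ssl_epochs})
                    model, _ = tpedn.pretrain_ssl(recs, ssl_cfg)
                    state = model.state_dict()
                self.tpedn_model, _ = tpedn.finetune_heads(
                    recs, tp_cfg, pretrained_state=state, epochs=cfg.tpedn_epochs
                )
                if cache_key is not None:
                    self.tpedn_cache[cache_key] = self.tpedn_model
        if cfg.variant != "tp_edn_only":
            grid_cfg = self._grid_config()
            stacks = np.stack([self.prepared.stacks[r.episode_id] for r in recs])
            probs, taps = self._conditioning(recs, grid_cfg)
            labels = tpedn.task_labels(recs)
            self.dc2_model, _ = dc2.train_dc2ptn(
                stacks, probs, taps, labels, grid_cfg, epochs=cfg.dc2_epochs
            )
        return self

    def _conditioning(self, recs, grid_cfg: GridConfig):
        n = len(recs)
        if self.tpedn_model is None:
            return np.full((n, 3), 0.5), None
        xs = tpedn.signals_to_arrays(recs, self.tpedn_model.config)
        p = self.tpedn_model.predict_proba(xs)
        probs = np.stack(
            [p["depression"][:, 1], p["valence"][:, 1], p["arousal"][:, 1]], axis=1
        )
        taps = self.tpedn_model.encoder_taps(xs) if grid_cfg.use_fusion else None
        return probs, taps

    def predict(self, records) -> dict[str, np.ndarray]:
        """P(high) per affect task for each episode."""
        recs = self.prepared.subset(records)
        source = self._source()
        out_tp = None
        if self.tpedn_model is not None:
            xs = tpedn.signals_to_arrays(recs, self.tpedn_model.config)
            p = self.tpedn_model.predict_proba(xs)
            out_tp = {
                "depression": p["depression"][:, 1],
                "valence": p["valence"][:, 1],
                "arousal": p["arousal"][:, 1],
            }
        out_dsq = None
        if self.dc2_model is not None:
            grid_cfg = self.dc2_model.config
            probs, taps = self._conditioning(recs, grid_cfg)
            stacks = np.stack([self.prepared.stacks[r.episode_id] for r in recs])
            scores = self.dc2_model.predict_scores(stacks, probs, taps)
            out_dsq = {"depression": scores[:, 0], "valence": scores[:, 1], "arousal": scores[:, 2]}
        if source == "tpedn" or out_dsq is None:
            return out_tp
        if source == "dsq" or out_tp is None:
            return out_dsq
        return {t: 0.5 * (out_tp[t] + out_dsq[t]) for t in out_tp}


def make_variant_factory(config: PipelineConfig, prepared: PreparedCohort):
    """Factory for the ablation harness: (variant, seed) -> pipeline.

    All variants produced by one factory share a raw-signal-branch cache, so
    the TP-EDN is trained once per (seed, fold) rather than once per variant.
    """
    cache: dict = {}

    def factory(variant: str, seed: int) -> AffectPipeline:
        cfg = PipelineConfig(**{**config.__dict__, "variant": variant})
        return AffectPipeline(cfg, prepared, seed=seed, tpedn_cache=cache)

    return factory


# ---------------------------------------------------------------------------
# Staged run with caching


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    tpedn: TPEDNConfig = field(default_factory=TPEDNConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    learners: fgecn.BaseLearnerConfig = field(default_factory=fgecn.BaseLearnerConfig)
    ssl_epochs: int = 10
    finetune_epochs: int = 8
    dc2_epochs: int = 6
    n_scales: int = 2
    wpt_levels: int = 5
    test_fraction: float = 0.2
    seed: int = 0

    def to_dict(self) -> dict:
        def norm(obj):
            if isinstance(obj, dict):
                return {k: norm(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [norm(v) for v in obj]
            return obj

        return norm(asdict(self))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        sub = {
            "cohort": CohortConfig,
            "preprocess": PreprocessConfig,
            "tpedn": TPEDNConfig,
            "grid": GridConfig,
            "learners": fgecn.BaseLearnerConfig,
        }
        for key, val in raw.items():
            if key in sub:
                if key == "tpedn" and "modalities" in val:
                    val["modalities"] = tuple(Modality(m) for m in val["modalities"])
                for tkey in ("conv_channels", "image_size", "row_widths", "tap_dims"):
                    if tkey in val:
                        val[tkey] = tuple(val[tkey])
                kwargs[key] = sub[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = self.to_dict()
        d["tpedn"]["modalities"] = [m.value for m in self.tpedn.modalities]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _hash_config(obj) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        if isinstance(o, (np.integer, np.floating)):
            return float(o)
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    blob = json.dumps(obj, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


class _StopPipeline(Exception):
    """Raised internally to stop after the requested stage."""


class _StageRunner:
    def __init__(self, outdir: Path, manifest: dict, until: str | None = None):
        self.outdir = outdir
        self.manifest = manifest
        self.until = until

    def run(self, name: str, config_hash: str, fn):
        stage_dir = self.outdir / name
        marker = stage_dir / ".stage.json"
        cached = False
        if marker.exists():
            info = json.loads(marker.read_text())
            cached = info.get("hash") == config_hash
        if cached:
            self.manifest["stages"][name] = {"hash": config_hash, "cached": True}
        else:
            stage_dir.mkdir(parents=True, exist_ok=True)
            fn(stage_dir)
            marker.write_text(json.dumps({"hash": config_hash}))
            self.manifest["stages"][name] = {"hash": config_hash, "cached": False}
        if self.until == name:
            raise _StopPipeline
        return stage_dir


PIPELINE_STAGES = (
    "simulate", "preprocess", "transform", "pretrain", "finetune",
    "train_dc2ptn", "features", "emotions", "evaluate",
)


def run_pipeline(config: RunConfig, outdir: str | Path, until: str | None = None) -> dict:
    """Execute the staged workflow; returns the run manifest.

    Each stage's outputs are cached under a configuration hash; re-running
    with an unchanged configuration is a no-op, and changing a late stage's
    configuration reruns only that stage and its dependents.  ``until`` stops
    after the named stage (the per-stage CLI verbs are built on this).
    """
    if until is not None and until not in PIPELINE_STAGES:
        raise ConfigurationError(f"unknown stage {until!r}")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "config": config.to_dict()}
    manifest["config"]["tpedn"]["modalities"] = [m.value for m in config.tpedn.modalities]
    runner = _StageRunner(outdir, manifest, until=until)
    try:
        _execute_stages(config, outdir, runner)
    except _StopPipeline:
        pass
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _execute_stages(config: RunConfig, outdir: Path, runner: _StageRunner) -> None:
    state: dict = {}

    h_cohort = _hash_config(config.cohort)

    def simulate(d):
        cohort = synthetic.generate_cohort(config.cohort)
        synthetic.write_cohort(cohort, d / "cohort")

    runner.run("simulate", h_cohort, simulate)
    cohort = synthetic.read_cohort(outdir / "simulate" / "cohort")
    state["cohort"] = cohort

    h_pre = _hash_config([h_cohort, config.preprocess, config.grid.image_size,
                          config.n_scales, config.wpt_levels])

    def preprocess(d):
        processed, dropped = preprocess_cohort(cohort, config.preprocess)
        pd.DataFrame([vars(x) for x in dropped]).to_csv(d / "drop_report.csv", index=False)
        arrays = {}
        for rec in processed:
            for mod, sig in rec.signals.items():
                arrays[f"{rec.episode_id}::{mod.value}"] = sig.values
        np.savez_compressed(d / "signals.npz", **arrays)

    runner.run("preprocess", h_pre, preprocess)
    prepared = prepare_cohort(
        cohort,
        config.preprocess,
        image_size=config.grid.image_size,
        n_scales=config.n_scales,
        wpt_levels=config.wpt_levels,
    )
    state["prepared"] = prepared

    def transform(d):
        np.savez_compressed(
            d / "stacks.npz", **{eid: st for eid, st in prepared.stacks.items()}
        )
        (d / "channels.json").write_text(json.dumps(prepared.channel_names))

    runner.run("transform", h_pre, transform)

    # subject-independent holdout for the supervised stages
    rng = np.random.default_rng(config.seed)
    subjects = list(dict.fromkeys(r.subject_id for r in prepared.records))
    rng.shuffle(subjects)
    n_test = max(1, int(round(config.test_fraction * len(subjects))))
    test_subjects = set(subjects[:n_test])
    train = [r for r in prepared.records if r.subject_id not in test_subjects]
    test = [r for r in prepared.records if r.subject_id in test_subjects]

    tp_cfg = TPEDNConfig(**{**config.tpedn.__dict__, "seed": config.seed})
    h_ssl = _hash_config([h_pre, tp_cfg, config.ssl_epochs, sorted(test_subjects)])

    def pretrain(d):
        ssl_cfg = TPEDNConfig(**{**tp_cfg.__dict__, "epochs": config.ssl_epochs})
        model, history = tpedn.pretrain_ssl(train, ssl_cfg)
        tpedn.save_checkpoint(model, d / "tpedn_ssl.npz", history)
        pd.DataFrame(history).to_csv(d / "ssl_log.csv", index=False)

    runner.run("pretrain", h_ssl, pretrain)

    h_ft = _hash_config([h_ssl, config.finetune_epochs])

    def finetune(d):
        ssl_model = tpedn.load_checkpoint(outdir / "pretrain" / "tpedn_ssl.npz")
        model, history = tpedn.finetune_heads(
            train, tp_cfg, pretrained_state=ssl_model.state_dict(), epochs=config.finetune_epochs
        )
        tpedn.save_checkpoint(model, d / "tpedn.npz", history)
        pd.DataFrame(history).to_csv(d / "finetune_log.csv", index=False)

    runner.run("finetune", h_ft, finetune)
    tp_model = tpedn.load_checkpoint(outdir / "finetune" / "tpedn.npz")

    grid_cfg = GridConfig(**{**config.grid.__dict__, "tap_dims": tp_model.tap_dims,
                             "seed": config.seed})
    h_dc = _hash_config([h_ft, grid_cfg, config.dc2_epochs])

    def train_dc(d):
        xs = tpedn.signals_to_arrays(train, tp_model.config)
        p = tp_model.predict_proba(xs)
        probs = np.stack([p["depression"][:, 1], p["valence"][:, 1], p["arousal"][:, 1]], 1)
        taps = tp_model.encoder_taps(xs) if grid_cfg.use_fusion else None
        stacks = np.stack([prepared.stacks[r.episode_id] for r in train])
        model, history = dc2.train_dc2ptn(
            stacks, probs, taps, tpedn.task_labels(train), grid_cfg, epochs=config.dc2_epochs
        )
        dc2.save_checkpoint(model, d / "dc2ptn.npz", history)
        pd.DataFrame(history).to_csv(d / "dc2_log.csv", index=False)

    runner.run("train_dc2ptn", h_dc, train_dc)
    dc_model = dc2.load_checkpoint(outdir / "train_dc2ptn" / "dc2ptn.npz")

    h_feat = _hash_config([h_dc])

    def features(d):
        table = fgecn.build_feature_table(
            prepared.records, tp_model, dc_model, prepared.stacks, prepared.channel_names
        )
        table.to_csv(d / "features.csv")
        schema = {"label_column": fgecn.LABEL_COLUMN,
                  "columns": [c for c in table.columns]}
        (d / "features.schema.json").write_text(json.dumps(schema, indent=2))

    runner.run("features", h_feat, features)
    table = pd.read_csv(outdir / "features" / "features.csv", index_col=0)

    h_emo = _hash_config([h_feat, config.learners, sorted(test_subjects)])

    def emotions(d):
        train_ids = {r.episode_id for r in train}
        idx_train = np.array([i for i, eid in enumerate(table.index) if eid in train_ids])
        idx_test = np.array([i for i, eid in enumerate(table.index) if eid not in train_ids])
        X, y, feats = fgecn.split_xy(table)
        models, classes = fgecn.fit_base_learners(table, idx_train, config.learners)
        # weights from attributions on a held-in validation slice, never test
        val = idx_train[: max(8, len(idx_train) // 5)]
        atts = {n: fgecn.shap_attributions(n, m, X[val], feats) for n, m in models.items()}
        weights = fgecn.ensemble_weights(atts)
        probs = fgecn.ensemble_predict(models, weights, X[idx_test])
        enc = {c: i for i, c in enumerate(classes)}
        pred = classes[np.argmax(probs, axis=1)]
        truth = y[idx_test]
        result = {
            "weights": weights.weights,
            "macro_f1": evalcv.macro_f1(truth, pred),
            "accuracy": float((pred == truth).mean()),
            "n_test": int(idx_test.size),
            "per_model_accuracy": {
                n: float(
                    (classes[np.argmax(p, axis=1)] == truth).mean()
                )
                for n, p in fgecn.predict_proba(models, X[idx_test]).items()
            },
        }
        (d / "emotions.json").write_text(json.dumps(result, indent=2))

    runner.run("emotions", h_emo, emotions)

    h_eval = _hash_config([h_emo])

    def evaluate(d):
        xs = tpedn.signals_to_arrays(test, tp_model.config)
        p = tp_model.predict_proba(xs)
        probs = np.stack([p["depression"][:, 1], p["valence"][:, 1], p["arousal"][:, 1]], 1)
        taps = tp_model.encoder_taps(xs) if dc_model.config.use_fusion else None
        stacks = np.stack([prepared.stacks[r.episode_id] for r in test])
        dsq = dc_model.predict_scores(stacks, probs, taps)
        rows = []
        for t_i, task in enumerate(evalcv.TASKS):
            truth = np.array([getattr(r.labels, task) for r in test])
            for source, mat in (("tpedn", probs), ("dsq", dsq)):
                pred = (mat[:, t_i] >= 0.5).astype(int)
                mv = evalcv.metrics(evalcv.confusion_counts(truth, pred, 1))
                rows.append(
                    {"task": task, "source": source, "accuracy": mv.accuracy,
                     "sensitivity": mv.sensitivity, "specificity": mv.specificity,
                     "f1": mv.f1, "n": len(test)}
                )
        pd.DataFrame(rows).to_csv(d / "affect_metrics.csv", index=False)

    runner.run("evaluate", h_eval, evaluate)


def report(outdir: str | Path) -> str:
    """Human-readable summary of a completed run (no recomputation)."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    lines = [f"run at {outdir} (seed {manifest['seed']})", ""]
    lines.append("stages: " + ", ".join(
        f"{n}{' [cached]' if s.get('cached') else ''}" for n, s in manifest["stages"].items()
    ))
    metrics_path = outdir / "evaluate" / "affect_metrics.csv"
    if metrics_path.exists():
        df = pd.read_csv(metrics_path)
        lines.append("\naffect classification (held-out subjects):")
        for _, row in df.iterrows():
            lines.append(
                f"  {row['task']:<11} {row['source']:<6} acc {100 * row['accuracy']:5.1f}%  "
                f"sens {100 * row['sensitivity']:5.1f}%  spec {100 * row['specificity']:5.1f}%  "
                f"F1 {100 * row['f1']:5.1f}%"
            )
    else:
        lines.append("\n(affect metrics missing: partial run)")
    emo_path = outdir / "emotions" / "emotions.json"
    if emo_path.exists():
        emo = json.loads(emo_path.read_text())
        lines.append("\nfine-grained emotion ensemble (held-out subjects):")
        lines.append(f"  macro-F1 {100 * emo['macro_f1']:5.1f}%  accuracy {100 * emo['accuracy']:5.1f}%")
        w = ", ".join(f"{k}={v:.3f}" for k, v in emo["weights"].items())
        lines.append(f"  attribution ensemble weights: {w}")
    else:
        lines.append("\n(emotion results missing: partial run)")
    return "\n".join(lines)
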