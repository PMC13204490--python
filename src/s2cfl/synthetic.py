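"""Synthetic wearable-affect cohort generator.

Generates cohorts that mimic the structure of ambulatory wearable recordings
paired with experience-sampling affect reports: per-episode HR / GSR / triaxial
ACC streams at their native rates over 30-minute windows, binary
depression/valence/arousal labels, a 10-class emotion category, and a noisy
self-report vector.  Labels are generated first and signals are conditioned on
them, so planted effects can be recovered by direct group statistics:

- high-arousal episodes carry an additive heart-rate baseline shift (and a
  proportionally faster/larger slow HR oscillation, so the effect is not a pure
  affine transform that per-episode z-scoring would erase);
- high-depression episodes carry an elevated phasic skin-conductance response
  rate;
- low-valence episodes carry damped accelerometer activity bouts.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning, so identical configurations yield bit-identical cohorts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import InvalidArgumentError, InvalidConfigError, UnsupportedModalityError
from .types import (
    EMOTION_VA_CENTROIDS,
    EMOTIONS,
    Cohort,
    CohortConfig,
    EpisodeRecord,
    LabelSet,
    Modality,
    ModalitySignal,
)

# Physiological baselines (units: HR bpm, GSR microsiemens, ACC g).
HR_BASELINE_BPM = 68.0
HR_OSC_AMP_BPM = 5.0
HR_AR_PHI = 0.9
HR_AR_SD = 2.5
GSR_TONIC_LEVEL = 4.0
GSR_BURST_RATE_PER_MIN = 1.2
GSR_SCR_MEAN_AMP = 0.3
GSR_NOISE_SD = 0.02
ACC_BOUT_RATE_PER_MIN = 1.0
ACC_BOUT_MEAN_DUR_S = 8.0
ACC_NOISE_FLOOR = 0.008
#: fraction of a corrupted signal's samples replaced by missing markers
CORRUPTION_SEGMENT_FRACTION = 0.05

#: the "strongly separable" study condition: pronounced affective responses
#: (~1.5x the default effect sizes), used by the supervised-separability
#: experiments.  hr shift in bpm; the others are dimensionless multipliers.
STRONG_EFFECT_SIZES = {
    "hr_arousal_shift": 12.0,
    "gsr_stress_rate": 2.0,
    "acc_valence_damping": 0.8,
}

_SCORE_NOISE_SD = 0.12
_SELF_REPORT_NOISE_SD = 0.15


def _ar1(rng: np.random.Generator, n: int, phi: float, stationary_sd: float) -> np.ndarray:
    innov_sd = stationary_sd * np.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, innov_sd, size=n)
    out = np.empty(n)
    prev = rng.normal(0.0, stationary_sd)
    for i in range(n):
        prev = phi * prev + eps[i]
        out[i] = prev
    return out


def _hr_kernel(rng: np.random.Generator, n: int, rate: float, fx: dict) -> np.ndarray:
    t = np.arange(n) / rate
    baseline = fx.get("baseline", HR_BASELINE_BPM) + fx.get("shift", 0.0)
    period = fx.get("osc_period_s", float(rng.uniform(600.0, 1200.0)))
    period /= max(fx.get("tempo", 1.0), 1e-6)
    amp = fx.get("osc_amp", HR_OSC_AMP_BPM)
    phase = fx.get("osc_phase", float(rng.uniform(0.0, 2.0 * np.pi)))
    drift = amp * np.sin(2.0 * np.pi * t / period + phase)
    noise = _ar1(rng, n, HR_AR_PHI, fx.get("ar_sd", HR_AR_SD))
    return baseline + drift + noise


def _scr_shape(t: np.ndarray, rise_s: float = 1.2, decay_s: float = 6.0) -> np.ndarray:
    """Canonical skin-conductance response: bi-exponential, peak-normalized."""
    shape = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = shape.max()
    return shape / peak if peak > 0 else shape


def _gsr_kernel(rng: np.random.Generator, n: int, rate: float, fx: dict) -> np.ndarray:
    t = np.arange(n) / rate
    duration = n / rate
    level = fx.get("tonic_level", GSR_TONIC_LEVEL)
    p1 = float(rng.uniform(400.0, 900.0))
    p2 = float(rng.uniform(120.0, 300.0))
    tonic = (
        level
        + 0.7 * np.sin(2.0 * np.pi * t / p1 + rng.uniform(0, 2 * np.pi))
        + 0.4 * np.sin(2.0 * np.pi * t / p2 + rng.uniform(0, 2 * np.pi))
    )
    out = tonic + rng.normal(0.0, GSR_NOISE_SD, size=n)
    burst_rate = fx.get("burst_rate_per_min", GSR_BURST_RATE_PER_MIN)
    n_events = rng.poisson(burst_rate * duration / 60.0)
    if n_events > 0:
        onsets = np.sort(rng.uniform(0.0, duration, size=n_events))
        support = np.arange(int(30.0 * rate)) / rate  # 30 s SCR support
        shape = _scr_shape(support)
        for onset in onsets:
            amp = rng.exponential(GSR_SCR_MEAN_AMP)
            i0 = int(round(onset * rate))
            seg = min(len(shape), n - i0)
            if seg > 0:
                out[i0 : i0 + seg] += amp * shape[:seg]
    return out


def _acc_kernel(rng: np.random.Generator, n: int, rate: float, fx: dict) -> np.ndarray:
    duration = n / rate
    gravity = np.array([0.02, -0.01, 0.98])
    out = gravity[None, :] + rng.normal(0.0, ACC_NOISE_FLOOR, size=(n, 3))
    bout_rate = fx.get("bout_rate_per_min", ACC_BOUT_RATE_PER_MIN)
    bout_scale = np.sqrt(max(fx.get("bout_var_scale", 1.0), 0.0))
    n_bouts = rng.poisson(bout_rate * duration / 60.0)
    chan_gain = np.array([0.9, 1.0, 1.1])
    for _ in range(n_bouts):
        start = rng.uniform(0.0, duration)
        dur = max(2.0, rng.exponential(ACC_BOUT_MEAN_DUR_S))
        i0 = int(start * rate)
        i1 = min(n, int((start + dur) * rate))
        m = i1 - i0
        if m <= 4:
            continue
        amp = rng.uniform(0.15, 0.35) * bout_scale
        burst = rng.normal(0.0, 1.0, size=(m, 3))
        # light smoothing -> band-limited movement noise
        burst = (burst + np.roll(burst, 1, axis=0) + np.roll(burst, -1, axis=0)) / 3.0
        envelope = np.sin(np.pi * np.arange(m) / m)[:, None]
        out[i0:i1] += amp * burst * envelope * chan_gain[None, :]
    return out


def _ppg_kernel(rng: np.random.Generator, n: int, rate: float, fx: dict) -> np.ndarray:
    bpm = fx.get("bpm", 60.0)
    amp = fx.get("pulse_amp", 1.0)
    duration = n / rate
    t = np.arange(n) / rate
    beat_interval = 60.0 / float(bpm)
    beats = np.arange(beat_interval / 2.0, duration, beat_interval)
    out = rng.normal(0.0, fx.get("noise_sd", 0.05), size=n)
    width = 0.12  # s, Gaussian pulse width
    for b in beats:
        lo = max(0, int((b - 4 * width) * rate))
        hi = min(n, int((b + 4 * width) * rate) + 1)
        out[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - b) / width) ** 2)
    return out


_KERNELS = {
    Modality.HR: (_hr_kernel, 1),
    Modality.GSR: (_gsr_kernel, 1),
    Modality.ACC: (_acc_kernel, 3),
    Modality.PPG: (_ppg_kernel, 1),
}


def generate_modality_signal(
    modality: Modality,
    duration_s: float,
    label_effects: dict | None = None,
    seed: int | np.random.SeedSequence = 0,
    rate: float | None = None,
) -> ModalitySignal:
    """Generate one synthetic modality stream.

    ``label_effects`` carries the per-episode conditioning (baseline shift,
    burst rate, bout variance scale, ...); unknown keys are ignored by kernels
    that do not use them.
    """
    try:
        modality = Modality(modality)
    except ValueError as exc:
        raise UnsupportedModalityError(f"no kernel for modality {modality!r}") from exc
    if modality not in _KERNELS:
        raise UnsupportedModalityError(f"no kernel for modality {modality}")
    if duration_s <= 0:
        raise InvalidConfigError("duration_s must be positive")
    if rate is None:
        rate = {Modality.HR: 1.0, Modality.GSR: 40.0, Modality.ACC: 20.0, Modality.PPG: 20.0}[
            modality
        ]
    rng = np.random.default_rng(seed)
    n = int(round(rate * duration_s))
    kernel, _ = _KERNELS[modality]
    values = kernel(rng, n, rate, dict(label_effects or {}))
    return ModalitySignal(modality=modality, rate=rate, values=values)


def inject_missing_segments(
    signal: ModalitySignal, fraction: float, seed: int | np.random.SeedSequence = 0
) -> ModalitySignal:
    """Replace contiguous runs totaling ``fraction`` of samples with NaN.

    Runs are placed without overlap at seeded positions; the total count of
    missing samples is exact up to rounding.
    """
    if not 0.0 <= fraction <= 1.0:
        raise InvalidArgumentError(f"fraction must lie in [0, 1], got {fraction}")
    out = signal.copy()
    n = out.n_samples
    target = int(round(fraction * n))
    if target == 0:
        return out
    if target >= n:
        out.values[...] = np.nan
        return out
    rng = np.random.default_rng(seed)
    mean_run = max(5, n // 40)
    n_runs = max(1, int(round(target / mean_run)))
    # split target into run lengths, then place runs separated by random gaps
    lengths = rng.multinomial(target - n_runs, np.full(n_runs, 1.0 / n_runs)) + 1
    free = n - target
    gaps = rng.multinomial(free, np.full(n_runs + 1, 1.0 / (n_runs + 1)))
    pos = 0
    for k in range(n_runs):
        pos += gaps[k]
        out.values[pos : pos + lengths[k]] = np.nan
        pos += lengths[k]
    return out


def _episode_labels(rng: np.random.Generator, subject_propensity: float, weights: np.ndarray):
    emotion = EMOTIONS[rng.choice(len(EMOTIONS), p=weights)]
    cv, ca = EMOTION_VA_CENTROIDS[emotion]
    v = cv + rng.normal(0.0, _SCORE_NOISE_SD)
    a = ca + rng.normal(0.0, _SCORE_NOISE_SD)
    d = 0.6 * subject_propensity - 0.25 * v + 0.3 * rng.normal() - 0.25
    raw = np.array([v, a, d])
    return LabelSet(
        depression=int(d > 0),
        valence=int(v > 0),
        arousal=int(a > 0),
        emotion=emotion,
        raw_scores=raw,
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort of subject-episodes under ``config``.

    Deterministic given ``config`` (including its seed).  The returned
    :class:`~s2cfl.types.Cohort` behaves as a sequence of EpisodeRecord and
    carries a manifest listing the configuration and the episodes corrupted
    with missing segments.
    """
    root = np.random.SeedSequence(config.seed)
    cohort_ss, report_ss, corrupt_ss, *subject_ss = root.spawn(3 + config.n_subjects)
    cohort_rng = np.random.default_rng(cohort_ss)
    corrupt_rng = np.random.default_rng(corrupt_ss)

    weights = np.asarray(config.emotion_weights, dtype=float)
    weights = weights / weights.sum()
    # random linear readout of the one-hot emotion class into the self-report
    n_proj = max(0, config.self_report_dim - 3)
    report_proj = np.random.default_rng(report_ss).normal(0.0, 0.8, size=(len(EMOTIONS), n_proj))

    fx = config.effect_sizes
    hr_shift = fx.get("hr_arousal_shift", 0.0)
    gsr_rate_gain = fx.get("gsr_stress_rate", 0.0)
    acc_damp = fx.get("acc_valence_damping", 0.0)

    records: list[EpisodeRecord] = []
    corrupted: list[dict] = []
    for si, sseq in enumerate(subject_ss):
        subject_id = f"s{si:03d}"
        srng = np.random.default_rng(sseq)
        propensity = float(srng.normal())
        hr_base = HR_BASELINE_BPM + float(srng.normal(0.0, 2.0))
        gsr_level = GSR_TONIC_LEVEL + float(srng.normal(0.0, 0.8))
        episode_ss = sseq.spawn(config.episodes_per_subject)
        for ei, eseq in enumerate(episode_ss):
            label_rng = np.random.default_rng(eseq)
            labels = _episode_labels(label_rng, propensity, weights)

            hr_fx = {"baseline": hr_base}
            if labels.arousal == 1:
                hr_fx["shift"] = hr_shift
                # scale-free companions of the baseline shift (see module docs)
                hr_fx["osc_amp"] = HR_OSC_AMP_BPM * (1.0 + 0.05 * hr_shift)
                hr_fx["tempo"] = 1.0 + 0.06 * hr_shift
            gsr_fx = {"tonic_level": gsr_level}
            if labels.depression == 1:
                gsr_fx["burst_rate_per_min"] = GSR_BURST_RATE_PER_MIN * (1.0 + gsr_rate_gain)
            acc_fx = {}
            if labels.valence == 0:
                acc_fx["bout_var_scale"] = 1.0 - acc_damp

            hr_ss, gsr_ss, acc_ss = eseq.spawn(3)
            signals = {
                Modality.HR: generate_modality_signal(
                    Modality.HR, config.duration_s, hr_fx, hr_ss, rate=config.hr_rate
                ),
                Modality.GSR: generate_modality_signal(
                    Modality.GSR, config.duration_s, gsr_fx, gsr_ss, rate=config.gsr_rate
                ),
                Modality.ACC: generate_modality_signal(
                    Modality.ACC, config.duration_s, acc_fx, acc_ss, rate=config.acc_rate
                ),
            }

            onehot = np.zeros(len(EMOTIONS))
            onehot[EMOTIONS.index(labels.emotion)] = 1.0
            report = np.concatenate([labels.raw_scores, onehot @ report_proj])
            report = report + label_rng.normal(0.0, _SELF_REPORT_NOISE_SD, size=report.shape)

            episode_id = f"{subject_id}-e{ei:03d}"
            if config.missing_fraction > 0 and corrupt_rng.random() < config.missing_fraction:
                mod = [Modality.HR, Modality.GSR, Modality.ACC][corrupt_rng.integers(3)]
                signals[mod] = inject_missing_segments(
                    signals[mod], CORRUPTION_SEGMENT_FRACTION, corrupt_rng.integers(2**31)
                )
                corrupted.append({"episode_id": episode_id, "modality": mod.value})

            records.append(
                EpisodeRecord(
                    subject_id=subject_id,
                    episode_id=episode_id,
                    signals=signals,
                    labels=labels,
                    self_report=report,
                )
            )

    manifest = {
        "config": config_to_dict(config),
        "corrupted_episodes": corrupted,
        "n_records": len(records),
    }
    return Cohort(records, manifest)


def config_to_dict(config: CohortConfig) -> dict:
    return {
        "n_subjects": config.n_subjects,
        "episodes_per_subject": config.episodes_per_subject,
        "duration_s": config.duration_s,
        "effect_sizes": dict(config.effect_sizes),
        "missing_fraction": config.missing_fraction,
        "seed": config.seed,
        "emotion_weights": list(config.emotion_weights),
        "hr_rate": config.hr_rate,
        "gsr_rate": config.gsr_rate,
        "acc_rate": config.acc_rate,
        "self_report_dim": config.self_report_dim,
    }


# ---------------------------------------------------------------------------
# Planted-effect recovery statistics (direct computations on raw arrays).


def hr_arousal_mean_difference(cohort) -> float:
    """Mean raw HR of high-arousal episodes minus low-arousal episodes (bpm)."""
    hi = [r.signals[Modality.HR].values.mean() for r in cohort if r.labels.arousal == 1]
    lo = [r.signals[Modality.HR].values.mean() for r in cohort if r.labels.arousal == 0]
    return float(np.mean(hi) - np.mean(lo))


def acc_valence_variance_ratio(cohort) -> float:
    """Mean dynamic ACC variance of low-valence episodes over high-valence ones."""

    def dyn_var(rec):
        v = rec.signals[Modality.ACC].values
        return float(np.mean(np.var(v, axis=0)))

    lo = [dyn_var(r) for r in cohort if r.labels.valence == 0]
    hi = [dyn_var(r) for r in cohort if r.labels.valence == 1]
    return float(np.mean(lo) / np.mean(hi))


#: effective dead time of the SCR rise detector (refractory + rise collision)
SCR_DETECTOR_DEAD_TIME_S = 2.0


def detect_scr_peaks(sig: ModalitySignal, slope_threshold: float = 0.03) -> int:
    """Count phasic skin-conductance responses in one GSR stream.

    Counts steep-rise onsets: upcrossings of the tonic-detrended slope
    (estimated over a 0.5 s span on the 1 s-smoothed signal) above
    ``slope_threshold`` uS/s.  SCR rising edges are much steeper than both the
    tonic drift and other SCRs' decay tails, so rise counting stays nearly
    unbiased when responses overlap at high rates, where peak-prominence
    counting merges events.
    """
    from scipy.ndimage import median_filter, uniform_filter1d

    x = uniform_filter1d(sig.values, max(1, int(sig.rate)))
    k = max(1, int(0.25 * sig.rate))
    dx = (x[2 * k :] - x[: -2 * k]) * (sig.rate / (2.0 * k))
    dx = dx - median_filter(dx, max(1, int(30 * sig.rate)), mode="nearest")
    above = dx > slope_threshold
    onsets = np.flatnonzero(above[1:] & ~above[:-1])
    if onsets.size == 0:
        return 0
    keep = np.concatenate([[True], np.diff(onsets) > 0.75 * sig.rate])
    return int(keep.sum())


def scr_rate_per_s(sig: ModalitySignal) -> float:
    """Dead-time-corrected SCR rate: r = m / (1 - m * tau).

    The standard non-paralyzable dead-time correction compensates the
    detector's event merging, which would otherwise bias high-rate episodes
    downward relative to low-rate ones.
    """
    m = detect_scr_peaks(sig) / sig.duration_s
    return m / max(1e-9, 1.0 - m * SCR_DETECTOR_DEAD_TIME_S)


def gsr_depression_peak_rate_ratio(cohort) -> float:
    """Detected phasic SCR rate of high-depression over low-depression episodes."""
    hi = [scr_rate_per_s(r.signals[Modality.GSR]) for r in cohort if r.labels.depression == 1]
    lo = [scr_rate_per_s(r.signals[Modality.GSR]) for r in cohort if r.labels.depression == 0]
    return float(np.mean(hi) / np.mean(lo))


# ---------------------------------------------------------------------------
# On-disk layout: one CSV per modality per episode + labels CSV + manifest.


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    label_rows = []
    for rec in cohort:
        epdir = outdir / rec.episode_id
        epdir.mkdir(exist_ok=True)
        for mod, sig in rec.signals.items():
            t = sig.t0 + np.arange(sig.n_samples) / sig.rate
            if mod is Modality.ACC:
                df = pd.DataFrame(
                    {"t": t, "value": sig.values[:, 0], "y": sig.values[:, 1], "z": sig.values[:, 2]}
                )
            else:
                df = pd.DataFrame({"t": t, "value": sig.values})
            df.to_csv(epdir / f"{mod.value.lower()}.csv", index=False)
        row = {
            "subject_id": rec.subject_id,
            "episode_id": rec.episode_id,
            "depression": rec.labels.depression,
            "valence": rec.labels.valence,
            "arousal": rec.labels.arousal,
            "emotion": rec.labels.emotion,
        }
        for k, v in enumerate(rec.labels.raw_scores):
            row[f"raw_score_{k}"] = v
        if rec.self_report is not None:
            for k, v in enumerate(rec.self_report):
                row[f"self_report_{k}"] = v
        label_rows.append(row)
    pd.DataFrame(label_rows).to_csv(outdir / "labels.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(cohort.manifest, fh, indent=2)
    return outdir


def read_cohort(indir: str | Path) -> Cohort:
    import pandas as pd

    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    labels = pd.read_csv(indir / "labels.csv")
    rates = {
        Modality.HR: manifest["config"]["hr_rate"],
        Modality.GSR: manifest["config"]["gsr_rate"],
        Modality.ACC: manifest["config"]["acc_rate"],
    }
    records = []
    for _, row in labels.iterrows():
        epdir = indir / row["episode_id"]
        signals = {}
        for mod in (Modality.HR, Modality.GSR, Modality.ACC):
            df = pd.read_csv(epdir / f"{mod.value.lower()}.csv")
            if mod is Modality.ACC:
                values = df[["value", "y", "z"]].to_numpy()
            else:
                values = df["value"].to_numpy()
            signals[mod] = ModalitySignal(mod, rates[mod], values, t0=float(df["t"].iloc[0]))
        raw_cols = sorted(c for c in labels.columns if c.startswith("raw_score_"))
        sr_cols = sorted(
            (c for c in labels.columns if c.startswith("self_report_")),
            key=lambda c: int(c.rsplit("_", 1)[1]),
        )
        records.append(
            EpisodeRecord(
                subject_id=row["subject_id"],
                episode_id=row["episode_id"],
                signals=signals,
                labels=LabelSet(
                    depression=int(row["depression"]),
                    valence=int(row["valence"]),
                    arousal=int(row["arousal"]),
                    emotion=row["emotion"],
                    raw_scores=row[raw_cols].to_numpy(dtype=float),
                ),
                self_report=row[sr_cols].to_numpy(dtype=float) if sr_cols else None,
            )
        )
    return Cohort(records, manifest)
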