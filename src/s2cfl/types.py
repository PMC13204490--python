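"""Core domain types: signals, labels, episodes, cohort configuration.

A cohort is a collection of subject-episodes.  Each episode carries three
aligned wearable modality streams (heart rate, galvanic skin response,
triaxial accelerometry) over one nominal 30-minute window anchored at an
experience-sampling questionnaire, plus binary affect labels (depression,
valence, arousal), a 10-class fine-grained emotion category and an optional
self-report feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import InvalidConfigError


class Modality(str, Enum):
    HR = "HR"
    GSR = "GSR"
    ACC = "ACC"
    PPG = "PPG"


#: The 10 fine-grained emotion categories (PANAS-derived item set).
EMOTIONS: tuple[str, ...] = (
    "upset",
    "hostile",
    "alert",
    "ashamed",
    "inspired",
    "nervous",
    "determined",
    "attentive",
    "afraid",
    "active",
)

#: Emotion centroids in the valence-arousal plane, in [-1, 1]^2.  The binary
#: valence/arousal labels of an episode are the signs of its (noisy) continuous
#: scores drawn around the centroid of its emotion class.
EMOTION_VA_CENTROIDS: dict[str, tuple[float, float]] = {
    "upset": (-0.55, 0.30),
    "hostile": (-0.70, 0.65),
    "alert": (0.30, 0.55),
    "ashamed": (-0.50, -0.40),
    "inspired": (0.65, 0.45),
    "nervous": (-0.40, 0.70),
    "determined": (0.55, -0.25),
    "attentive": (0.40, -0.45),
    "afraid": (-0.65, 0.80),
    "active": (0.60, 0.75),
}


@dataclass
class ModalitySignal:
    """One modality stream of one episode.

    ``values`` has shape ``(n,)`` for single-channel modalities and ``(n, 3)``
    for triaxial ACC.  Missing samples are NaN sentinels, so the nominal
    duration bookkeeping stays intact even for gappy signals.
    """

    modality: Modality
    rate: float
    values: np.ndarray
    t0: float = 0.0
    short: bool = False  # set when an extracted window is shorter than requested

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise InvalidConfigError(f"sampling rate must be positive, got {self.rate}")
        if self.modality is Modality.ACC:
            # raw ACC is triaxial; a derived vector-magnitude stream is 1-D
            if self.values.ndim == 2 and self.values.shape[1] != 3:
                raise InvalidConfigError("triaxial ACC signals must have shape (n, 3)")
            if self.values.ndim > 2:
                raise InvalidConfigError("ACC signals must be (n,) magnitude or (n, 3)")
        else:
            if self.values.ndim != 1:
                raise InvalidConfigError(
                    f"{self.modality.value} signals must be 1-D, got shape {self.values.shape}"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    @property
    def n_channels(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[1]

    def missing_fraction(self) -> float:
        flat = np.isnan(self.values)
        if flat.ndim == 2:  # a sample is missing if any channel is missing
            flat = flat.any(axis=1)
        return float(flat.mean()) if flat.size else 0.0

    def copy(self) -> "ModalitySignal":
        return ModalitySignal(self.modality, self.rate, self.values.copy(), self.t0, self.short)


@dataclass
class LabelSet:
    """Binary affect labels plus the fine-grained emotion category.

    ``raw_scores`` holds the continuous (valence, arousal, depression) scores
    the binaries were thresholded from: valence/arousal binaries are the signs
    of the first two scores, depression is ``score > 0``.
    """

    depression: int
    valence: int
    arousal: int
    emotion: str
    raw_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.emotion not in EMOTIONS:
            raise InvalidConfigError(f"unknown emotion category {self.emotion!r}")
        for name in ("depression", "valence", "arousal"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise InvalidConfigError(f"{name} label must be 0 (low) or 1 (high), got {v}")
        if self.raw_scores is not None:
            self.raw_scores = np.asarray(self.raw_scores, dtype=float)
            derived = derive_binaries(self.raw_scores)
            if (self.valence, self.arousal, self.depression) != derived:
                raise InvalidConfigError("binary labels inconsistent with raw_scores")


def derive_binaries(raw_scores: np.ndarray) -> tuple[int, int, int]:
    """(valence, arousal, depression) binaries from continuous scores."""
    v, a, d = (float(x) for x in raw_scores[:3])
    return int(v > 0), int(a > 0), int(d > 0)


@dataclass
class EpisodeRecord:
    """One subject-episode: aligned modality signals plus labels."""

    subject_id: str
    episode_id: str
    signals: dict[Modality, ModalitySignal]
    labels: LabelSet
    self_report: np.ndarray | None = None

    def duration_s(self) -> float:
        return max(sig.duration_s for sig in self.signals.values())


@dataclass
class CohortConfig:
    """Study-condition knobs for the synthetic cohort generator.

    ``effect_sizes`` plants the label-dependent physiological structure:

    - ``hr_arousal_shift``: baseline heart-rate elevation (bpm) of high-arousal
      episodes; also scales the relative amplitude/tempo of the slow HR
      oscillation so the effect survives per-episode z-scoring.
    - ``gsr_stress_rate``: multiplicative increase of the phasic skin
      conductance response rate for high-depression episodes
      (rate_high = rate_base * (1 + gsr_stress_rate)).
    - ``acc_valence_damping``: fraction in [0, 1) by which the activity-bout
      variance of low-valence episodes is reduced.
    """

    n_subjects: int = 30
    episodes_per_subject: int = 10
    duration_s: float = 1800.0
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: {
            "hr_arousal_shift": 8.0,
            "gsr_stress_rate": 1.5,
            "acc_valence_damping": 0.6,
        }
    )
    missing_fraction: float = 0.0
    seed: int = 0
    emotion_weights: Sequence[float] = (1.2, 0.8, 1.0, 0.9, 1.1, 1.0, 1.0, 1.1, 0.7, 1.2)
    hr_rate: float = 1.0
    gsr_rate: float = 40.0
    acc_rate: float = 20.0
    self_report_dim: int = 8

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.episodes_per_subject <= 0:
            raise InvalidConfigError("subject and episode counts must be positive")
        if self.duration_s <= 0:
            raise InvalidConfigError("duration_s must be positive")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise InvalidConfigError("missing_fraction must lie in [0, 1]")
        for key, val in self.effect_sizes.items():
            if val < 0:
                raise InvalidConfigError(f"effect size {key} must be nonnegative, got {val}")
        if len(self.emotion_weights) != len(EMOTIONS):
            raise InvalidConfigError("emotion_weights must have one entry per emotion class")


class Cohort(Sequence):
    """A generated cohort: a sequence of EpisodeRecord plus a manifest.

    The manifest records the generating configuration and which episodes were
    corrupted with missing segments, so downstream filtering can be checked
    against ground truth rather than against the filter itself.
    """

    def __init__(self, records: list[EpisodeRecord], manifest: Mapping):
        self.records = records
        self.manifest = dict(manifest)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, idx):
        return self.records[idx]

    def __iter__(self) -> Iterator[EpisodeRecord]:
        return iter(self.records)
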