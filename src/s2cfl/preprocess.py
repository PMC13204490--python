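"""Signal conditioning: RMS down-sampling, z-scoring, windowing, episode filter.

The conditioning chain mirrors standard ambulatory-wearable practice: raw
streams are RMS-pooled on a sliding 10 s window evaluated at 1 Hz (triaxial
ACC is first collapsed to its vector magnitude), z-scored per episode and per
channel with population sigma (normalization is a per-device amplitude fix, so
no cross-episode state is used), cut to the 30 minutes preceding each
experience-sampling prompt, and episodes that are short or contain missing
segments are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    DegenerateSignalError,
    EmptyWindowError,
    InvalidConfigError,
    MissingDataError,
)
from .types import EpisodeRecord, Modality, ModalitySignal


@dataclass
class PreprocessConfig:
    window_s: float = 10.0  # RMS pooling window
    target_rate: float = 1.0  # output rate
    min_duration_s: float = 1800.0  # exclusion threshold for short episodes
    max_missing_fraction: float = 0.0  # any gap drops the episode by default

    def __post_init__(self) -> None:
        if self.target_rate <= 0 or self.window_s < 1.0 / self.target_rate:
            raise InvalidConfigError("window_s must cover at least one output interval")
        if self.min_duration_s <= 0:
            raise InvalidConfigError("min_duration_s must be positive")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise InvalidConfigError("max_missing_fraction must lie in [0, 1]")


def acc_magnitude(signal: ModalitySignal) -> ModalitySignal:
    """Collapse triaxial ACC to the per-sample vector magnitude."""
    if signal.values.ndim != 2:
        return signal.copy()
    mag = np.sqrt(np.sum(signal.values**2, axis=1))
    return ModalitySignal(signal.modality, signal.rate, mag, signal.t0, signal.short)


def rms_downsample(signal: ModalitySignal, config: PreprocessConfig | None = None) -> ModalitySignal:
    """RMS-pool a signal onto the target rate with a centred sliding window.

    Output sample k is the RMS of the raw samples within ``window_s`` centred
    at time ``k / target_rate`` (edge windows truncated).  A 10 s window
    evaluated at 1 Hz therefore overlaps its neighbours by 9 s.  ACC is
    collapsed to its vector magnitude before pooling.  Windows containing
    missing samples raise :class:`MissingDataError` with the window index.
    """
    config = config or PreprocessConfig()
    if signal.rate < config.target_rate:
        raise InvalidConfigError(
            f"signal rate {signal.rate} Hz below target rate {config.target_rate} Hz"
        )
    if signal.modality is Modality.ACC and signal.values.ndim == 2:
        signal = acc_magnitude(signal)
    x = signal.values
    n = x.shape[0]
    n_out = int(round(n / signal.rate * config.target_rate))
    half = config.window_s / 2.0
    sq = x * x
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    nan_flags = np.isnan(x)
    nan_csum = np.concatenate([[0], np.cumsum(nan_flags)])
    out = np.empty(n_out)
    for k in range(n_out):
        tc = k / config.target_rate
        lo = max(0, int(np.ceil((tc - half) * signal.rate)))
        hi = min(n, int(np.floor((tc + half) * signal.rate)) + 1)
        if hi <= lo:
            raise InvalidConfigError("empty RMS window; window_s too small for rate")
        if nan_csum[hi] - nan_csum[lo] > 0:
            raise MissingDataError(f"missing samples in RMS window {k}", window_index=k)
        out[k] = np.sqrt((csum[hi] - csum[lo]) / (hi - lo))
    return ModalitySignal(signal.modality, config.target_rate, out, signal.t0, signal.short)


def zscore(signal: ModalitySignal) -> ModalitySignal:
    """Per-episode, per-channel standardization with population sigma."""
    x = signal.values
    if x.shape[0] < 2:
        raise DegenerateSignalError("need at least 2 samples to z-score")
    mean = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0)  # population sigma
    if np.any(sd == 0) or np.any(~np.isfinite(sd)):
        raise DegenerateSignalError("zero-variance channel cannot be z-scored")
    return ModalitySignal(signal.modality, signal.rate, (x - mean) / sd, signal.t0, signal.short)


def extract_episode_window(
    stream: ModalitySignal, event_time_s: float, span_s: float = 1800.0
) -> ModalitySignal:
    """Return the ``span_s`` seconds ending at ``event_time_s``.

    When less history is available the shorter window is returned with its
    ``short`` flag set, so it can be excluded later by :func:`filter_episodes`.
    """
    start = event_time_s - span_s
    stream_end = stream.t0 + stream.duration_s
    if event_time_s <= stream.t0:
        raise EmptyWindowError("event precedes the stream start")
    if event_time_s > stream_end + 1e-9:
        raise EmptyWindowError("event lies beyond the stream extent")
    lo = max(0, int(np.ceil((start - stream.t0) * stream.rate)))
    hi = int(round((event_time_s - stream.t0) * stream.rate))
    values = stream.values[lo:hi]
    expected = int(round(span_s * stream.rate))
    return ModalitySignal(
        stream.modality,
        stream.rate,
        values,
        t0=stream.t0 + lo / stream.rate,
        short=values.shape[0] < expected,
    )


@dataclass
class DropRecord:
    episode_id: str
    subject_id: str
    reason: str  # "short:<modality>" or "missing:<modality>"


def filter_episodes(
    records, config: PreprocessConfig | None = None
) -> tuple[list[EpisodeRecord], list[DropRecord]]:
    """Partition episodes into kept and dropped (with machine-readable reasons).

    An episode is dropped iff any modality window is shorter than
    ``min_duration_s`` or has a missing-sample fraction above
    ``max_missing_fraction``.  Filtering the kept set again drops nothing.
    """
    config = config or PreprocessConfig()
    kept: list[EpisodeRecord] = []
    dropped: list[DropRecord] = []
    for rec in records:
        reason = None
        for mod, sig in rec.signals.items():
            if sig.duration_s < config.min_duration_s - 1e-9 or sig.short:
                reason = f"short:{mod.value}"
                break
            if sig.missing_fraction() > config.max_missing_fraction:
                reason = f"missing:{mod.value}"
                break
        if reason is None:
            kept.append(rec)
        else:
            dropped.append(DropRecord(rec.episode_id, rec.subject_id, reason))
    return kept, dropped


def ppg_to_hr(ppg: ModalitySignal, target_rate: float = 1.0) -> ModalitySignal:
    """Derive a heart-rate stream from a PPG pulse train.

    Peaks are detected on the pulse train; the instantaneous rate is
    60 / inter-peak interval, linearly resampled onto the target grid.
    """
    from scipy.signal import find_peaks

    if ppg.rate < 10.0:
        raise InvalidConfigError("PPG rate must be at least 10 Hz for peak detection")
    x = ppg.values
    sd = float(np.std(x))
    if sd == 0:
        raise DegenerateSignalError("flat PPG signal: no detectable peaks")
    from scipy.ndimage import uniform_filter1d

    x = uniform_filter1d(x, 3)  # light smoothing stabilizes sub-sample peak fits
    height = float(np.mean(x)) + 0.5 * sd
    peaks, _ = find_peaks(x, height=height, distance=int(0.3 * ppg.rate))
    if len(peaks) < 3:
        raise DegenerateSignalError("flat PPG signal: no detectable peaks")
    # parabolic sub-sample refinement removes the sampling-grid quantization
    # of beat times (a 20 Hz grid alone quantizes instantaneous HR coarsely)
    refined = peaks.astype(float)
    inner = (peaks > 0) & (peaks < len(x) - 1)
    p = peaks[inner]
    denom = x[p - 1] - 2.0 * x[p] + x[p + 1]
    ok = np.abs(denom) > 1e-12
    refined[inner] = p + np.where(ok, 0.5 * (x[p - 1] - x[p + 1]) / np.where(ok, denom, 1.0), 0.0)
    peak_t = refined / ppg.rate
    ibi = np.diff(peak_t)
    hr = 60.0 / ibi
    if hr.size >= 5:  # median over 5 beats suppresses single-beat timing jitter
        from scipy.signal import medfilt

        hr = medfilt(hr, 5)
    hr_t = (peak_t[:-1] + peak_t[1:]) / 2.0
    n_out = int(round(ppg.duration_s * target_rate))
    grid = np.arange(n_out) / target_rate
    out = np.interp(grid, hr_t, hr)
    return ModalitySignal(Modality.HR, target_rate, out, ppg.t0, ppg.short)


def preprocess_episode(rec: EpisodeRecord, config: PreprocessConfig | None = None) -> EpisodeRecord:
    """RMS-downsample and z-score every modality of an episode."""
    config = config or PreprocessConfig()
    signals = {mod: zscore(rms_downsample(sig, config)) for mod, sig in rec.signals.items()}
    return replace(rec, signals=signals)


def preprocess_cohort(records, config: PreprocessConfig | None = None):
    """Filter then condition a cohort; returns (processed_records, drop_report)."""
    config = config or PreprocessConfig()
    kept, dropped = filter_episodes(records, config)
    return [preprocess_episode(r, config) for r in kept], dropped
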