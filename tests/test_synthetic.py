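"""Cohort generator: determinism, planted effects, missing-segment injection."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from s2cfl import CohortConfig, Modality, generate_cohort, generate_modality_signal
from s2cfl.errors import InvalidArgumentError, InvalidConfigError, UnsupportedModalityError
from s2cfl.synthetic import (
    hr_arousal_mean_difference,
    inject_missing_segments,
    write_cohort,
    read_cohort,
)
from s2cfl.types import EMOTIONS


def _cfg(**kw):
    base = dict(n_subjects=8, episodes_per_subject=5, duration_s=300, seed=7)
    base.update(kw)
    return CohortConfig(**base)


class TestDeterminismAndContracts:
    def test_same_seed_gives_identical_cohorts(self):
        cfg = _cfg(n_subjects=2, episodes_per_subject=1)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        for ra, rb in zip(a, b):
            assert ra.episode_id == rb.episode_id
            for mod in ra.signals:
                assert ra.signals[mod].values.tobytes() == rb.signals[mod].values.tobytes()
            assert np.array_equal(ra.self_report, rb.self_report)

    def test_shapes_rates_and_labels(self):
        cohort = generate_cohort(_cfg(n_subjects=3, episodes_per_subject=2))
        assert len(cohort) == 6
        for rec in cohort:
            assert rec.labels.emotion in EMOTIONS
            acc = rec.signals[Modality.ACC]
            assert acc.values.shape == (round(acc.rate * 300), 3)
            hr = rec.signals[Modality.HR]
            assert hr.values.shape == (round(hr.rate * 300),)
            v, a, d = rec.labels.raw_scores
            assert rec.labels.valence == int(v > 0)
            assert rec.labels.arousal == int(a > 0)
            assert rec.labels.depression == int(d > 0)

    def test_invalid_configs_rejected(self):
        with pytest.raises(InvalidConfigError):
            _cfg(n_subjects=0)
        with pytest.raises(InvalidConfigError):
            _cfg(duration_s=-5)
        with pytest.raises(InvalidConfigError):
            _cfg(missing_fraction=1.5)
        with pytest.raises(UnsupportedModalityError):
            generate_modality_signal("EEG", 60.0)

    def test_csv_roundtrip(self, tmp_path):
        cohort = generate_cohort(_cfg(n_subjects=2, episodes_per_subject=2, duration_s=60))
        write_cohort(cohort, tmp_path / "c")
        back = read_cohort(tmp_path / "c")
        assert len(back) == len(cohort)
        for ra, rb in zip(cohort, back):
            assert ra.episode_id == rb.episode_id
            assert ra.labels.emotion == rb.labels.emotion
            assert np.allclose(ra.signals[Modality.HR].values, rb.signals[Modality.HR].values)
            assert np.allclose(ra.self_report, rb.self_report)


class TestPlantedEffects:
    def test_zero_effects_leave_no_hr_arousal_signal(self):
        cfg = _cfg(
            n_subjects=10,
            episodes_per_subject=6,
            effect_sizes={"hr_arousal_shift": 0.0, "gsr_stress_rate": 0.0, "acc_valence_damping": 0.0},
            seed=21,
        )
        cohort = generate_cohort(cfg)
        hi = [r.signals[Modality.HR].values.mean() for r in cohort if r.labels.arousal == 1]
        lo = [r.signals[Modality.HR].values.mean() for r in cohort if r.labels.arousal == 0]
        se = np.sqrt(np.var(hi, ddof=1) / len(hi) + np.var(lo, ddof=1) / len(lo))
        assert abs(np.mean(hi) - np.mean(lo)) < 2.0 * se

    def test_hr_shift_recovered_by_group_mean_difference(self):
        shift = 10.0
        cfg = _cfg(
            n_subjects=10,
            episodes_per_subject=6,
            effect_sizes={"hr_arousal_shift": shift, "gsr_stress_rate": 0.0, "acc_valence_damping": 0.0},
            seed=13,
        )
        cohort = generate_cohort(cfg)
        assert hr_arousal_mean_difference(cohort) == pytest.approx(shift, abs=2.0)

    def test_acc_damping_recovered_by_variance_ratio(self):
        d = 0.6
        cfg = _cfg(
            n_subjects=12,
            episodes_per_subject=6,
            duration_s=600,
            effect_sizes={"hr_arousal_shift": 0.0, "gsr_stress_rate": 0.0, "acc_valence_damping": d},
            seed=17,
        )
        cohort = generate_cohort(cfg)

        def dyn_var(rec):
            return float(np.mean(np.var(rec.signals[Modality.ACC].values, axis=0)))

        lo = np.array([dyn_var(r) for r in cohort if r.labels.valence == 0])
        hi = np.array([dyn_var(r) for r in cohort if r.labels.valence == 1])
        ratio = lo.mean() / hi.mean()
        se = ratio * np.sqrt(
            np.var(lo, ddof=1) / len(lo) / lo.mean() ** 2
            + np.var(hi, ddof=1) / len(hi) / hi.mean() ** 2
        )
        assert abs(ratio - (1.0 - d)) < 2.0 * se + 0.03  # small sensor-noise floor offset

    def test_gsr_burst_rate_ratio_recovered(self):
        g = 1.5
        cfg = _cfg(
            n_subjects=12,
            episodes_per_subject=6,
            duration_s=600,
            effect_sizes={"hr_arousal_shift": 0.0, "gsr_stress_rate": g, "acc_valence_damping": 0.0},
            seed=19,
        )
        cohort = generate_cohort(cfg)
        from s2cfl.synthetic import scr_rate_per_s

        hi = np.array(
            [scr_rate_per_s(r.signals[Modality.GSR]) for r in cohort if r.labels.depression == 1]
        )
        lo = np.array(
            [scr_rate_per_s(r.signals[Modality.GSR]) for r in cohort if r.labels.depression == 0]
        )
        ratio = hi.mean() / lo.mean()
        se = ratio * np.sqrt(
            np.var(hi, ddof=1) / len(hi) / hi.mean() ** 2
            + np.var(lo, ddof=1) / len(lo) / lo.mean() ** 2
        )
        assert abs(ratio - (1.0 + g)) < 2.0 * se


class TestModalityKernels:
    def test_gsr_zero_burst_rate_is_strictly_tonic(self):
        sig = generate_modality_signal(
            Modality.GSR, 600.0, {"burst_rate_per_min": 0.0}, seed=3
        )
        from scipy.ndimage import gaussian_filter1d, uniform_filter1d

        x = uniform_filter1d(sig.values, int(sig.rate))
        tonic = gaussian_filter1d(x, sigma=20.0 * sig.rate)
        noise_sd = (x - tonic).std()
        peaks, _ = find_peaks(x - tonic, height=3.0 * noise_sd + 0.05, distance=int(4 * sig.rate))
        assert len(peaks) == 0

    def test_hr_length_contract(self):
        sig = generate_modality_signal(Modality.HR, 1800.0, {}, seed=1, rate=1.0)
        assert sig.n_samples == 1800

    def test_ppg_constant_60bpm_has_1s_beat_interval(self):
        sig = generate_modality_signal(Modality.PPG, 120.0, {"bpm": 60.0}, seed=5, rate=20.0)
        peaks, _ = find_peaks(sig.values, height=0.5, distance=int(0.5 * sig.rate))
        intervals = np.diff(peaks) / sig.rate
        assert np.mean(intervals) == pytest.approx(1.0, abs=0.05)


class TestMissingInjection:
    def test_fraction_zero_is_identity(self, small_cohort):
        sig = small_cohort[0].signals[Modality.HR]
        out = inject_missing_segments(sig, 0.0, seed=1)
        assert np.array_equal(out.values, sig.values)

    def test_fraction_one_is_all_missing(self, small_cohort):
        sig = small_cohort[0].signals[Modality.HR]
        out = inject_missing_segments(sig, 1.0, seed=1)
        assert np.isnan(out.values).all()

    def test_half_fraction_count_and_contiguity(self):
        sig = generate_modality_signal(Modality.HR, 1000.0, {}, seed=2, rate=1.0)
        out = inject_missing_segments(sig, 0.5, seed=9)
        n_missing = int(np.isnan(out.values).sum())
        assert abs(n_missing - 500) <= 10
        runs = np.diff(np.flatnonzero(np.isnan(out.values)))
        assert np.median(runs) == 1  # mostly contiguous

    def test_invalid_fraction_rejected(self, small_cohort):
        with pytest.raises(InvalidArgumentError):
            inject_missing_segments(small_cohort[0].signals[Modality.HR], 1.2, seed=0)

    def test_manifest_records_corrupted_episodes(self):
        cfg = _cfg(n_subjects=6, episodes_per_subject=5, missing_fraction=0.3, seed=8)
        cohort = generate_cohort(cfg)
        corrupted = {c["episode_id"] for c in cohort.manifest["corrupted_episodes"]}
        actually_gappy = {
            r.episode_id
            for r in cohort
            if any(s.missing_fraction() > 0 for s in r.signals.values())
        }
        assert corrupted == actually_gappy
        assert corrupted  # at 30% corruption of 30 episodes this is nonempty
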