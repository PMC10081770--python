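"""Synthetic generator: determinism, symptom injection, diaries, glitches."""
import dataclasses

import numpy as np
import pytest
from scipy.signal import periodogram

from wristpd.core import AccelRecording
from wristpd.synthdata import (ScenarioConfig, TASKS, corrupt_timestamps,
                               draw_symptom_events, effective_severity,
                               generate_scenario, generate_task_sessions,
                               synthesize_task_signal)


def band_power(sig, lo, hi, fs=50.0):
    f, p = periodogram(sig - sig.mean(axis=0), fs=fs, axis=0)
    mask = (f >= lo) & (f <= hi)
    return float(p[mask].sum())


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"duration_per_subject": 0.0},
        {"n_patients": -1},
        {"brady_attenuation": 1.5},
        {"tremor_amp": -0.1},
        {"sampling_rate": 9.0},  # below twice the tremor frequency
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScenarioConfig(**kwargs).validate()


class TestScenario:
    def test_no_patients_means_no_symptoms(self):
        cfg = ScenarioConfig(n_patients=0, n_controls=2,
                             duration_per_subject=600.0, glitch_rate=0.0, seed=3)
        recs, diary, truth = generate_scenario(cfg)
        assert len(recs) == 2
        assert diary == [] and truth.true_events == []

    def test_determinism_same_seed(self):
        cfg = ScenarioConfig(n_patients=1, n_controls=1,
                             duration_per_subject=900.0, seed=5)
        a = generate_scenario(cfg)
        b = generate_scenario(cfg)
        for ra, rb in zip(a[0], b[0]):
            np.testing.assert_array_equal(ra.t, rb.t)
            np.testing.assert_array_equal(ra.xyz, rb.xyz)
        assert [dataclasses.astuple(d) for d in a[1]] == \
               [dataclasses.astuple(d) for d in b[1]]

    def test_event_rate_matches_poisson_expectation(self):
        """Mean injected tremor events per patient sits in the Poisson band."""
        rate, days, n_draws = 6.0, 1.0, 300
        counts = []
        for seed in range(n_draws):
            rng = np.random.default_rng(seed)
            ev = draw_symptom_events(rng, {"tremor": rate}, days * 86400.0)
            counts.append(len(ev))
        mean = np.mean(counts)
        se = np.sqrt(rate * days / n_draws)
        assert abs(mean - rate * days) < 3 * se

    def test_diary_events_overlap_truth_when_jitter_small(self):
        cfg = ScenarioConfig(n_patients=3, n_controls=0,
                             duration_per_subject=4 * 3600.0,
                             symptom_rates={"tremor": 12.0},
                             diary_jitter_sd=0.5, glitch_rate=0.0, seed=9)
        _, diary, truth = generate_scenario(cfg)
        assert len(diary) == len(truth.true_events) > 0
        for d, t in zip(diary, truth.true_events):
            assert d.subject_id == t.subject_id
            assert d.start < t.end and d.end > t.start  # intervals overlap


class TestTaskSignals:
    def test_unknown_task_rejected(self):
        with pytest.raises(KeyError):
            synthesize_task_signal("jumping", 10.0)

    def test_sitting_is_gravity_plus_noise(self):
        sig = synthesize_task_signal("sitting", 10.0, 0.0, seed=1)
        vm = np.linalg.norm(sig, axis=1).mean()
        assert abs(vm - 1.0) < 0.05

    @pytest.mark.parametrize("task", ["walking", "walking-variant"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_walking_fundamental_in_gait_band(self, task, seed):
        sig = synthesize_task_signal(task, 60.0, 0.0, seed=seed)
        f, p = periodogram(sig - sig.mean(axis=0), fs=50.0, axis=0)
        peak = f[np.argmax(p.sum(axis=1) * (f > 0.5))]
        assert 1.5 <= peak <= 2.5

    def test_tremor_raises_band_power_by_10db(self):
        calm = synthesize_task_signal("sitting", 60.0, 0.0, seed=4)
        shaky = synthesize_task_signal("sitting", 60.0, 3.0, "OFF", seed=4)
        gain = 10 * np.log10(band_power(shaky, 4, 6) / band_power(calm, 4, 6))
        assert gain >= 10.0

    def test_drug_on_attenuates_tremor(self):
        off = synthesize_task_signal("sitting", 60.0, 3.0, "OFF", seed=4)
        on = synthesize_task_signal("sitting", 60.0, 3.0, "ON", seed=4)
        assert band_power(on, 4, 6) < band_power(off, 4, 6)

    def test_bradykinesia_attenuates_low_frequency_walking(self):
        cfg = ScenarioConfig()
        normal = synthesize_task_signal("walking", 60.0, {"bradykinesia": 0.0},
                                        seed=6, config=cfg)
        slow = synthesize_task_signal("walking", 60.0, {"bradykinesia": 4.0},
                                      seed=6, config=cfg)
        assert band_power(slow, 0.5, 4) < band_power(normal, 0.5, 4)

    def test_effective_severity_polarity(self):
        assert effective_severity(2.0, "tremor", "ON", 0.5) == 1.0
        assert effective_severity(2.0, "bradykinesia", "ON", 0.5) == 1.0
        assert effective_severity(2.0, "dyskinesia", "ON", 0.5) == 4.0
        assert effective_severity(2.0, "tremor", "OFF", 0.5) == 2.0


class TestGlitches:
    def _one_hour(self):
        n = 180000
        rng = np.random.default_rng(0)
        return AccelRecording("S", "control", 50.0, np.arange(n) / 50.0,
                              rng.standard_normal((n, 3)) * 0.01)

    def test_zero_rate_is_identity(self):
        rec = self._one_hour()
        out = corrupt_timestamps(rec, 0.0, seed=1)
        assert out is rec

    def test_timestamps_stay_strictly_increasing(self):
        rec = self._one_hour()
        out = corrupt_timestamps(rec, 5.0, seed=2)
        assert out.n_samples < rec.n_samples
        assert np.all(np.diff(out.t) > 0)

    def test_gap_count_is_poisson_on_average(self):
        rec = self._one_hour()
        rate = 2.0
        counts = []
        for seed in range(250):
            out = corrupt_timestamps(rec, rate, seed=seed)
            counts.append(int(np.sum(np.diff(out.t) > 0.1)))
        mean = np.mean(counts)
        se = np.sqrt(rate / 250)
        assert abs(mean - rate) < 4 * se


class TestTaskSessions:
    def test_schedule_structure(self):
        sessions, signals, truth = generate_task_sessions(
            n_subjects=3, n_visits=1, sessions_per_visit=2, duration=5.0, seed=2)
        assert len(sessions) == 3 * 1 * 2 * len(TASKS) == len(signals)
        assert set(sessions["drug_state"]) == {"ON", "OFF"}
        per_subject = sessions.groupby("subject")["drug_state"].nunique()
        assert (per_subject == 2).all()
        for sym in ("tremor", "bradykinesia", "dyskinesia"):
            col = sessions[f"{sym}_score"]
            assert col.between(0, 4).all()
        assert len(truth.task_schedule) == len(sessions)
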