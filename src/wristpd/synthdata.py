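"""Synthetic cohorts, recordings, diaries, and in-clinic task sessions.

The generator emulates wrist-worn tri-axial accelerometry at 50 Hz from a
Parkinson cohort and matched controls: a background of everyday activity
bouts (sitting, standing, walking), slow drift of the gravity direction,
white measurement noise, and injected motor symptoms with known ground
truth.  Symptom phenomenology follows the standard clinical picture:

* tremor    — additive narrow-band oscillation near 5 Hz;
* bradykinesia — multiplicative attenuation of voluntary movement power
  below 4 Hz;
* dyskinesia — additive broadband (1-8 Hz) irregular activity.

Levodopa ("drug ON") attenuates tremor and bradykinesia and amplifies
dyskinesia, which is the polarity the scoring analyses must recover.

Everything is deterministic given the scenario seed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import (
    APP_SYMPTOM_LABEL,
    CONTROL,
    PATIENT,
    AccelRecording,
    DiaryEvent,
    GroundTruth,
    TaskSession,
    TrueEvent,
)

#: task taxonomy: canonical label -> movement family
TASK_FAMILIES = {
    "sitting": "stationary",
    "standing": "stationary",
    "walking": "walking",
    "walking-variant": "walking",
    "finger-to-nose": "fine-motor",
    "repeated-arm-movement": "arm-movement",
}
TASKS = tuple(TASK_FAMILIES)

SYMPTOMS = ("tremor", "bradykinesia", "dyskinesia")

#: white measurement noise, g units
NOISE_SD = 0.01
#: slow wander of the gravity direction, degrees per minute
GRAVITY_DRIFT_DEG_PER_MIN = 1.0


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic home-monitoring scenario.

    Defaults describe a fluctuating-PD cohort: eight patients and eight
    controls, eight hours of continuous wrist accelerometry each, tremor
    as the dominant reported symptom.  Amplitudes are calibrated to be
    detectable above the 0.01 g noise floor, not to clinical magnitudes.
    """

    n_patients: int = 8
    n_controls: int = 8
    duration_per_subject: float = 8 * 3600.0  # seconds
    sampling_rate: float = 50.0  # Hz
    symptom_rates: Mapping[str, float] = field(
        default_factory=lambda: {"tremor": 8.0, "bradykinesia": 4.0, "dyskinesia": 4.0}
    )  # events per day
    baseline_severity: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"tremor": (0.5, 2.0), "bradykinesia": (0.5, 2.0)}
    )  # per-subject constitutive severity range (uniform draw), patients only
    tremor_freq: float = 5.0  # Hz
    tremor_amp: float = 0.15  # g at severity 4
    brady_attenuation: float = 0.25  # power factor on <4 Hz movement at severity 4
    dyskinesia_amp: float = 0.10  # g RMS at severity 4
    drug_effect: float = 0.5  # ON-state severity multiplier (tremor/brady)
    diary_jitter_sd: float = 3.0  # minutes
    glitch_rate: float = 0.5  # timestamp gaps per hour
    activity_mix: Mapping[str, float] = field(
        default_factory=lambda: {"sitting": 0.5, "standing": 0.2, "walking": 0.3}
    )  # background bout probabilities
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValueError("subject counts must be non-negative")
        if self.duration_per_subject <= 0:
            raise ValueError("duration_per_subject must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.sampling_rate <= 2 * self.tremor_freq:
            raise ValueError("sampling_rate must exceed twice the tremor frequency")
        if not 0.0 <= self.brady_attenuation <= 1.0:
            raise ValueError("brady_attenuation must lie in [0, 1]")
        for name, value in [
            ("tremor_amp", self.tremor_amp),
            ("dyskinesia_amp", self.dyskinesia_amp),
            ("diary_jitter_sd", self.diary_jitter_sd),
            ("glitch_rate", self.glitch_rate),
            ("drug_effect", self.drug_effect),
        ]:
            if value < 0:
                raise ValueError(f"{name} must be non-negative")
        for sym, rate in self.symptom_rates.items():
            if sym not in SYMPTOMS:
                raise ValueError(f"unknown symptom class {sym!r}")
            if rate < 0:
                raise ValueError("symptom rates must be non-negative")
        for sym, (lo, hi) in self.baseline_severity.items():
            if sym not in SYMPTOMS:
                raise ValueError(f"unknown symptom class {sym!r}")
            if not (0 <= lo <= hi <= 4):
                raise ValueError("baseline severity range must satisfy 0 <= lo <= hi <= 4")
        if not self.activity_mix or any(p < 0 for p in self.activity_mix.values()):
            raise ValueError("activity_mix must be non-empty with non-negative weights")
        for task in self.activity_mix:
            if task not in TASK_FAMILIES:
                raise ValueError(f"unknown activity {task!r} in activity_mix")


# ---------------------------------------------------------------------------
# low-level signal components
# ---------------------------------------------------------------------------


def _rand_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _gravity_walk(n: int, fs: float, rng: np.random.Generator,
                  g0: np.ndarray | None = None) -> np.ndarray:
    """Unit gravity direction drifting as a slow random walk (~1 deg/min)."""
    if g0 is None:
        g0 = _rand_unit(rng)
    step = np.deg2rad(GRAVITY_DRIFT_DEG_PER_MIN) / np.sqrt(60.0 * fs)
    steps = rng.standard_normal((n, 3)) * step
    g = g0[None, :] + np.cumsum(steps, axis=0)
    return g / np.linalg.norm(g, axis=1, keepdims=True)


def _tremor_wave(n: int, fs: float, rng: np.random.Generator,
                 freq: float, amp: float) -> np.ndarray:
    """Additive resting-tremor oscillation with edge ramps and slow AM."""
    t = np.arange(n) / fs
    f = freq + rng.normal(0.0, 0.15)
    axis = _rand_unit(rng)
    # slow +-15 % amplitude modulation
    am = 1.0 + 0.15 * np.sin(2 * np.pi * rng.uniform(0.05, 0.15) * t + rng.uniform(0, 2 * np.pi))
    env = sps.windows.tukey(n, alpha=0.2)
    wave = amp * am * env * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return wave[:, None] * axis


def _dyskinesia_wave(n: int, fs: float, rng: np.random.Generator,
                     amp: float) -> np.ndarray:
    """Broadband 1-8 Hz irregular movement, RMS-normalised then scaled."""
    raw = rng.standard_normal((n, 3))
    if n > 30:
        sos = sps.butter(4, [1.0, 8.0], btype="bandpass", fs=fs, output="sos")
        raw = sps.sosfilt(sos, raw, axis=0)
    rms = np.sqrt(np.mean(raw**2))
    if rms > 0:
        raw = raw / rms
    env = sps.windows.tukey(n, alpha=0.2)
    return amp * env[:, None] * raw


def _attenuate_low(m: np.ndarray, fs: float, power_factor: float) -> np.ndarray:
    """Scale the <4 Hz part of a movement signal by ``power_factor`` (power)."""
    if m.shape[0] < 30 or power_factor >= 1.0:
        return m * 1.0
    sos = sps.butter(4, 4.0, btype="low", fs=fs, output="sos")
    # zero-phase split so the band components recombine coherently
    low = sps.sosfiltfilt(sos, m, axis=0)
    return low * np.sqrt(power_factor) + (m - low)


def _movement(task: str, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Voluntary-movement acceleration (device frame, gravity excluded)."""
    if task not in TASK_FAMILIES:
        raise KeyError(f"unknown task label {task!r}; known: {sorted(TASK_FAMILIES)}")
    t = np.arange(n) / fs
    m = np.zeros((n, 3))
    family = TASK_FAMILIES[task]
    if task == "sitting":
        pass
    elif task == "standing":
        # postural sway plus occasional weight-shift transients
        f = rng.uniform(0.3, 0.5)
        m += 0.008 * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))[:, None] * _rand_unit(rng)
        n_shifts = rng.poisson(n / fs / 4.0)
        width = int(0.4 * fs)
        profile = sps.windows.gaussian(2 * width + 1, std=width / 2.5)
        for _ in range(n_shifts):
            at = int(rng.uniform(0, max(1, n - profile.size)))
            axis = _rand_unit(rng)
            m[at:at + profile.size] += 0.04 * rng.uniform(0.5, 1.5) * profile[:, None] * axis
    elif family == "walking":
        f0 = rng.uniform(1.6, 2.1) if task == "walking" else rng.uniform(1.9, 2.4)
        for harmonic, amp in enumerate((0.25, 0.12, 0.06), start=1):
            phase = rng.uniform(0, 2 * np.pi)
            m += amp * np.sin(2 * np.pi * harmonic * f0 * t + phase)[:, None] * _rand_unit(rng)
        m += 0.02 * rng.standard_normal((n, 3))
    elif task == "finger-to-nose":
        # large slow arm transport with low-amplitude 5-8 Hz bursts gated
        # by the reach-touch cycle
        f_cycle = rng.uniform(0.3, 0.5)
        phase = rng.uniform(0, 2 * np.pi)
        m += 0.12 * np.sin(2 * np.pi * f_cycle * t + phase)[:, None] * _rand_unit(rng)
        f = rng.uniform(5.0, 8.0)
        gate = 0.5 * (1 + np.sin(2 * np.pi * f_cycle * t + phase))
        m += (0.06 * gate * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)))[:, None] * _rand_unit(rng)
        m += 0.01 * rng.standard_normal((n, 3))
    elif task == "repeated-arm-movement":
        f0 = rng.uniform(0.7, 1.1)
        for harmonic, amp in enumerate((0.35, 0.10), start=1):
            phase = rng.uniform(0, 2 * np.pi)
            m += amp * np.sin(2 * np.pi * harmonic * f0 * t + phase)[:, None] * _rand_unit(rng)
        m += 0.015 * rng.standard_normal((n, 3))
    return m


def effective_severity(severity: float, symptom: str, drug_state: str,
                       drug_effect: float) -> float:
    """Severity after drug-state modulation, clipped to the 0-4 scale.

    ON multiplies tremor/bradykinesia severity by ``drug_effect`` and
    divides dyskinesia severity by it (levodopa-induced dyskinesia).
    """
    if drug_state not in ("ON", "OFF"):
        raise ValueError("drug_state must be 'ON' or 'OFF'")
    if drug_state == "OFF" or severity == 0:
        return float(np.clip(severity, 0.0, 4.0))
    if symptom == "dyskinesia":
        scaled = severity / drug_effect if drug_effect > 0 else 4.0
    else:
        scaled = severity * drug_effect
    return float(np.clip(scaled, 0.0, 4.0))


def _inject_symptoms(movement: np.ndarray, fs: float, rng: np.random.Generator,
                     severities: Mapping[str, float], config: ScenarioConfig) -> np.ndarray:
    """Apply the three symptom mechanisms to a movement signal in place."""
    n = movement.shape[0]
    out = movement
    sev_b = float(severities.get("bradykinesia", 0.0))
    if sev_b > 0:
        factor = 1.0 - (1.0 - config.brady_attenuation) * sev_b / 4.0
        out = _attenuate_low(out, fs, factor)
    sev_t = float(severities.get("tremor", 0.0))
    if sev_t > 0:
        out = out + _tremor_wave(n, fs, rng, config.tremor_freq, config.tremor_amp * sev_t / 4.0)
    sev_d = float(severities.get("dyskinesia", 0.0))
    if sev_d > 0:
        out = out + _dyskinesia_wave(n, fs, rng, config.dyskinesia_amp * sev_d / 4.0)
    return out


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def synthesize_task_signal(task_label: str, duration: float,
                           severity: float | Mapping[str, float] = 0.0,
                           drug_state: str = "OFF", seed: int = 0,
                           config: ScenarioConfig | None = None) -> np.ndarray:
    """Tri-axial signal for one task performance.

    ``severity`` may be a mapping from symptom class to 0-4 severity or a
    scalar, in which case it is read as the tremor severity.  Drug-state
    modulation is applied internally via :func:`effective_severity`.

    Returns an (n, 3) array in g units at ``config.sampling_rate``.
    """
    cfg = config or ScenarioConfig()
    if task_label not in TASK_FAMILIES:
        raise KeyError(f"unknown task label {task_label!r}; known: {sorted(TASK_FAMILIES)}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if isinstance(severity, (int, float)):
        severity = {"tremor": float(severity)}
    rng = np.random.default_rng(seed)
    fs = cfg.sampling_rate
    n = int(round(duration * fs))
    movement = _movement(task_label, n, fs, rng)
    eff = {s: effective_severity(v, s, drug_state, cfg.drug_effect)
           for s, v in severity.items()}
    movement = _inject_symptoms(movement, fs, rng, eff, cfg)
    gravity = _gravity_walk(n, fs, rng)
    return gravity + movement + NOISE_SD * rng.standard_normal((n, 3))


def draw_symptom_events(rng: np.random.Generator, rates: Mapping[str, float],
                        duration: float) -> list[tuple[str, float, float, float]]:
    """Poisson symptom events for one patient: (class, start, end, severity).

    Event counts per class follow a Poisson law with the configured
    events/day rate; onsets are uniform over the recording; durations are
    log-normal with a 20-minute median, clipped to 5-90 minutes; severity
    is uniform on [1, 4].
    """
    events = []
    days = duration / 86400.0
    for symptom in SYMPTOMS:
        rate = float(rates.get(symptom, 0.0))
        if rate <= 0:
            continue
        count = rng.poisson(rate * days)
        for _ in range(count):
            start = rng.uniform(0.0, duration)
            length = float(np.clip(rng.lognormal(np.log(20 * 60.0), 0.5), 300.0, 5400.0))
            end = min(start + length, duration)
            severity = rng.uniform(1.0, 4.0)
            events.append((symptom, start, end, severity))
    events.sort(key=lambda e: e[1])
    return events


def _background_movement(n: int, fs: float, rng: np.random.Generator,
                         mix: Mapping[str, float] | None = None) -> np.ndarray:
    """Everyday-activity movement: bouts drawn from the activity mixture."""
    if mix is None:
        mix = {"sitting": 0.5, "standing": 0.2, "walking": 0.3}
    labels = tuple(mix)
    total = sum(mix.values())
    probs = tuple(p / total for p in mix.values())
    parts: list[np.ndarray] = []
    filled = 0
    while filled < n:
        task = rng.choice(labels, p=probs)
        bout = int(np.clip(rng.lognormal(np.log(8 * 60.0), 0.5), 120.0, 1500.0) * fs)
        bout = min(bout, n - filled)
        parts.append(_movement(task, bout, fs, rng))
        filled += bout
    return np.concatenate(parts, axis=0)


def corrupt_timestamps(recording: AccelRecording, glitch_rate: float,
                       seed: int = 0) -> AccelRecording:
    """Drop 0.5-10 s runs of samples at Poisson times (``glitch_rate``/hour).

    Sample values outside the gaps are untouched; timestamps remain
    strictly increasing because samples are removed, not shifted.
    """
    if glitch_rate < 0:
        raise ValueError("glitch_rate must be non-negative")
    if glitch_rate == 0 or recording.n_samples == 0:
        return recording
    rng = np.random.default_rng(seed)
    hours = recording.duration / 3600.0
    n_gaps = rng.poisson(glitch_rate * hours)
    if n_gaps == 0:
        return recording
    keep = np.ones(recording.n_samples, dtype=bool)
    t0, t1 = recording.t[0], recording.t[-1]
    for _ in range(n_gaps):
        gap_start = rng.uniform(t0, t1)
        gap_len = rng.uniform(0.5, 10.0)
        keep &= ~((recording.t >= gap_start) & (recording.t < gap_start + gap_len))
    return dataclasses.replace(recording, t=recording.t[keep], xyz=recording.xyz[keep])


def generate_scenario(config: ScenarioConfig) -> tuple[
        list[AccelRecording], list[DiaryEvent], GroundTruth]:
    """Generate a full home-monitoring scenario with known ground truth.

    Patients carry a mild constitutive symptom load (drawn per subject
    from ``baseline_severity``; PD motor signs are present throughout the
    day, which is what makes patient and control aggregate spectra
    differ) plus episodic worsening events at the configured per-class
    rates; controls carry neither.  The diary reports only the episodic
    events, with boundaries perturbed by N(0, ``diary_jitter_sd``^2)
    minutes and 5 % of reported durations inflated twofold, emulating
    imprecise self-report.
    """
    config.validate()
    fs = config.sampling_rate
    n = int(round(config.duration_per_subject * fs))
    root = np.random.SeedSequence(config.seed)
    n_subjects = config.n_patients + config.n_controls
    children = root.spawn(n_subjects + 1)
    diary_rng = np.random.default_rng(children[-1])

    recordings: list[AccelRecording] = []
    diary: list[DiaryEvent] = []
    truth = GroundTruth()

    for idx in range(n_subjects):
        is_patient = idx < config.n_patients
        subject_id = f"P{idx + 1:02d}" if is_patient else f"C{idx - config.n_patients + 1:02d}"
        rng = np.random.default_rng(children[idx])
        movement = _background_movement(n, fs, rng, config.activity_mix)

        if is_patient:
            baseline = {sym: float(rng.uniform(lo, hi))
                        for sym, (lo, hi) in config.baseline_severity.items()}
            movement = _inject_symptoms(movement, fs, rng, baseline, config)
            truth.baseline_severity[subject_id] = baseline
            events = draw_symptom_events(rng, config.symptom_rates, config.duration_per_subject)
            for symptom, start, end, severity in events:
                i0, i1 = int(start * fs), int(end * fs)
                i1 = min(i1, n)
                if i1 - i0 < 10:
                    continue
                seg = movement[i0:i1]
                movement[i0:i1] = _inject_symptoms(
                    seg, fs, rng, {symptom: severity}, config)
                truth.true_events.append(
                    TrueEvent(subject_id, symptom, start, min(end, config.duration_per_subject),
                              severity))

        gravity = _gravity_walk(n, fs, rng)
        xyz = gravity + movement + NOISE_SD * rng.standard_normal((n, 3))
        rec = AccelRecording(subject_id, PATIENT if is_patient else CONTROL,
                             fs, np.arange(n) / fs, xyz)
        if config.glitch_rate > 0:
            rec = corrupt_timestamps(rec, config.glitch_rate,
                                     seed=int(children[idx].generate_state(1)[0] % 2**31))
        recordings.append(rec)

    jitter = config.diary_jitter_sd * 60.0
    for ev in truth.true_events:
        start = ev.start + diary_rng.normal(0.0, jitter)
        end = ev.end + diary_rng.normal(0.0, jitter)
        if diary_rng.uniform() < 0.05:
            end = start + 2.0 * (ev.end - ev.start)  # duration inflation
        if end - start < 60.0:
            end = start + 60.0
        diary.append(DiaryEvent(ev.subject_id, APP_SYMPTOM_LABEL[ev.symptom],
                                start, end))
    return recordings, diary, truth


def generate_task_sessions(n_subjects: int = 12, n_visits: int = 2,
                           sessions_per_visit: int = 2, duration: float = 30.0,
                           config: ScenarioConfig | None = None,
                           seed: int = 0) -> tuple[pd.DataFrame, list[np.ndarray], GroundTruth]:
    """In-clinic task sessions with observer-scored symptoms.

    Emulates a levodopa-response protocol: every subject performs the full
    task battery in each session; drug state alternates OFF/ON across the
    sessions of a visit.  Each subject has latent 0-4 severity traits per
    symptom; observers score the drug-modulated severity on the ordinal
    0-4 scale with noise.

    Returns ``(sessions, signals, truth)`` where ``sessions`` has one row
    per replicate (subject, visit, session, task, drug state, wear hand,
    observer scores, true severities) and ``signals[i]`` is the (n, 3)
    accelerometer signal of row ``i``.
    """
    cfg = config or ScenarioConfig()
    if n_subjects < 1:
        raise ValueError("n_subjects must be positive")
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_subjects)
    rows = []
    signals: list[np.ndarray] = []
    truth = GroundTruth()
    clock = 0.0
    for s in range(n_subjects):
        rng = np.random.default_rng(children[s])
        subject_id = f"S{s + 1:02d}"
        traits = {
            "tremor": float(rng.uniform(1.0, 3.5)),
            "bradykinesia": float(rng.uniform(1.0, 3.5)),
            "dyskinesia": float(rng.uniform(0.5, 3.0)),
        }
        wear_hand = "right" if rng.uniform() < 0.8 else "left"
        for visit in range(1, n_visits + 1):
            for session in range(1, sessions_per_visit + 1):
                drug_state = "OFF" if session % 2 == 1 else "ON"
                for task in TASKS:
                    eff = {sym: effective_severity(sev, sym, drug_state, cfg.drug_effect)
                           for sym, sev in traits.items()}
                    sig_seed = int(rng.integers(0, 2**31))
                    sig = synthesize_task_signal(task, duration, traits, drug_state,
                                                 seed=sig_seed, config=cfg)
                    scores = {f"{sym}_score": int(np.clip(round(eff[sym] + rng.normal(0, 0.35)), 0, 4))
                              for sym in SYMPTOMS}
                    rows.append({
                        "subject": subject_id, "visit": visit, "session": session,
                        "session_id": f"{subject_id}-v{visit}-s{session}",
                        "task": task, "family": TASK_FAMILIES[task],
                        "drug_state": drug_state, "wear_hand": wear_hand,
                        **scores,
                        **{f"true_{sym}": eff[sym] for sym in SYMPTOMS},
                    })
                    signals.append(sig)
                    truth.task_schedule.append(
                        TaskSession(subject_id, visit, session, task, drug_state,
                                    clock, clock + duration))
                    clock += duration + 30.0
    sessions = pd.DataFrame(rows)
    return sessions, signals, truth


def generate_windowed_task_dataset(n_subjects: int = 12,
                                   windows_per_task: int = 45,
                                   config: ScenarioConfig | None = None,
                                   seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labelled 10-second windows for movement-state representation learning.

    Every subject performs every task long enough to yield
    ``windows_per_task`` non-overlapping 10 s windows; subjects carry mild
    symptom traits so the windows are not artificially clean.  Returns
    ``(windows, task_labels, subject_ids)`` with windows already
    standardised and flattened to 1500 values.
    """
    from .vae import WINDOW_SECONDS, windows_from_array

    cfg = config or ScenarioConfig()
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_subjects)
    xs, ys, gs = [], [], []
    for s in range(n_subjects):
        rng = np.random.default_rng(children[s])
        subject_id = f"S{s + 1:02d}"
        traits = {
            "tremor": float(rng.uniform(0.0, 2.0)),
            "bradykinesia": float(rng.uniform(0.0, 2.0)),
            "dyskinesia": float(rng.uniform(0.0, 1.0)),
        }
        for task in TASKS:
            duration = windows_per_task * WINDOW_SECONDS
            sig = synthesize_task_signal(task, duration, traits, "OFF",
                                         seed=int(rng.integers(0, 2**31)),
                                         config=cfg)
            w = windows_from_array(sig, cfg.sampling_rate)
            xs.append(w)
            ys.extend([task] * w.shape[0])
            gs.extend([subject_id] * w.shape[0])
    return np.concatenate(xs), np.asarray(ys), np.asarray(gs)


# ---------------------------------------------------------------------------
# plain-text export
# ---------------------------------------------------------------------------


def recording_frame(recording: AccelRecording) -> pd.DataFrame:
    """Recording as a DataFrame with ISO-8601 timestamps."""
    from .core import EPOCH_ISO

    ts = pd.Timestamp(EPOCH_ISO) + pd.to_timedelta(recording.t, unit="s")
    return pd.DataFrame({
        "t_iso8601": ts.strftime("%Y-%m-%dT%H:%M:%S.%f"),
        "x_g": recording.xyz[:, 0],
        "y_g": recording.xyz[:, 1],
        "z_g": recording.xyz[:, 2],
    })


def diary_frame(diary: Sequence[DiaryEvent]) -> pd.DataFrame:
    return pd.DataFrame([
        {"subject": d.subject_id, "class": d.symptom,
         "start": d.start, "end": d.end, "source": d.source}
        for d in diary
    ])


def truth_dict(truth: GroundTruth) -> dict:
    return {
        "true_events": [dataclasses.asdict(e) for e in truth.true_events],
        "task_schedule": [dataclasses.asdict(s) for s in truth.task_schedule],
        "baseline_severity": truth.baseline_severity,
    }
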