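"""Core data records shared across the pipeline.

Times are float seconds relative to the start of a recording scenario; the
CSV writers render them as ISO-8601 instants anchored at a fixed epoch.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PATIENT = "patient"
CONTROL = "control"

#: epoch used when rendering relative seconds as wall-clock instants
EPOCH_ISO = "2023-01-01T00:00:00"

#: symptom labels as they appear in the diary app's pre-defined list,
#: keyed by the physiological class the generator injects
APP_SYMPTOM_LABEL = {
    "tremor": "tremor",
    "bradykinesia": "slowness",
    "dyskinesia": "dyskinesia",
}


def symptom_group(label: str) -> str:
    """Collapse a diary symptom label to the two analysis groups.

    Tremor keeps its own group; every other movement symptom is pooled
    into ``"other"``.
    """
    return "tremor" if label == "tremor" else "other"


@dataclass
class AccelRecording:
    """One subject's timestamped tri-axial 50 Hz accelerometer signal."""

    subject_id: str
    cohort: str  # patient | control | unknown
    sampling_rate: float  # Hz
    t: np.ndarray  # (n,) seconds, strictly increasing
    xyz: np.ndarray  # (n, 3) acceleration in g units

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.t.shape[0] != self.xyz.shape[0]:
            raise ValueError("t and xyz length mismatch")
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be (n, 3)")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        """Span of the recording in seconds (0 for empty/singleton)."""
        if self.t.size < 2:
            return 0.0
        return float(self.t[-1] - self.t[0])


@dataclass
class DiaryEvent:
    """A patient-reported symptom interval."""

    subject_id: str
    symptom: str  # app label, e.g. "tremor", "slowness", "dyskinesia"
    start: float  # seconds
    end: float  # seconds
    source: str = "diary"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("event end precedes start")

    @property
    def duration_minutes(self) -> float:
        return (self.end - self.start) / 60.0

    @property
    def midpoint(self) -> float:
        """Centre of the reported interval, the analysis anchor."""
        return 0.5 * (self.start + self.end)

    @property
    def symptom_class(self) -> str:
        return symptom_group(self.symptom)


@dataclass
class TrueEvent:
    """Ground-truth symptom interval with its injected severity."""

    subject_id: str
    symptom: str  # physiological class: tremor | bradykinesia | dyskinesia
    start: float
    end: float
    severity: float  # 0-4 scale

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("event end precedes start")


@dataclass
class TaskSession:
    """One scheduled task performance in an in-clinic session."""

    subject_id: str
    visit: int
    session: int
    task: str
    drug_state: str  # ON | OFF
    start: float
    end: float


@dataclass
class GroundTruth:
    """Everything the generator knows that the analyses must discover."""

    true_events: list[TrueEvent] = field(default_factory=list)
    task_schedule: list[TaskSession] = field(default_factory=list)
    baseline_severity: dict = field(default_factory=dict)  # subject -> {symptom: 0-4}
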