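import numpy as np
import pytest

from wristpd.core import AccelRecording
from wristpd.synthdata import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """Rest-dominated tremor scenario for event-envelope integration tests.

    Resting tremor is characterised at rest, so the background activity is
    mostly sitting; tremor events are frequent enough that a short
    recording still yields a usable event tensor.
    """
    cfg = ScenarioConfig(n_patients=4, n_controls=1,
                         duration_per_subject=6 * 3600.0,
                         symptom_rates={"tremor": 24.0},
                         baseline_severity={},  # events only, quiet background
                         activity_mix={"sitting": 0.8, "standing": 0.2},
                         diary_jitter_sd=1.0, glitch_rate=0.0, seed=11)
    return cfg, generate_scenario(cfg)


@pytest.fixture()
def regular_recording():
    """A clean 50 Hz recording long enough for three blocks."""
    n = 3 * 65536 // 2 + 65536  # covers starts 0..HOP*3
    rng = np.random.default_rng(0)
    return AccelRecording("S01", "control", 50.0, np.arange(n) / 50.0,
                          rng.standard_normal((n, 3)) * 0.01 + [0, 0, 1.0])
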