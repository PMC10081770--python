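"""Simulate the default home-monitoring cohort and summarise what it holds.

Eight fluctuating-PD patients and eight controls, eight hours of 50 Hz
wrist accelerometry each, with ground-truth symptom events and a noisy
self-report diary.  Writes the diary, the ground truth and a scenario
summary under results/cohort/.
"""
import pathlib
import sys

from wristpd.pipeline import PipelineConfig, run_pipeline
from wristpd.synthdata import ScenarioConfig

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "cohort"


def main(seed: int = 1) -> None:
    config = PipelineConfig(scenario=ScenarioConfig(seed=seed), out_dir=str(OUT))
    manifest = run_pipeline(config, stages=["simulate"])
    print(f"wrote {len(manifest['artifacts'])} artifacts to {OUT}")
    for name in manifest["artifacts"]:
        print(" -", name)


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
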