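"""Accelerometer scores and drug/task effects on task-session data.

Trains one L2 proportional-odds scorer per symptom on spectral features
of dominant-hand task replicates, scores every replicate, and estimates
the ON-OFF contrast per task with a mixed model plus subject bootstrap.
The expected polarity: dyskinesia up, tremor and bradykinesia down under
levodopa.  Writes scores and effects under results/scoring/.
"""
import json
import pathlib
import sys

from wristpd.pipeline import PipelineConfig, run_pipeline
from wristpd.synthdata import ScenarioConfig

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "scoring"


def main(seed: int = 5) -> None:
    config = PipelineConfig(scenario=ScenarioConfig(), out_dir=str(OUT),
                            seeds={"sessions": seed, "score": seed + 1, "vae": 0})
    run_pipeline(config, stages=["score"])
    effects = json.loads((OUT / "task_effects.json").read_text())
    for symptom, rows in effects.items():
        overall = next(r for r in rows if r["task"] == "(all tasks)")
        print(f"{symptom:13s} ON-OFF delta {overall['drug_delta']:+.2f} "
              f"[{overall['ci_low']:+.2f}, {overall['ci_high']:+.2f}]")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 5)
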