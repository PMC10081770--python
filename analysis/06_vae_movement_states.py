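"""VAE movement-state embeddings and task classification.

Trains the 1500-400-20 fully connected VAE on >= 3000 ten-second windows
from a six-task scenario, classifies tasks from the latent means with an
MLP(50, 50) under grouped five-fold CV, checks that confusion clusters
within task families, and evaluates transfer to a fresh cohort.  Writes
vae_eval.json and the confusion matrix under results/vae/.
"""
import json
import pathlib
import sys

from wristpd.pipeline import PipelineConfig, run_pipeline
from wristpd.synthdata import ScenarioConfig

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "vae"


def main(seed: int = 3) -> None:
    config = PipelineConfig(scenario=ScenarioConfig(), out_dir=str(OUT),
                            vae_epochs=20, seeds={"sessions": 1, "score": 2,
                                                  "vae": seed})
    run_pipeline(config, stages=["vae"])
    ev = json.loads((OUT / "vae_eval.json").read_text())
    print(f"windows: {ev['n_windows']}, chance {ev['chance']:.3f}")
    print(f"within-cohort grouped five-fold accuracy: {ev['within_accuracy']:.3f}")
    print(f"same-family confusion {ev['same_family_confusion']:.3f} vs "
          f"cross-family {ev['cross_family_confusion']:.3f}")
    print(f"cross-scenario transfer accuracy: {ev['transfer_accuracy']:.3f}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 3)
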