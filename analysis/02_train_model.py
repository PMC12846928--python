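#!/usr/bin/env python
"""Train the dropout U-Net on the in-distribution training cohort.

Reads the cohort written by 01_generate_cohorts.py, trains the desk-scale
network (20 epochs, batch 8, left-right flips), and writes the checkpoint,
the loss trace and the learned per-layer spatial-concrete-dropout
probabilities under results/analysis/.
"""

import json
from pathlib import Path

import pandas as pd

from segqa.io import read_volume
from segqa.model import TrainConfig, build_model, save_checkpoint, train
from segqa.pipeline import derive_seeds

OUT = Path("results/analysis")
SEED = 1


def load_cohort(d: Path):
    cohort = []
    for img in sorted(d.glob("scan_*_image.nii.gz")):
        vol, _ = read_volume(img)
        msk, _ = read_volume(Path(str(img).replace("_image", "_mask")), is_mask=True)
        cohort.append((vol, msk))
    return cohort


def main() -> None:
    seeds = derive_seeds(SEED)
    cohort = load_cohort(OUT / "data" / "train")
    model = build_model(seed=seeds["model_init"])
    result = train(model, cohort, TrainConfig(seed=seeds["train"]))
    save_checkpoint(model, OUT / "model.npz")
    pd.DataFrame({"epoch": range(1, len(result.loss_trace) + 1),
                  "train_loss": result.loss_trace,
                  "val_loss": result.val_loss_trace}).to_csv(
        OUT / "training_trace.csv", index=False)
    (OUT / "dropout_probabilities.json").write_text(json.dumps({
        "per_layer": result.dropout_probabilities,
        "mean": result.mean_dropout_probability,
    }, indent=2))
    print(f"training loss {result.loss_trace[0]:.4f} -> {result.loss_trace[-1]:.4f} "
          f"over {len(result.loss_trace)} epochs")
    print(f"learned mean dropout probability {result.mean_dropout_probability:.3f} "
          f"across {len(result.dropout_probabilities)} dropout layers")


if __name__ == "__main__":
    main()
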