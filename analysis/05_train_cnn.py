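"""Train and evaluate the CNN on the standardized images (desk scale).

Uses the global 75/25 split of original images.  By default the training
partition is expanded with its exact quarter-turn rotations (seeds land
at arbitrary orientations); `--augment` runs the full 86-variant
deterministic expansion instead (slow).  Writes the evaluation summary
to results/cnn_summary.csv and the pooled confusion matrix to
results/confusion_cnn.csv.

At this scale (tens of training images per taxon, absolute size erased
by standardization) the image route is expected to trail the measured
six-variable route; it exists here to exercise the full protocol end to
end, not to reach its large-data accuracy.

Usage: python analysis/05_train_cnn.py [--epochs N] [--reps R] [--augment]
"""

import argparse
import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from seedtax import cnn
from seedtax import harness as har
from seedtax.augment import DEFAULT_PLAN

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--epochs", type=int, default=30)
    ap.add_argument("--reps", type=int, default=1)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--augment", action="store_true",
                    help="expand training images 86x (full protocol; slow)")
    ap.add_argument("--no-dihedral", action="store_true",
                    help="disable the default exact quarter-turn augmentation")
    args = ap.parse_args()

    rows = [r for r in csv.DictReader(
        (ROOT / "results" / "preprocess_manifest.csv").open())
        if r["excluded"] == "0"]
    std_dir = ROOT / "scratch" / "standard"
    x = np.stack([iio.imread(std_dir / r["file"].replace(".png", "_std.png"))
                  for r in rows]).astype(np.float32) / 255.0
    y = np.array([int(r["class_id"]) for r in rows])
    print(f"{len(x)} standardized images, {len(np.unique(y))} taxa")

    spec = cnn.ArchitectureSpec()
    net = cnn.build_network(spec, rng_seed=args.seed)
    print(f"network parameters: {cnn.count_parameters(net):,}")

    config = cnn.desk_train_config(max_epochs=args.epochs, rng_seed=args.seed)
    plan = DEFAULT_PLAN if args.augment else None
    results = cnn.run_cnn_repetitions(x, y, n_rep=args.reps, config=config,
                                      spec=spec, augment_plan=plan,
                                      dihedral=not args.no_dihedral)
    summary = har.summarize_accuracy(results, method="cnn")
    print(f"CNN test accuracy over {args.reps} repetition(s): "
          f"mean {summary.mean:.1f}% (min {summary.min:.1f}, "
          f"max {summary.max:.1f}, SD {summary.sd:.2f})")

    pd.DataFrame([{"method": "cnn", "min": summary.min, "max": summary.max,
                   "mean": summary.mean, "median": summary.median,
                   "sd": summary.sd, "n_parameters": cnn.count_parameters(net),
                   "epochs": args.epochs, "augmented": bool(plan)}]
                 ).round(2).to_csv(ROOT / "results" / "cnn_summary.csv",
                                   index=False)
    agg = har.aggregate_confusion(results)
    pd.DataFrame(agg).to_csv(ROOT / "results" / "confusion_cnn.csv", index=False)
    print("wrote cnn_summary.csv and confusion_cnn.csv under results/")


if __name__ == "__main__":
    main()
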