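"""Run the repeated-split LDA/QDA/RDF comparison on the feature table.

Each method is refit on a fresh per-taxon 75/25 split per repetition;
accuracy summaries (results/table2.csv), pooled row-percent confusion
matrices (results/confusion_<method>.csv), permutation importances
(results/importance.csv) and one-vs-rest AUCs (results/roc_<method>.csv)
are written.

Usage: python analysis/04_run_harness.py [--reps N] [--seed S]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from seedtax import harness as har
from seedtax.morphometrics import FEATURE_NAMES

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--reps", type=int, default=25)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    table = pd.read_csv(ROOT / "results" / "features.csv")
    har.validate_feature_table(table)
    x, y = har.table_to_xy(table)

    summaries = []
    importance_rows = []
    for method in ("lda", "qda", "rdf"):
        results = har.run_repetitions(method, table, n_rep=args.reps,
                                      base_seed=args.seed)
        summary = har.summarize_accuracy(results, method=method)
        summaries.append(summary)
        print(f"{method.upper()}: mean {summary.mean:.1f}% "
              f"(min {summary.min:.1f}, max {summary.max:.1f}, "
              f"median {summary.median:.1f}, SD {summary.sd:.2f})")
        agg = har.aggregate_confusion(results)
        pd.DataFrame(agg).to_csv(ROOT / "results" / f"confusion_{method}.csv",
                                 index=False)

        plan = har.split_per_class(table, rng_seed=args.seed)
        model = har._FITTERS[method](x[plan.train_idx], y[plan.train_idx],
                                     args.seed)
        prof = har.permutation_importance(model, x[plan.test_idx],
                                          y[plan.test_idx], rng_seed=args.seed)
        for name, imp in zip(prof.feature_names, prof.importances):
            importance_rows.append({"method": method, "feature": name,
                                    "importance": imp})
        aucs = har.roc_auc_ovr(model, x[plan.test_idx], y[plan.test_idx])
        pd.DataFrame([{"class": c, "auc": v["auc"]} for c, v in aucs.items()]
                     ).to_csv(ROOT / "results" / f"roc_{method}.csv", index=False)

    rows = [{"method": s.method, "min": s.min, "max": s.max, "mean": s.mean,
             "median": s.median, "sd": s.sd} for s in summaries]
    pd.DataFrame(rows).round(2).to_csv(ROOT / "results" / "table2.csv",
                                       index=False)
    pd.DataFrame(importance_rows).to_csv(ROOT / "results" / "importance.csv",
                                         index=False)
    print("wrote table2.csv, confusion/importance/roc tables under results/")


if __name__ == "__main__":
    main()
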