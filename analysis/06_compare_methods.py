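"""Merge the harness and CNN results into the final ranked comparison.

Reads results/table2.csv and results/cnn_summary.csv, ranks every method
by mean test accuracy, and writes results/report.json plus a combined
results/comparison.csv in the classic Min/Max/Mean/Median/SD layout.

Usage: python analysis/06_compare_methods.py
"""

from pathlib import Path

import pandas as pd

from seedtax.harness import HarnessSummary
from seedtax.report import compare_methods

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    frames = [pd.read_csv(ROOT / "results" / "table2.csv")]
    cnn_csv = ROOT / "results" / "cnn_summary.csv"
    if cnn_csv.exists():
        frames.append(pd.read_csv(cnn_csv)[["method", "min", "max", "mean",
                                            "median", "sd"]])
    else:
        print("note: no cnn_summary.csv found; comparing harness methods only")
    merged = pd.concat(frames, ignore_index=True)

    summaries = [HarnessSummary(method=r["method"], min=r["min"], max=r["max"],
                                mean=r["mean"], median=r["median"], sd=r["sd"],
                                n_repetitions=0)
                 for _, r in merged.iterrows()]
    report = compare_methods(summaries)
    (ROOT / "results" / "report.json").write_text(report.to_json())
    report.table().to_csv(ROOT / "results" / "comparison.csv", index=False)

    print("final ranking by mean test accuracy:")
    for row in report.rows:
        print(f"  {row['method']:>4}: mean {row['mean']:.1f}% "
              f"(min {row['min']:.1f}, max {row['max']:.1f}, SD {row['sd']:.2f})")
    if cnn_csv.exists():
        print("note: the CNN row reflects the scaled desk run (tens of "
              "training images per taxon); see docs/methods.md")


if __name__ == "__main__":
    main()
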