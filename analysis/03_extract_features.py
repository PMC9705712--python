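"""Measure the six morphometric variables on every kept frame.

Re-segments each raw frame (measurements are taken at full resolution,
not on the 128x128 classifier input), extracts area, perimeter, rectangle
sides, bend angle and pit count, and writes results/features.csv.  Also
reports how well the measurements track the generator's ground truth.

Usage: python analysis/03_extract_features.py
"""

import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from seedtax import preprocess as pp
from seedtax import synthetic as syn
from seedtax.morphometrics import FEATURE_NAMES, extract_features

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    img_dir = ROOT / "scratch" / "images"
    manifest = list(csv.DictReader((ROOT / "results" / "manifest.csv").open()))
    keep = {r["file"] for r in
            csv.DictReader((ROOT / "results" / "preprocess_manifest.csv").open())
            if r["excluded"] == "0"}
    out_csv = ROOT / "results" / "features.csv"

    bar_h = syn.SyntheticScene().metadata_bar_height
    measured, truth = [], []
    with out_csv.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["file", "class_id", "population_id", *FEATURE_NAMES])
        for row in manifest:
            if row["file"] not in keep:
                continue
            pixels = iio.imread(img_dir / row["file"])
            mask = pp.clean_mask(pp.segment_foreground(pixels),
                                 metadata_bar_height=bar_h).mask
            rec = extract_features(pixels, mask, class_id=int(row["class_id"]),
                                   population_id=row["population_id"])
            writer.writerow([row["file"], rec.class_id, rec.population_id,
                             *[getattr(rec, n) for n in FEATURE_NAMES]])
            measured.append(rec.as_vector())
            truth.append([float(row[n]) for n in FEATURE_NAMES])

    measured, truth = np.array(measured), np.array(truth)
    print(f"measured {len(measured)} seeds -> {out_csv}")
    for j, name in enumerate(FEATURE_NAMES):
        if np.std(truth[:, j]) > 0:
            r = np.corrcoef(measured[:, j], truth[:, j])[0, 1]
            print(f"  {name:>10}: correlation with ground truth r = {r:.3f}")


if __name__ == "__main__":
    main()
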