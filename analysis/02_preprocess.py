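"""Standardize raw frames to 128x128 classifier inputs.

Reads the frames listed in results/manifest.csv, runs the segmentation ->
contact check -> cleaning -> crop/pad -> rescale pipeline, writes the
standardized PNGs to scratch/standard and the per-frame outcome (kept or
excluded, with reason and bounding box) to results/preprocess_manifest.csv.

Usage: python analysis/02_preprocess.py
"""

import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from seedtax import preprocess as pp

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    img_dir = ROOT / "scratch" / "images"
    std_dir = ROOT / "scratch" / "standard"
    std_dir.mkdir(parents=True, exist_ok=True)
    manifest = ROOT / "results" / "manifest.csv"
    out_csv = ROOT / "results" / "preprocess_manifest.csv"

    rows = list(csv.DictReader(manifest.open()))
    kept = excluded = 0
    with out_csv.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["file", "class_id", "population_id", "excluded",
                         "reason", "r0", "c0", "r1", "c1"])
        for row in rows:
            pixels = iio.imread(img_dir / row["file"])
            result = pp.preprocess_image(pixels, source=row["file"])
            if isinstance(result, pp.Excluded):
                excluded += 1
                writer.writerow([row["file"], row["class_id"],
                                 row["population_id"], 1, result.reason,
                                 "", "", "", ""])
                continue
            kept += 1
            out_name = row["file"].replace(".png", "_std.png")
            iio.imwrite(std_dir / out_name,
                        (result.pixels * 255).round().astype(np.uint8))
            writer.writerow([row["file"], row["class_id"],
                             row["population_id"], 0, "", *result.bbox])
    print(f"standardized {kept} frames, excluded {excluded}; "
          f"outcomes in {out_csv}")


if __name__ == "__main__":
    main()
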