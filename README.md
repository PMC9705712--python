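# seedtax

Comparing classical morphometric discriminant analysis with a lightweight
convolutional network for seed-based plant identification, on synthetic
microscope-style seed images with analytic ground truth.

## The problem

In several aquatic plant genera the vegetative organs are too plastic to
identify species reliably; seed shape — overall size, the degree of
curvature of the seed axis, and the pitted sculpture of the seed coat —
is the diagnostic character of choice.  Two identification routes are
compared under a common protocol:

* **morphometrics**: six measured variables per seed — projected area
  `A`, outline perimeter `P`, the sides `a >= b` of the minimum-area
  rotated bounding rectangle, the axis bend angle `beta` (180° =
  straight, ~90° = U-shaped), and the seed-coat pit count — classified
  with Gaussian discriminants using the score

  `delta_k(x) = -1/2 ln|S_k| - 1/2 (x-mu_k)' S_k^{-1} (x-mu_k) + ln pi_k`

  with pooled covariance (LDA) or per-class covariance (QDA), plus a
  100-tree random decision forest (RDF); each method is refit on 100
  fresh per-taxon 75/25 splits and summarized as Min/Max/Mean/Median/SD
  accuracy, with pooled row-percent confusion matrices, permutation
  feature importances and one-vs-rest ROC/AUC;

* **deep learning**: a small CNN (four conv(3×3)+BN+ReLU+maxpool stages
  with 16/32/64/128 filters, two dense layers, softmax over 12 classes;
  168,060 trainable parameters) trained on standardized 128×128 seed
  images, expanded 86-fold by a fixed deterministic augmentation scheme
  (5 brightness/contrast + 6 sharpen + 12 blur + 61 rotation + 2 flip
  variants per image).

No real micrographs ship with the package.  Instead a synthetic
generator renders 1024×768 8-bit frames — one bent-capsule seed with
countable pits, debris blobs, a metadata bar, Gaussian noise — with
exact ground-truth masks and morphometrics, organized as 12 taxa in 28
populations (1299 frames in the full layout).  Every downstream stage is
validated against that ground truth.  See `docs/methods.md` for models,
parameters and limitations.

## Worked example

```python
import numpy as np
from seedtax import synthetic as syn, preprocess as pp, harness as har
from seedtax.report import features_from_images

# 28-population study layout, scaled to 4 images per population
specs = syn.table1_population_specs(separation=1.5, rng_seed=0,
                                    images_per_population=4)
images = syn.generate_image_dataset(specs, rng_seed=0)
standard, excluded = pp.preprocess_dataset(images)
print(len(images), "frames,", len(excluded), "excluded")

table = features_from_images(images)
for method in ("lda", "qda", "rdf"):
    results = har.run_repetitions(method, table, n_rep=10, base_seed=0)
    s = har.summarize_accuracy(results, method)
    print(f"{method}: mean {s.mean:.1f}%  (min {s.min:.1f}, max {s.max:.1f}, "
          f"SD {s.sd:.2f})")
```

prints (one CPU core, about two minutes, most of it rendering):

```
112 frames, 0 excluded
lda: mean 92.9%  (min 85.7, max 100.0, SD 5.05)
qda: mean 92.9%  (min 85.7, max 96.4, SD 3.76)
rdf: mean 97.5%  (min 92.9, max 100.0, SD 2.94)
```

i.e. at this class separation the six measured variables identify most
synthetic seeds; with only three training seeds in the rarest taxon the
forest edges out the Gaussian discriminants here, and the Min–Max spread
shows why repeated splits (not a single one) are summarized.  The
numbered scripts under `analysis/`
run the same stages with persisted artifacts:

```sh
python analysis/01_generate_dataset.py      # render frames + manifest
python analysis/02_preprocess.py            # standardize to 128x128
python analysis/03_extract_features.py      # measure the six variables
python analysis/04_run_harness.py           # LDA/QDA/RDF repetitions
python analysis/05_train_cnn.py             # desk-scale CNN training
python analysis/06_compare_methods.py       # ranked comparison table
```

Tables land in `results/` (images in `scratch/`, which is disposable).

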