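"""End-to-end comparison: rank methods and emit table/confusion/ROC artifacts.

The report mirrors the familiar comparison-table layout: one row per
method with Min/Max/Mean/Median accuracy in percent (1 decimal) and SD
(2 decimals), rows ordered by mean accuracy descending with an
alphabetical tie-break; aggregated row-percent confusion matrices and
per-class one-vs-rest AUC values ride along.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cnn as cnn_mod
from . import harness, preprocess, synthetic
from .morphometrics import FEATURE_NAMES, extract_features
from .harness import HarnessSummary


@dataclass
class ComparisonReport:
    """Ranked per-method summaries plus confusion/AUC side tables."""

    rows: list            # dicts: method, min, max, mean, median, sd
    confusions: dict      # method -> row-percent matrix (list of lists)
    aucs: dict            # method -> {class: auc}
    metadata: dict

    def to_json(self) -> str:
        payload = {"rows": self.rows, "confusions": self.confusions,
                   "aucs": self.aucs, "metadata": self.metadata}
        return json.dumps(payload, indent=2, sort_keys=True)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def compare_methods(summaries: Sequence[HarnessSummary],
                    confusions: dict | None = None,
                    aucs: dict | None = None,
                    metadata: dict | None = None) -> ComparisonReport:
    """Rank method summaries by mean accuracy (desc), tie-break on name."""
    names = [s.method for s in summaries]
    if len(set(names)) != len(names):
        raise ValueError("duplicate method names")
    if not summaries:
        raise ValueError("need at least one summary")
    ranked = sorted(summaries, key=lambda s: (-s.mean, s.method))
    rows = [
        {"method": s.method,
         "min": round(s.min, 1), "max": round(s.max, 1),
         "mean": round(s.mean, 1), "median": round(s.median, 1),
         "sd": round(s.sd, 2), "n_repetitions": s.n_repetitions}
        for s in ranked
    ]
    return ComparisonReport(rows=rows,
                            confusions=confusions or {},
                            aucs=aucs or {},
                            metadata=metadata or {})


@dataclass
class PipelineConfig:
    """Desk-scale end-to-end run configuration.

    The full study layout (28 populations, 1299 frames, 100 repetitions,
    86x augmentation) is available by lifting these limits, but the
    defaults keep a complete run on one CPU core in minutes.
    """

    separation: float = 1.5
    images_per_population: int | None = 4   # None = full study counts
    methods: tuple[str, ...] = ("lda", "qda", "rdf")
    n_repetitions: int = 10
    include_cnn: bool = False
    cnn_epochs: int = 30
    cnn_repetitions: int = 1
    cnn_augment: bool = False
    rng_seed: int = 0


def make_separable_image_set(n_per_class: int, rng_seed: int = 11,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Render and preprocess the well-separated 12-class image set.

    Returns ``(pixels, labels)`` with pixels of shape (N, 128, 128) in
    [0, 1]; class geometries come from the aspect-ratio x bend-angle grid
    of :func:`seedtax.synthetic.image_separable_phenotypes`, one
    population per class.
    """
    phenos = synthetic.image_separable_phenotypes()
    specs = [synthetic.PopulationSpec(phenotype=p, population_id=f"p{p.class_id}",
                                      n_images=n_per_class)
             for p in phenos]
    standard, excluded = preprocess.preprocess_dataset(
        synthetic.iter_image_dataset(specs, rng_seed=rng_seed,
                                     population_effect=0.0))
    assert not excluded, "separable preset must not produce exclusions"
    return (np.stack([s.pixels for s in standard]),
            np.array([s.class_id for s in standard]))


def run_desk_cnn_demo(rng_seed: int = 0, n_train_per_class: int = 20,
                      n_test_per_class: int = 5, max_epochs: int = 15,
                      ) -> tuple[float, "cnn_mod.TrainedClassifier"]:
    """Desk-scale CNN demonstration: train on separable synthetics, report
    held-out accuracy.

    Training uses the package's desk preset: the image-separable class
    grid, exact quarter-turn augmentation of the training partition, the
    default architecture with dropout disabled (the augmentation is the
    regularizer at this scale), Adam at 1e-3, batch 32.
    """
    from .augment import dihedral_rotations

    x, y = make_separable_image_set(n_train_per_class + n_test_per_class,
                                    rng_seed=rng_seed)
    train_idx, test_idx = [], []
    for k in range(12):
        idx = np.flatnonzero(y == k)
        train_idx.extend(idx[:n_train_per_class])
        test_idx.extend(idx[n_train_per_class:])
    train_idx, test_idx = np.asarray(train_idx), np.asarray(test_idx)
    x_aug, y_aug = dihedral_rotations(x[train_idx], y[train_idx], flips=False)
    spec = cnn_mod.ArchitectureSpec(dropout_rates=(0.0, 0.0))
    net = cnn_mod.build_network(spec, rng_seed=rng_seed)
    cfg = cnn_mod.desk_train_config(max_epochs=max_epochs, rng_seed=rng_seed)
    model = cnn_mod.train(net, x_aug, cnn_mod.one_hot(y_aug, 12), cfg)
    acc, _ = cnn_mod.evaluate(model, x[test_idx], y[test_idx])
    return acc, model


def features_from_images(images, use_truth_mask: bool = False) -> pd.DataFrame:
    """Measure the six variables on preprocessed frames -> feature table."""
    rows = []
    for im in images:
        if use_truth_mask:
            mask = im.truth_mask
        else:
            raw = preprocess.segment_foreground(im.pixels)
            mask = preprocess.clean_mask(
                raw, metadata_bar_height=synthetic.SyntheticScene().metadata_bar_height
            ).mask
        rec = extract_features(im.pixels, mask, class_id=im.class_id,
                               population_id=im.population_id)
        rows.append({**{n: getattr(rec, n) for n in FEATURE_NAMES},
                     "class_id": rec.class_id,
                     "population_id": rec.population_id})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path | None = None) -> ComparisonReport:
    """Generate -> preprocess -> features -> harness (-> CNN) -> report."""
    pop_specs = synthetic.table1_population_specs(
        separation=config.separation, rng_seed=config.rng_seed,
        images_per_population=config.images_per_population)
    images = synthetic.generate_image_dataset(pop_specs, rng_seed=config.rng_seed)
    standard, excluded = preprocess.preprocess_dataset(images)
    table = features_from_images(images)

    summaries, confusions, aucs = [], {}, {}
    for method in config.methods:
        results = harness.run_repetitions(method, table,
                                          n_rep=config.n_repetitions,
                                          base_seed=config.rng_seed)
        summaries.append(harness.summarize_accuracy(results, method=method))
        confusions[method] = harness.aggregate_confusion(results).tolist()
        plan = harness.split_per_class(table, rng_seed=config.rng_seed)
        x, y = harness.table_to_xy(table)
        fitter = harness._FITTERS[method]
        model = fitter(x[plan.train_idx], y[plan.train_idx], config.rng_seed)
        aucs[method] = {str(c): v["auc"] for c, v in
                        harness.roc_auc_ovr(model, x[plan.test_idx],
                                            y[plan.test_idx]).items()}

    if config.include_cnn:
        pixels = np.stack([s.pixels for s in standard])
        labels = np.array([s.class_id for s in standard])
        cfg = cnn_mod.TrainConfig(learning_rate=1e-3,
                                  max_epochs=config.cnn_epochs,
                                  patience=config.cnn_epochs,
                                  rng_seed=config.rng_seed)
        from .augment import DEFAULT_PLAN
        plan = DEFAULT_PLAN if config.cnn_augment else None
        results = cnn_mod.run_cnn_repetitions(
            pixels, labels, config.cnn_repetitions, cfg, augment_plan=plan)
        summaries.append(harness.summarize_accuracy(results, method="cnn"))
        confusions["cnn"] = harness.aggregate_confusion(results).tolist()

    config_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:16]
    metadata = {
        "config": asdict(config),
        "config_hash": config_hash,
        "n_images": len(images),
        "n_excluded": len(excluded),
        "n_populations": len(pop_specs),
    }
    report = compare_methods(summaries, confusions, aucs, metadata)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        report.table().to_csv(out / "table2.csv", index=False)
        for method, cm in report.confusions.items():
            pd.DataFrame(cm).to_csv(out / f"confusion_{method}.csv", index=False)
        for method, per_class in report.aucs.items():
            pd.DataFrame(sorted(per_class.items()),
                         columns=["class", "auc"]
                         ).to_csv(out / f"roc_{method}.csv", index=False)
    return report
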