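"""Repeated-split classification harness for six-feature seed tables.

Three classifiers are compared under a common protocol: Gaussian
discriminants with pooled (LDA) or per-class (QDA) covariance, and a
random decision forest (RDF).  Each repetition draws a fresh per-class
75/25 split, refits from scratch, and records the test-set confusion
matrix; repetitions are aggregated into min/max/mean/median/SD accuracy
summaries, pooled row-percent confusion matrices, permutation feature
importances, and one-vs-rest ROC/AUC curves.

LDA/QDA use the Gaussian discriminant score

    delta_k(x) = -1/2 ln|S_k| - 1/2 (x - mu_k)^T S_k^{-1} (x - mu_k) + ln pi_k

with a shared pooled S for LDA; a small ridge (1e-6 of the mean diagonal)
keeps per-class covariances invertible on small classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc, confusion_matrix, roc_curve

from .morphometrics import FEATURE_NAMES


# ---------------------------------------------------------------------------
# Feature tables and splits
# ---------------------------------------------------------------------------

def validate_feature_table(table: pd.DataFrame) -> None:
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing or "class_id" not in table.columns:
        raise ValueError(f"feature table missing columns: {missing + ['class_id']}")
    if table[list(FEATURE_NAMES)].isna().any().any():
        raise ValueError("feature table contains missing values")
    counts = table["class_id"].value_counts()
    if len(counts) < 2:
        raise ValueError("feature table needs at least 2 classes")
    if counts.min() < 4:
        raise ValueError("every class needs at least 4 rows")


def table_to_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    return (table[list(FEATURE_NAMES)].to_numpy(dtype=float),
            table["class_id"].to_numpy())


@dataclass
class SplitPlan:
    """Per-class (stratified) train/test row indices."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    train_frac: float
    stratified: bool
    rng_seed: int

    def __post_init__(self):
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test overlap")


def split_per_class(table: pd.DataFrame, train_frac: float = 0.75,
                    rng_seed: int = 0) -> SplitPlan:
    """Stratified split; per-class test size is ceil(n_k * (1 - train_frac))."""
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must lie in (0, 1)")
    y = table["class_id"].to_numpy()
    rng = np.random.default_rng(rng_seed)
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 rows")
        perm = rng.permutation(idx)
        n_test = math.ceil(len(idx) * (1.0 - train_frac))
        n_test = min(n_test, len(idx) - 1)  # keep at least one training row
        test.append(perm[:n_test])
        train.append(perm[n_test:])
    return SplitPlan(train_idx=np.sort(np.concatenate(train)),
                     test_idx=np.sort(np.concatenate(test)),
                     train_frac=train_frac, stratified=True, rng_seed=rng_seed)


# ---------------------------------------------------------------------------
# Gaussian discriminant models
# ---------------------------------------------------------------------------

@dataclass
class GaussianDiscriminantModel:
    """Fitted LDA ('pooled') or QDA ('per-class') Gaussian classifier."""

    kind: str                    # "lda" | "qda"
    classes: np.ndarray
    means: np.ndarray            # (K, p)
    covs: np.ndarray             # (K, p, p); identical slices for LDA
    priors: np.ndarray           # (K,)
    ridge: float

    def _log_scores(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        scores = np.empty((x.shape[0], len(self.classes)))
        for k in range(len(self.classes)):
            cov = self.covs[k]
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                raise np.linalg.LinAlgError("covariance not positive definite")
            diff = x - self.means[k]
            sol = np.linalg.solve(cov, diff.T).T
            maha = np.einsum("ij,ij->i", diff, sol)
            scores[:, k] = -0.5 * logdet - 0.5 * maha + np.log(self.priors[k])
        return scores

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        return self._log_scores(x)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self._log_scores(x), axis=1)]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        s = self._log_scores(x)
        return np.exp(s - logsumexp(s, axis=1, keepdims=True))


def _fit_gaussian(x: np.ndarray, y: np.ndarray, kind: str,
                  ridge: float) -> GaussianDiscriminantModel:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    k, p = len(classes), x.shape[1]
    means = np.empty((k, p))
    priors = np.empty(k)
    scatters = np.zeros((k, p, p))
    counts = np.empty(k, dtype=int)
    for i, cls in enumerate(classes):
        xc = x[y == cls]
        counts[i] = len(xc)
        means[i] = xc.mean(axis=0)
        priors[i] = len(xc) / len(x)
        d = xc - means[i]
        scatters[i] = d.T @ d
    eps = ridge * np.trace(x.T @ x / len(x)) / p
    if kind == "lda":
        pooled = scatters.sum(axis=0) / max(len(x) - k, 1)
        pooled = pooled + eps * np.eye(p)
        covs = np.repeat(pooled[None], k, axis=0)
    elif kind == "qda":
        covs = np.empty((k, p, p))
        for i in range(k):
            denom = max(counts[i] - 1, 1)
            covs[i] = scatters[i] / denom + eps * np.eye(p)
    else:
        raise ValueError("kind must be 'lda' or 'qda'")
    return GaussianDiscriminantModel(kind=kind, classes=classes, means=means,
                                     covs=covs, priors=priors, ridge=ridge)


def fit_lda(x: np.ndarray, y: np.ndarray,
            ridge: float = 1e-6) -> GaussianDiscriminantModel:
    """Pooled-covariance Gaussian discriminant (linear boundaries)."""
    return _fit_gaussian(x, y, "lda", ridge)


def fit_qda(x: np.ndarray, y: np.ndarray,
            ridge: float = 1e-6) -> GaussianDiscriminantModel:
    """Per-class-covariance Gaussian discriminant (quadratic boundaries)."""
    return _fit_gaussian(x, y, "qda", ridge)


def fit_rdf(x: np.ndarray, y: np.ndarray, n_estimators: int = 100,
            rng_seed: int = 0) -> RandomForestClassifier:
    """Random decision forest: bootstrap trees with sqrt-p feature subsetting."""
    if n_estimators < 1:
        raise ValueError("n_estimators must be >= 1")
    model = RandomForestClassifier(n_estimators=n_estimators,
                                   random_state=rng_seed, n_jobs=1)
    model.fit(x, y)
    return model


_FITTERS = {
    "lda": lambda x, y, seed: fit_lda(x, y),
    "qda": lambda x, y, seed: fit_qda(x, y),
    "rdf": lambda x, y, seed: fit_rdf(x, y, rng_seed=seed),
}


# ---------------------------------------------------------------------------
# Repetition loop and aggregation
# ---------------------------------------------------------------------------

@dataclass
class RepetitionResult:
    """One repetition: accuracy and the K x K confusion count matrix."""

    index: int
    accuracy: float
    confusion: np.ndarray  # rows = true class, columns = predicted

    def __post_init__(self):
        total = self.confusion.sum()
        if total and not np.isclose(self.accuracy,
                                    np.trace(self.confusion) / total):
            raise ValueError("accuracy inconsistent with confusion trace")


@dataclass
class HarnessSummary:
    """Min/max/mean/median/SD of accuracy over repetitions, in percent."""

    method: str
    min: float
    max: float
    mean: float
    median: float
    sd: float
    n_repetitions: int

    def __post_init__(self):
        if not (self.min <= self.median <= self.max) or self.sd < 0:
            raise ValueError("inconsistent summary statistics")


@dataclass
class ImportanceProfile:
    """Mean accuracy drop per feature under within-column permutation."""

    feature_names: tuple
    importances: np.ndarray
    n_shuffles: int
    rng_seed: int


def run_repetitions(method: str, table: pd.DataFrame, n_rep: int = 100,
                    base_seed: int = 0, train_frac: float = 0.75,
                    ) -> list[RepetitionResult]:
    """Fresh split (seed = base_seed + r) -> fresh fit -> test confusion."""
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if method not in _FITTERS:
        raise ValueError(f"unknown method {method!r}")
    validate_feature_table(table)
    x, y = table_to_xy(table)
    classes = np.unique(y)
    results = []
    for r in range(n_rep):
        seed = base_seed + r
        plan = split_per_class(table, train_frac=train_frac, rng_seed=seed)
        model = _FITTERS[method](x[plan.train_idx], y[plan.train_idx], seed)
        pred = model.predict(x[plan.test_idx])
        cm = confusion_matrix(y[plan.test_idx], pred, labels=classes)
        acc = float(np.trace(cm) / cm.sum())
        results.append(RepetitionResult(index=r, accuracy=acc, confusion=cm))
    return results


def aggregate_confusion(results: list[RepetitionResult],
                        mode: str = "pooled") -> np.ndarray:
    """Row-percent confusion matrix over all repetitions.

    ``pooled`` sums counts over repetitions before row-normalizing;
    ``per_rep_mean`` averages the per-repetition row-percent matrices.
    """
    if not results:
        raise ValueError("no repetition results")
    if mode == "pooled":
        total = np.sum([r.confusion for r in results], axis=0).astype(float)
        rows = total.sum(axis=1, keepdims=True)
        return 100.0 * total / np.where(rows == 0, 1, rows)
    if mode == "per_rep_mean":
        mats = []
        for r in results:
            cm = r.confusion.astype(float)
            rows = cm.sum(axis=1, keepdims=True)
            mats.append(100.0 * cm / np.where(rows == 0, 1, rows))
        return np.mean(mats, axis=0)
    raise ValueError("mode must be 'pooled' or 'per_rep_mean'")


def summarize_accuracy(results: list[RepetitionResult],
                       method: str = "") -> HarnessSummary:
    """Table-style summary of per-repetition accuracies, in percent."""
    acc = 100.0 * np.array([r.accuracy for r in results], dtype=float)
    if acc.size == 0:
        raise ValueError("no repetition results")
    sd = float(np.std(acc, ddof=1)) if acc.size > 1 else 0.0
    return HarnessSummary(method=method, min=float(acc.min()),
                          max=float(acc.max()), mean=float(acc.mean()),
                          median=float(np.median(acc)), sd=sd,
                          n_repetitions=acc.size)


def permutation_importance(model, x_test: np.ndarray, y_test: np.ndarray,
                           n_shuffles: int = 10, rng_seed: int = 0,
                           feature_names: tuple = FEATURE_NAMES,
                           ) -> ImportanceProfile:
    """Mean accuracy drop when one feature column is shuffled label-free."""
    rng = np.random.default_rng(rng_seed)
    baseline = float(np.mean(model.predict(x_test) == y_test))
    p = x_test.shape[1]
    importances = np.zeros(p)
    for j in range(p):
        drops = []
        for _ in range(n_shuffles):
            xp = x_test.copy()
            xp[:, j] = xp[rng.permutation(len(xp)), j]
            drops.append(baseline - float(np.mean(model.predict(xp) == y_test)))
        importances[j] = np.mean(drops)
    return ImportanceProfile(feature_names=tuple(feature_names),
                             importances=importances,
                             n_shuffles=n_shuffles, rng_seed=rng_seed)


def roc_auc_ovr(model, x_test: np.ndarray, y_test: np.ndarray) -> dict:
    """One-vs-rest ROC points and trapezoid AUC per class, from posteriors."""
    proba = model.predict_proba(x_test)
    classes = model.classes if hasattr(model, "classes") else model.classes_
    out = {}
    for k, cls in enumerate(classes):
        binary = (np.asarray(y_test) == cls).astype(int)
        if binary.min() == binary.max():
            continue  # class absent (or exclusive) in the test set
        fpr, tpr, _ = roc_curve(binary, proba[:, k])
        out[cls] = {"fpr": fpr, "tpr": tpr, "auc": float(auc(fpr, tpr))}
    return out
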