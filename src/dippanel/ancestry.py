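"""Biogeographic-ancestry assignment and its evaluation protocol.

The evaluation mirrors the standard design for continental-ancestry panels:
a stratified 75/25 train/test split over three continental classes (Africa,
East Asia, Other), a classifier trained on the training genotypes, and a
prediction-by-truth confusion matrix whose accuracy carries an exact
Clopper–Pearson 95% confidence interval.

The reference classifier is a transparent allele-frequency likelihood model
(per-class per-locus deletion frequencies with a 0.5 pseudocount per allele;
an individual is scored by the summed log HWE genotype probability under each
class, uniform prior).  It is a scikit-learn estimator so that externally
trained learners (gradient boosting, SVM, random forests...) can be swapped
in behind the same fit/predict surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.proportion import proportion_confint

from .io import GenotypeDataset, ParameterError


def stratified_split(
    ds: GenotypeDataset,
    train_fraction: float = 0.75,
    seed: int = 0,
    stratify_by: str = "continent",
) -> tuple[GenotypeDataset, GenotypeDataset]:
    """Per-class random split of a dataset at the given training fraction."""
    if not (0.0 < train_fraction < 1.0):
        raise ParameterError("train_fraction must lie in (0, 1)")
    labels = ds.samples[stratify_by].astype(str)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    for cls in pd.unique(labels):
        idx = np.flatnonzero((labels == cls).to_numpy())
        if len(idx) < 2:
            raise ParameterError(f"class {cls!r} has fewer than 2 individuals")
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(rng.permutation(idx)[:n_train])
    mask = np.zeros(ds.n_samples, dtype=bool)
    mask[train_idx] = True

    def take(m: np.ndarray) -> GenotypeDataset:
        return GenotypeDataset(
            ds.loci, ds.samples.loc[m].reset_index(drop=True), ds.calls[m]
        )

    return take(mask), take(~mask)


class FrequencyLikelihoodClassifier(BaseEstimator, ClassifierMixin):
    """Naive allele-frequency likelihood classifier for biallelic genotypes.

    fit(X, y) expects X as a deletion-dosage matrix (0/1/2, NaN for missing)
    and y as class labels.  Per class and locus the deletion frequency is
    estimated with a pseudocount of ``pseudocount`` per allele, so learned
    frequencies never reach 0 or 1.  predict scores each individual by the
    summed log HWE genotype probability under each class's frequencies with a
    uniform class prior; ties break deterministically by label order.

    Attributes
    ----------
    classes_ : ndarray of class labels, sorted
    freqs_ : ndarray (n_classes, n_loci) learned deletion frequencies
    """

    def __init__(self, pseudocount: float = 0.5):
        self.pseudocount = pseudocount

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ParameterError("X must be 2-D with one label per row")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ParameterError("need >= 2 classes")
        freqs = np.empty((len(self.classes_), X.shape[1]))
        for i, cls in enumerate(self.classes_):
            sub = X[y == cls]
            n_called = np.sum(~np.isnan(sub), axis=0)
            d_alleles = np.nansum(sub, axis=0)
            freqs[i] = (d_alleles + self.pseudocount) / (
                2 * n_called + 2 * self.pseudocount
            )
        self.freqs_ = freqs
        self.n_features_in_ = X.shape[1]
        return self

    def _log_likelihoods(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        p = self.freqs_  # (C, L)
        logg = np.stack(
            [np.log((1 - p) ** 2), np.log(2 * p * (1 - p)), np.log(p**2)]
        )  # (3, C, L)
        out = np.zeros((X.shape[0], p.shape[0]))
        for g in (0, 1, 2):
            mask = X == g  # (N, L)
            out += mask @ logg[g].T
        return out

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "freqs_")
        ll = self._log_likelihoods(X)
        return np.exp(ll - logsumexp(ll, axis=1, keepdims=True))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "freqs_")
        ll = self._log_likelihoods(X)
        # argmax takes the first (label-order) class on ties
        return self.classes_[np.argmax(ll, axis=1)]


def classify(model: FrequencyLikelihoodClassifier, genotypes) -> tuple[str | None, np.ndarray]:
    """Assign one individual: (label, posterior vector over model.classes_).

    Returns label None (a no-call) when every locus is missing.
    """
    g = np.asarray(genotypes, dtype=float).reshape(1, -1)
    if np.all(np.isnan(g)):
        return None, np.full(len(model.classes_), 1.0 / len(model.classes_))
    posterior = model.predict_proba(g)[0]
    return str(model.predict(g)[0]), posterior


@dataclass
class ConfusionMatrix:
    """Prediction-by-truth counts with accuracy and exact binomial 95% CI."""

    labels: list[str]
    counts: np.ndarray  # rows: predicted, cols: true
    accuracy: float
    ci_low: float
    ci_high: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.labels, name="prediction"),
            columns=pd.Index(self.labels, name="truth"),
        )


def clopper_pearson(successes: int, total: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper–Pearson) two-sided binomial confidence interval."""
    if total < 1 or not (0 <= successes <= total):
        raise ParameterError("need 0 <= successes <= total, total >= 1")
    low, high = proportion_confint(successes, total, alpha=alpha, method="beta")
    return float(low), float(high)


def evaluate(predictions, truth, labels: list[str] | None = None) -> ConfusionMatrix:
    """Confusion matrix, accuracy and Clopper–Pearson 95% CI."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ParameterError("predictions and truth must have equal length")
    if labels is None:
        labels = sorted(set(truth) | set(predictions))
    index = {lbl: i for i, lbl in enumerate(labels)}
    for v in np.concatenate([predictions, truth]):
        if v not in index:
            raise ParameterError(f"label {v!r} outside the class set {labels}")
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for p, t in zip(predictions, truth):
        counts[index[p], index[t]] += 1
    return confusion_from_counts(labels, counts)


def confusion_from_counts(labels: list[str], counts: np.ndarray) -> ConfusionMatrix:
    """Build a ConfusionMatrix (accuracy + exact CI) from a counts matrix."""
    counts = np.asarray(counts, dtype=int)
    if (counts < 0).any():
        raise ParameterError("counts must be nonnegative")
    total = int(counts.sum())
    correct = int(np.trace(counts))
    accuracy = correct / total
    low, high = clopper_pearson(correct, total)
    return ConfusionMatrix(list(labels), counts, accuracy, low, high)


def ancestry_evaluation(
    ds: GenotypeDataset,
    classifier=None,
    train_fraction: float = 0.75,
    seed: int = 0,
    stratify_by: str = "continent",
) -> ConfusionMatrix:
    """End-to-end evaluation: stratified split, fit, predict, confusion matrix."""
    clf = classifier if classifier is not None else FrequencyLikelihoodClassifier()
    train, test = stratified_split(ds, train_fraction, seed, stratify_by)
    clf.fit(train.deletion_dosage(), train.samples[stratify_by].to_numpy())
    preds = clf.predict(test.deletion_dosage())
    return evaluate(preds, test.samples[stratify_by].to_numpy())
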