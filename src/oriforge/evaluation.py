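"""Classification metrics and the cross-validation harness.

Metrics are ACC (thresholded accuracy), Matthews correlation coefficient
(0 by convention when any confusion-matrix margin is empty) and AUC (the
Mann-Whitney probability that a random positive outscores a random negative,
ties counted one half).  Cross-validation is stratified k-fold (k=10 by
default); within each training fold a stratified 90/10 split provides the
early-stopping validation set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import classifier as clf
from .zcurve import ZSpaceConfig, encode_batch


@dataclass(frozen=True)
class MetricsReport:
    acc: float
    mcc: float
    auc: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class CVResult:
    folds: tuple[MetricsReport, ...]
    fold_assignment: np.ndarray  # test-fold index per sample

    @property
    def k(self) -> int:
        return len(self.folds)

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(f, metric) for f in self.folds]))

    def std(self, metric: str) -> float:
        return float(np.std([getattr(f, metric) for f in self.folds]))

    def summary(self) -> dict[str, float]:
        return {
            f"{m}_{s}": getattr(self, s)(m)
            for m in ("acc", "mcc", "auc")
            for s in ("mean", "std")
        }


def _check(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if y.size == 0:
        raise ValueError("metrics are undefined on empty input")
    if y.shape != s.shape:
        raise ValueError("labels and scores must have the same length")
    return y, s


def accuracy(labels, scores, threshold: float = 0.5) -> float:
    """Fraction of samples whose thresholded score equals the label."""
    y, s = _check(labels, scores)
    return float(np.mean((s >= threshold).astype(int) == y))


def mcc(labels, scores, threshold: float = 0.5) -> float:
    """Matthews correlation coefficient of the thresholded confusion matrix."""
    y, s = _check(labels, scores)
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def auc(labels, scores) -> float:
    """Area under the ROC curve; requires both classes to be present."""
    y, s = _check(labels, scores)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC is undefined with a single class")
    return float(roc_auc_score(y, s))


def evaluate(labels, scores, threshold: float = 0.5) -> MetricsReport:
    y, s = _check(labels, scores)
    return MetricsReport(
        acc=accuracy(y, s, threshold),
        mcc=mcc(y, s, threshold),
        auc=auc(y, s),
        n_pos=int(np.sum(y == 1)),
        n_neg=int(np.sum(y == 0)),
    )


def kfold_split(n_pos: int, n_neg: int, k: int, seed: int) -> np.ndarray:
    """Stratified, shuffled fold assignment for [pos..., neg...] ordering.

    Returns an integer array of length n_pos + n_neg giving each sample's
    test fold; per class, fold sizes differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if min(n_pos, n_neg) < k:
        raise ValueError(f"each class needs >= k={k} members")
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    return _assign_folds(labels, k, seed)


def _assign_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return assignment


def cross_validate(
    sequences,
    labels,
    zconfig: ZSpaceConfig | None = None,
    cconfig: "clf.ClassifierConfig | None" = None,
    tconfig: "clf.TrainConfig | None" = None,
    k: int = 10,
    threshold: float = 0.5,
    val_fraction: float = 0.1,
) -> CVResult:
    """Stratified k-fold cross-validation of the full encode-train-score path.

    ``sequences`` may be DnaSequence objects or an already-encoded matrix.
    """
    zconfig = zconfig or ZSpaceConfig()
    tconfig = tconfig or clf.TrainConfig()
    y = np.asarray(labels)
    already_encoded = isinstance(sequences, np.ndarray) or (
        len(sequences) > 0 and isinstance(sequences[0], np.ndarray)
    )
    X = np.asarray(sequences) if already_encoded else encode_batch(sequences, zconfig)
    if cconfig is None:
        cconfig = clf.ClassifierConfig(input_dim=X.shape[1])
    if min(np.sum(y == 1), np.sum(y == 0)) < k:
        raise ValueError(f"each class needs >= k={k} members")
    assignment = _assign_folds(y, k, tconfig.seed)
    folds = []
    for fold in range(k):
        test = assignment == fold
        Xtr, Xva, ytr, yva = train_test_split(
            X[~test], y[~test], test_size=val_fraction, stratify=y[~test],
            random_state=tconfig.seed + fold,
        )
        model = clf.train((Xtr, ytr), (Xva, yva), cconfig, tconfig)
        folds.append(evaluate(y[test], model.predict_proba(X[test]), threshold))
    return CVResult(folds=tuple(folds), fold_assignment=assignment)


def cross_cell_line_experiment(
    datasets: dict[str, tuple[list, np.ndarray]],
    zconfig: ZSpaceConfig | None = None,
    cconfig: "clf.ClassifierConfig | None" = None,
    tconfig: "clf.TrainConfig | None" = None,
    k: int = 10,
) -> dict[str, CVResult]:
    """Cross-validate each labelled set alone and the pooled union ("pooled").

    Mirrors comparing per-cell-line models with one model trained on the
    amalgamated data from all cell lines.
    """
    if not datasets:
        raise ValueError("at least one dataset is required")
    for name, (_, y) in datasets.items():
        labs = set(np.unique(np.asarray(y)).tolist())
        if not labs <= {0, 1}:
            raise ValueError(f"dataset {name!r} has non-binary labels {sorted(labs)}")
    results = {
        name: cross_validate(seqs, y, zconfig, cconfig, tconfig, k=k)
        for name, (seqs, y) in datasets.items()
    }
    if len(datasets) > 1:
        pooled_seqs = [s for seqs, _ in datasets.values() for s in seqs]
        pooled_y = np.concatenate([np.asarray(y) for _, y in datasets.values()])
        results["pooled"] = cross_validate(pooled_seqs, pooled_y, zconfig, cconfig, tconfig, k=k)
    return results


def cell_line_discrimination(
    pos_sets: dict[str, list],
    zconfig: ZSpaceConfig | None = None,
    cconfig: "clf.ClassifierConfig | None" = None,
    tconfig: "clf.TrainConfig | None" = None,
    k: int = 5,
) -> CVResult:
    """Can origins be told apart BY cell line?  Labels the positives of two
    sets by their set of origin and cross-validates that binary problem.

    On identically distributed sets this scores near chance, which is the
    evidence that origins from different cell lines share one encoding
    pattern (and hence that a pooled cross-cell-line model is sensible).
    """
    if len(pos_sets) != 2:
        raise ValueError("discrimination experiment expects exactly two sets")
    (name_a, seqs_a), (name_b, seqs_b) = pos_sets.items()
    y = np.concatenate([np.ones(len(seqs_a), dtype=int), np.zeros(len(seqs_b), dtype=int)])
    return cross_validate(list(seqs_a) + list(seqs_b), y, zconfig, cconfig, tconfig, k=k)
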