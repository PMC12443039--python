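"""Minimal nearest-centroid gene signatures (ClaNC-style).

Given subtype labels, genes are ranked per class by a class-vs-rest pooled
two-sample t-statistic.  Each gene is owned by the class maximizing |t|;
within each class the top N owned genes are selected, giving k disjoint
sets and a signature of k*N genes.  Per-class centroids are the class
means of the signature genes on the training samples, and new samples are
classified to the nearest centroid in Euclidean distance.  Signature size
is chosen by repeated stratified 70/30 cross-validation over a range of N.

An independent correlation-based classifier (assign each sample to the
centroid with the highest Pearson correlation after per-gene median
centering) is also provided; it is the convention used to transfer
published subtype centroids across cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit

from .containers import ExpressionMatrix

__all__ = [
    "CentroidSignature",
    "CVReport",
    "class_t_statistics",
    "build_signature",
    "classify_nearest_centroid",
    "cross_validate_signature",
    "classify_by_correlation",
]


@dataclass
class CentroidSignature:
    classes: list                      # ordered class names (labels)
    n_per_class: int
    genes: list[str]                   # k * N gene ids, grouped by class
    class_of_gene: pd.Series           # owning class per signature gene
    centroids: pd.DataFrame            # class x gene
    training_stats: pd.DataFrame       # per-gene mean/sd over training set

    def __post_init__(self) -> None:
        k = len(self.classes)
        if len(self.genes) != k * self.n_per_class:
            raise ValueError("signature size must be k * n_per_class")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature gene sets must be disjoint")
        if self.centroids.shape != (k, len(self.genes)):
            raise ValueError("centroid matrix shape inconsistent")


@dataclass
class CVReport:
    n_repeats: int
    train_fraction: float
    per_N_errors: pd.DataFrame     # index N; mean/sd train & test error
    chosen_N: int


def _labels_as_series(labels, sample_ids) -> pd.Series:
    if hasattr(labels, "labels"):      # SubtypeAssignment
        labels = labels.labels
    s = pd.Series(labels, index=sample_ids if not isinstance(labels, pd.Series)
                  else labels.index)
    return s.reindex(sample_ids)


def class_t_statistics(expr: ExpressionMatrix, labels) -> pd.DataFrame:
    """Class-vs-rest pooled t-statistics, one row per class.

    t[c, g] = (mean_in - mean_out) / (s_pooled * sqrt(1/n_in + 1/n_out))
    with the usual two-sample pooled variance.  Genes with zero pooled
    variance get +/-inf (sign of the mean difference; 0 when the means are
    also equal), which ranks them above all finite statistics.
    """
    y = _labels_as_series(labels, expr.sample_ids)
    if y.isna().any():
        raise ValueError("labels missing for some samples")
    X = expr.values.to_numpy(dtype=float)       # genes x samples
    classes = sorted(pd.unique(y))
    n_total = X.shape[1]
    rows = {}
    for c in classes:
        mask = (y == c).to_numpy()
        n_in = int(mask.sum())
        n_out = n_total - n_in
        if n_in < 2 or n_out < 2:
            raise ValueError(f"class {c!r} needs >= 2 samples in and out")
        x_in, x_out = X[:, mask], X[:, ~mask]
        m_in, m_out = x_in.mean(axis=1), x_out.mean(axis=1)
        ss = (((x_in - m_in[:, None]) ** 2).sum(axis=1)
              + ((x_out - m_out[:, None]) ** 2).sum(axis=1))
        s2 = ss / (n_in + n_out - 2)
        denom = np.sqrt(s2 * (1.0 / n_in + 1.0 / n_out))
        diff = m_in - m_out
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / denom
        t[(denom == 0) & (diff > 0)] = np.inf
        t[(denom == 0) & (diff < 0)] = -np.inf
        t[(denom == 0) & (diff == 0)] = 0.0
        rows[c] = t
    return pd.DataFrame(rows, index=expr.gene_ids).T


def build_signature(expr: ExpressionMatrix, labels,
                    n_per_class: int) -> CentroidSignature:
    """Select the k*N signature and its class centroids on training data.

    Each gene is provisionally owned by the class with the largest |t|;
    ties in |t| go to the class where the gene is up-regulated (t > 0) —
    with two classes the class-vs-rest statistics are exactly antisymmetric,
    so every gene ties and the sign decides — then to the first class in
    order.  Within each class the top ``n_per_class`` owned genes by |t|
    are kept, ties broken by gene id.  Centroids are per-class means of
    every signature gene.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    t = class_t_statistics(expr, labels)
    y = _labels_as_series(labels, expr.sample_ids)
    classes = list(t.index)
    abs_t = t.abs()
    abs_arr = abs_t.to_numpy()
    t_arr = t.to_numpy()
    is_max = abs_arr == abs_arr.max(axis=0)[None, :]
    up_max = is_max & (t_arr > 0)
    owner_idx = np.where(up_max.any(axis=0), up_max.argmax(axis=0),
                         is_max.argmax(axis=0))
    selected: list[str] = []
    class_of_gene = {}
    for ci, c in enumerate(classes):
        owned = [g for g, oi in zip(t.columns, owner_idx) if oi == ci]
        if len(owned) < n_per_class:
            raise ValueError(
                f"class {c!r} owns only {len(owned)} genes; "
                f"reduce n_per_class below {n_per_class}")
        ranked = sorted(owned, key=lambda g: (-abs_t.loc[c, g], g))
        chosen = ranked[:n_per_class]
        selected.extend(chosen)
        for g in chosen:
            class_of_gene[g] = c
    sub = expr.values.loc[selected]
    centroids = pd.DataFrame(
        {c: sub.loc[:, (y == c).to_numpy()].mean(axis=1) for c in classes}
    ).T
    stats = pd.DataFrame({"mean": sub.mean(axis=1),
                          "sd": sub.std(axis=1, ddof=1)})
    return CentroidSignature(classes=classes, n_per_class=n_per_class,
                             genes=selected,
                             class_of_gene=pd.Series(class_of_gene),
                             centroids=centroids, training_stats=stats)


def classify_nearest_centroid(sig: CentroidSignature,
                              expr: ExpressionMatrix,
                              standardize: bool = False) -> pd.DataFrame:
    """Assign each sample to its nearest centroid (Euclidean distance).

    Returns a DataFrame indexed by sample with a ``label`` column and one
    ``dist_<class>`` column per class.  With ``standardize=True`` both the
    sample vectors and the centroids are z-scored per gene using the
    signature's training statistics before distances are taken.  Ties go
    to the first class in order.
    """
    missing = [g for g in sig.genes if g not in expr.gene_ids]
    if missing:
        raise KeyError(f"signature genes missing from matrix: {missing[:10]}")
    X = expr.values.loc[sig.genes].to_numpy(dtype=float)   # genes x samples
    if not np.isfinite(X).all():
        raise ValueError("non-finite expression values")
    C = sig.centroids.loc[sig.classes, sig.genes].to_numpy(dtype=float)
    if standardize:
        mu = sig.training_stats["mean"].loc[sig.genes].to_numpy()
        sd = sig.training_stats["sd"].loc[sig.genes].to_numpy()
        sd = np.where(sd > 0, sd, 1.0)
        X = (X - mu[:, None]) / sd[:, None]
        C = (C - mu[None, :]) / sd[None, :]
    # distances: classes x samples
    d = np.sqrt(((X[None, :, :] - C[:, :, None]) ** 2).sum(axis=1))
    label_idx = d.argmin(axis=0)                 # ties -> first class
    out = pd.DataFrame(d.T, index=expr.sample_ids,
                       columns=[f"dist_{c}" for c in sig.classes])
    out.insert(0, "label", [sig.classes[i] for i in label_idx])
    return out


def cross_validate_signature(expr: ExpressionMatrix, labels,
                             n_range=range(1, 31), repeats: int = 100,
                             train_fraction: float = 0.7,
                             seed: int = 0,
                             standardize: bool = False) -> CVReport:
    """Error of the N-per-class signature under repeated stratified splits.

    For each repeat a stratified ``train_fraction`` split is drawn, a
    signature is built on the training samples for every N in ``n_range``
    and the misclassification rate against the input labels is recorded on
    both halves.  ``chosen_N`` is the smallest N whose mean test error is
    within one standard error of the minimum (parsimony rule).
    """
    y = _labels_as_series(labels, expr.sample_ids)
    n_range = list(n_range)
    splitter = StratifiedShuffleSplit(n_splits=repeats,
                                      train_size=train_fraction,
                                      random_state=seed % (2 ** 32))
    sample_ids = expr.sample_ids
    train_err = np.zeros((repeats, len(n_range)))
    test_err = np.zeros((repeats, len(n_range)))
    for rep, (tr, te) in enumerate(splitter.split(y.to_numpy()[:, None],
                                                  y.to_numpy())):
        expr_tr = ExpressionMatrix(expr.values.iloc[:, tr],
                                   expr.is_mito)
        y_tr, y_te = y.iloc[tr], y.iloc[te]
        expr_te = ExpressionMatrix(expr.values.iloc[:, te], expr.is_mito)
        for ni, N in enumerate(n_range):
            sig = build_signature(expr_tr, y_tr, N)
            pred_tr = classify_nearest_centroid(sig, expr_tr,
                                                standardize=standardize)
            pred_te = classify_nearest_centroid(sig, expr_te,
                                                standardize=standardize)
            train_err[rep, ni] = float(
                (pred_tr["label"].to_numpy() != y_tr.to_numpy()).mean())
            test_err[rep, ni] = float(
                (pred_te["label"].to_numpy() != y_te.to_numpy()).mean())
    table = pd.DataFrame({
        "N": n_range,
        "train_error": train_err.mean(axis=0),
        "train_error_sd": train_err.std(axis=0, ddof=1) if repeats > 1 else 0.0,
        "test_error": test_err.mean(axis=0),
        "test_error_sd": test_err.std(axis=0, ddof=1) if repeats > 1 else 0.0,
    }).set_index("N")
    best_i = int(table["test_error"].to_numpy().argmin())
    se = (table["test_error_sd"].iloc[best_i] / np.sqrt(repeats)
          if repeats > 1 else 0.0)
    threshold = table["test_error"].iloc[best_i] + se
    chosen = next(N for N, e in table["test_error"].items() if e <= threshold)
    return CVReport(n_repeats=repeats, train_fraction=train_fraction,
                    per_N_errors=table, chosen_N=int(chosen))


def classify_by_correlation(centroids: pd.DataFrame,
                            expr: ExpressionMatrix) -> pd.DataFrame:
    """Centroid-correlation classification after per-gene median centering.

    Each gene is centered by its median across the samples of ``expr``;
    each sample is then assigned to the class whose centroid it correlates
    with best (Pearson).  Samples with zero variance over the shared genes
    cannot be correlated and come back with a null label.
    """
    shared = [g for g in centroids.columns if g in expr.gene_ids]
    if len(shared) < 3:
        raise ValueError("need at least 3 genes shared with the centroids")
    X = expr.values.loc[shared]
    X = X.sub(X.median(axis=1), axis=0).to_numpy(dtype=float)  # genes x samples
    C = centroids[shared].to_numpy(dtype=float)                # classes x genes
    Xc = X - X.mean(axis=0)[None, :]
    Cc = C - C.mean(axis=1)[:, None]
    x_norm = np.sqrt((Xc ** 2).sum(axis=0))
    c_norm = np.sqrt((Cc ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Cc @ Xc) / (c_norm[:, None] * x_norm[None, :])
    classes = list(centroids.index)
    out = pd.DataFrame(r.T, index=expr.sample_ids,
                       columns=[f"r_{c}" for c in classes])
    valid = np.isfinite(r).all(axis=0)
    labels = np.where(valid,
                      np.asarray(classes, dtype=object)[np.nan_to_num(
                          r, nan=-2.0).argmax(axis=0)],
                      None)
    out.insert(0, "label", labels)
    return out
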