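"""Library-size normalization and high-variance gene selection.

Size factors use the median-of-ratios estimator: each sample's factor is
the median, over reference genes (genes with positive counts in every
sample), of that sample's count divided by the gene's geometric mean
across samples.  Dividing counts by the factors removes library-size
differences while leaving relative expression intact.  A counts-per-million
fallback is provided for matrices where no gene is positive everywhere.

Gene selection mirrors the standard subtype-discovery filter: keep genes
whose median normalized level exceeds a floor, drop mitochondrial genes,
rank the survivors by variance and keep the top ``n_top``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix

__all__ = ["size_factors", "normalize_counts", "select_genes"]


def size_factors(counts: CountMatrix,
                 allow_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Parameters
    ----------
    counts
        Raw count matrix.
    allow_pseudo_reference
        If no gene has positive counts in every sample the estimator is
        undefined; with this flag the geometric mean of each gene is taken
        over its positive entries only and ratios are computed where the
        count is positive (the "positive counts" fallback).
    """
    arr = counts.values.to_numpy(dtype=float)
    all_positive = (arr > 0).all(axis=1)
    if all_positive.any():
        ref = arr[all_positive]
        log_gm = np.mean(np.log(ref), axis=1)
        log_ratios = np.log(ref) - log_gm[:, None]
        factors = np.exp(np.median(log_ratios, axis=0))
    elif allow_pseudo_reference:
        with np.errstate(divide="ignore"):
            logs = np.where(arr > 0, np.log(arr), np.nan)
        log_gm = np.nanmean(logs, axis=1)
        usable = np.isfinite(log_gm)
        if not usable.any():
            raise ValueError("count matrix is entirely zero")
        log_ratios = logs[usable] - log_gm[usable, None]
        factors = np.exp(np.nanmedian(log_ratios, axis=0))
    else:
        raise ValueError(
            "no gene has positive counts in every sample; median-of-ratios "
            "is undefined — pass allow_pseudo_reference=True to fall back "
            "to a positive-counts pseudo-reference")
    if not np.isfinite(factors).all() or (factors <= 0).any():
        raise ValueError("degenerate size factors; check the count matrix")
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def normalize_counts(counts: CountMatrix,
                     method: str = "median_of_ratios",
                     allow_pseudo_reference: bool = False,
                     ) -> ExpressionMatrix:
    """Return counts divided by per-sample size factors.

    ``method`` is ``"median_of_ratios"`` (default) or ``"cpm"``
    (counts per million mapped reads).
    """
    if method == "median_of_ratios":
        factors = size_factors(counts,
                               allow_pseudo_reference=allow_pseudo_reference)
    elif method == "cpm":
        totals = counts.values.sum(axis=0).astype(float)
        if (totals <= 0).any():
            raise ValueError("sample with zero total counts")
        factors = totals / 1e6
        factors.name = "size_factor"
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    values = counts.values.div(factors, axis=1)
    return ExpressionMatrix(values, counts.is_mito)


def select_genes(expr: ExpressionMatrix, n_top: int = 5000,
                 median_min: float = 1.0,
                 log_variance: bool = False) -> ExpressionMatrix:
    """High-variance gene selection for subtype discovery.

    Keeps genes with median normalized level > ``median_min`` that are not
    mitochondrial, ranks them by variance (descending) and returns the top
    ``n_top`` (all survivors if fewer).  With ``log_variance=True`` the
    variance is computed on log2(x+1) values; selection ties are broken by
    gene id so the output is deterministic.
    """
    values = expr.values
    medians = values.median(axis=1)
    keep = (medians > median_min) & ~expr.is_mito
    if not keep.any():
        raise ValueError(
            "no genes survive the median/mitochondrial filter")
    surv = values.loc[keep]
    basis = np.log2(surv + 1.0) if log_variance else surv
    variances = basis.var(axis=1, ddof=1)
    # stable sort on a gene-id-sorted series -> variance ties resolve
    # lexicographically
    ranked = variances.sort_index().sort_values(
        ascending=False, kind="mergesort")
    chosen = ranked.index[:n_top]
    return ExpressionMatrix(values.loc[chosen], expr.is_mito.loc[chosen])
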