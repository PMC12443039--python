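import numpy as np
import pandas as pd
import pytest

from subtypekit import (CountMatrix, ExpressionMatrix, SyntheticConfig,
                        generate_dataset, normalize_counts, select_genes)


def small_config(seed: int = 42, **overrides) -> SyntheticConfig:
    """A fast three-subtype cohort used across the unit tests."""
    kwargs = dict(
        n_subtypes=3,
        samples_per_subtype=[20, 20, 20],
        n_genes=400,
        n_signature_genes_per_subtype=40,
        signature_log2fc=2.0,
        nb_dispersion=0.2,
        n_mito_genes=10,
        lineage_set_sizes=(12, 12, 12),
        cross_lineage_fraction=(0.05, 0.15, 0.6),
        baseline_hazards=(0.01, 0.02, 0.045),
        censoring_rate=0.3,
        stage_subtype_odds=(0.7, 0.5, 0.25),
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def small_selected(small_dataset):
    expr = normalize_counts(small_dataset.counts)
    return select_genes(expr, n_top=5000, median_min=1.0)


def make_separable(n_per_class=(10, 10, 10), markers_per_class=42,
                   high=10.0, low=1.0) -> tuple[ExpressionMatrix, pd.Series]:
    """Noise-free block expression: markers of class c are ``high`` in
    class-c samples and ``low`` elsewhere."""
    k = len(n_per_class)
    n_samples = sum(n_per_class)
    labels = np.repeat(np.arange(1, k + 1), n_per_class)
    genes = [f"M{c}_{i:03d}" for c in range(1, k + 1)
             for i in range(markers_per_class)]
    vals = np.full((k * markers_per_class, n_samples), low)
    for c in range(k):
        rows = slice(c * markers_per_class, (c + 1) * markers_per_class)
        vals[rows, labels == c + 1] = high
    samples = [f"S{j:03d}" for j in range(n_samples)]
    expr = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples))
    return expr, pd.Series(labels, index=samples, name="subtype")


def tiny_counts(values, mito=None) -> CountMatrix:
    arr = np.asarray(values)
    genes = [f"g{i}" for i in range(arr.shape[0])]
    samples = [f"s{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=genes, columns=samples)
    is_mito = pd.Series(mito if mito is not None else False, index=genes)
    return CountMatrix(df, is_mito)
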