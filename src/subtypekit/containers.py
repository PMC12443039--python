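"""Core in-memory containers shared across the pipeline stages.

Expression data is held gene x sample in a pandas DataFrame (genes on the
index, samples on the columns) together with a per-gene mitochondrial flag.
Survival/clinical data is a plain DataFrame validated by
:func:`validate_survival_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "LineageGeneSets",
    "validate_survival_table",
    "SURVIVAL_CORE_COLUMNS",
]


def _check_ids(values: pd.DataFrame) -> None:
    if values.index.has_duplicates:
        dupes = values.index[values.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    if values.columns.has_duplicates:
        dupes = values.columns[values.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dupes[:5]}")


def _check_mito(values: pd.DataFrame, is_mito: pd.Series) -> pd.Series:
    is_mito = is_mito.reindex(values.index)
    if is_mito.isna().any():
        missing = is_mito.index[is_mito.isna()].tolist()
        raise ValueError(f"is_mito flag missing for genes: {missing[:5]}")
    return is_mito.astype(bool)


@dataclass
class CountMatrix:
    """Raw integer read counts, gene x sample."""

    values: pd.DataFrame
    is_mito: pd.Series

    def __post_init__(self) -> None:
        _check_ids(self.values)
        arr = self.values.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integral")
        self.values = self.values.astype(np.int64)
        self.is_mito = _check_mito(self.values, self.is_mito)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ExpressionMatrix:
    """Normalized non-negative expression values, gene x sample.

    This is the matrix V fed to non-negative matrix factorization, so
    non-negativity is enforced at construction.
    """

    values: pd.DataFrame
    is_mito: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        _check_ids(self.values)
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        self.values = self.values.astype(float)
        if self.is_mito is None:
            self.is_mito = pd.Series(False, index=self.values.index)
        self.is_mito = _check_mito(self.values, self.is_mito)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.values.loc[list(genes)],
                                self.is_mito.loc[list(genes)])


@dataclass
class LineageGeneSets:
    """Marker gene lists for the three histological lineages.

    The canonical set names are LUAD, LUSC and NET; sets must be pairwise
    disjoint and non-empty.
    """

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("no lineage sets provided")
        seen: set[str] = set()
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"lineage set {name!r} is empty")
            gset = set(genes)
            if len(gset) != len(genes):
                raise ValueError(f"lineage set {name!r} has duplicate genes")
            overlap = seen & gset
            if overlap:
                raise ValueError(
                    f"lineage sets overlap: {sorted(overlap)[:5]}")
            seen |= gset

    @property
    def names(self) -> list[str]:
        return list(self.sets)


SURVIVAL_CORE_COLUMNS = ("time", "event", "age", "sex", "stage")

MUTATION_COLUMNS = ("tp53", "egfr", "kras", "alk_fusion")


def validate_survival_table(df: pd.DataFrame,
                            required: tuple[str, ...] = ("time", "event"),
                            ) -> pd.DataFrame:
    """Validate a per-sample clinical/survival table.

    ``time`` is follow-up in months (> 0), ``event`` a 0/1 death indicator,
    ``stage`` ordinal 1-4.  Only the columns named in ``required`` are
    checked for presence and missingness, so tables lacking e.g. mutation
    flags remain usable by models that do not need them.
    """
    for col in required:
        if col not in df.columns:
            raise ValueError(f"survival table lacks required column {col!r}")
        if df[col].isna().any():
            raise ValueError(f"survival column {col!r} has missing values")
    if "time" in required and (df["time"] <= 0).any():
        raise ValueError("survival times must be strictly positive")
    if "event" in required and not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    if "stage" in required and not df["stage"].isin([1, 2, 3, 4]).all():
        raise ValueError("stage must be ordinal 1-4")
    return df
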