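"""Histological-lineage scores and the mix-lineage score.

For each tumor the score of a lineage (LUAD, LUSC, NET) is the total
expression of that lineage's marker genes divided by the total expression
of all three marker sets, so the three scores are non-negative and sum to
one.  The mix-lineage score

    S_mix = 1 - max(S_LUAD, S_LUSC, S_NET)

is 0 when a single lineage carries all marker expression and maximal
(1 - 1/3 = 2/3 for three lineages) when the three scores are equal; high
values indicate lineage infidelity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, LineageGeneSets

__all__ = ["lineage_score"]


def lineage_score(expr: ExpressionMatrix,
                  sets: LineageGeneSets) -> pd.DataFrame:
    """Per-sample lineage scores and S_mix.

    Returns a DataFrame indexed by sample with one ``S_<lineage>`` column
    per lineage set plus ``S_mix``.  Samples whose total marker expression
    is zero cannot be scored and come back as NaN rows (flagged in the
    boolean ``unscored`` column).
    """
    totals = {}
    for name, genes in sets.sets.items():
        present = [g for g in genes if g in expr.gene_ids]
        if not present:
            raise ValueError(
                f"no genes of lineage set {name!r} present in the matrix")
        totals[name] = expr.values.loc[present].sum(axis=0)
    tot = pd.DataFrame(totals)
    grand = tot.sum(axis=1)
    ok = grand > 0
    scores = tot.div(grand.where(ok), axis=0)
    scores.columns = [f"S_{n}" for n in tot.columns]
    scores["S_mix"] = 1.0 - scores.max(axis=1)
    scores["unscored"] = ~ok
    scores.loc[~ok, scores.columns[:-1]] = np.nan
    return scores
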