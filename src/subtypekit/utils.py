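"""Small shared helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["label_agreement", "match_labels"]


def match_labels(reference, other) -> dict:
    """Best one-to-one mapping of ``other``'s labels onto ``reference``'s.

    Cluster labels are arbitrary up to permutation; the mapping maximizing
    the number of agreeing samples is found by solving the assignment
    problem on the confusion matrix.  Returns {other_label: reference_label}.
    """
    ref = pd.Series(reference).to_numpy()
    oth = pd.Series(other).to_numpy()
    if len(ref) != len(oth):
        raise ValueError("label vectors must have equal length")
    ref_vals = np.unique(ref)
    oth_vals = np.unique(oth)
    conf = np.zeros((len(oth_vals), len(ref_vals)))
    for i, a in enumerate(oth_vals):
        for j, b in enumerate(ref_vals):
            conf[i, j] = np.sum((oth == a) & (ref == b))
    rows, cols = linear_sum_assignment(-conf)
    return {oth_vals[i]: ref_vals[j] for i, j in zip(rows, cols)}


def label_agreement(reference, other) -> float:
    """Fraction of samples agreeing after the best label permutation."""
    mapping = match_labels(reference, other)
    oth = pd.Series(other).map(mapping).to_numpy()
    ref = pd.Series(reference).to_numpy()
    return float(np.mean(oth == ref))
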