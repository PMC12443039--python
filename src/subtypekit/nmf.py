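"""Consensus non-negative matrix factorization for subtype discovery.

The factorization V ~ W @ H (all entries non-negative) is fitted by the
classical multiplicative updates for the Kullback-Leibler divergence

    H <- H * (W' (V / WH)) / (W' 1)
    W <- W * ((V / WH) H') / (1 H')

which decrease the generalized KL divergence D(V || WH) monotonically.
Sample clusters are read off as the argmax row of H per sample.  Stability
at a given rank is assessed by re-fitting from many random initializations
and recording, for each sample pair, the fraction of runs in which the pair
co-clusters (the consensus matrix); the cophenetic correlation of the
consensus dissimilarity measures how close the consensus is to a clean
block structure, and the rank maximizing it is selected.

Gene specificity for a fitted basis W is scored by normalized entropy of a
gene's loading profile p(i, q) = W[i, q] / sum_q W[i, q]:

    S_i = 1 + (1 / log2 k) * sum_q p(i, q) log2 p(i, q)

so S_i = 0 for a gene loading all programs equally and S_i = 1 for a gene
loading a single program.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .containers import ExpressionMatrix

__all__ = [
    "NMFFactorization",
    "ConsensusResult",
    "SubtypeAssignment",
    "GeneSpecificity",
    "fit_nmf_brunet",
    "consensus_over_runs",
    "cophenetic_coefficient",
    "select_rank",
    "cophenetic_curve",
    "assign_clusters",
    "basis_specificity",
    "top_specific_genes",
]

_EPS = 1e-12


@dataclass
class NMFFactorization:
    W: np.ndarray                 # gene x rank basis
    H: np.ndarray                 # rank x sample coefficients
    rank: int
    objective_trace: list[float]  # KL divergence, recorded every
    seed: int                     # ``objective_interval`` iterations
    n_iter: int = 0
    gene_ids: pd.Index | None = None
    sample_ids: pd.Index | None = None

    @property
    def final_divergence(self) -> float:
        return self.objective_trace[-1]


@dataclass
class ConsensusResult:
    rank: int
    consensus: np.ndarray         # sample x sample, entries in [0,1]
    cophenetic: float
    silhouette_consensus: float
    silhouette_basis: float
    silhouette_coef: float
    n_runs: int
    best_fit: NMFFactorization | None = None
    sample_ids: pd.Index | None = None


@dataclass
class SubtypeAssignment:
    labels: pd.Series             # per-sample integer in 1..k
    membership: pd.DataFrame      # sample x cluster, rows sum to 1


@dataclass
class GeneSpecificity:
    score: pd.Series              # S_i per gene, NaN for all-zero W rows
    profile: pd.DataFrame         # gene x cluster p(i, q)
    k: int


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH), with 0 log 0 = 0."""
    mask = V > 0
    div = np.sum(V[mask] * np.log(V[mask] / np.maximum(WH[mask], _EPS)),
                 dtype=np.float64)
    return float(div - V.sum(dtype=np.float64) + WH.sum(dtype=np.float64))


def _make_kl(V: np.ndarray):
    """Closure evaluating D(V || WH) with the V-only terms precomputed."""
    mask = V > 0
    vpos = V[mask].astype(np.float64)
    const = float(np.sum(vpos * np.log(vpos)) - V.sum(dtype=np.float64))
    buf = np.empty_like(V)

    def kl(WH: np.ndarray) -> float:
        np.log(WH, out=buf)
        cross = np.sum(V * buf, dtype=np.float64)
        return const - float(cross) + float(WH.sum(dtype=np.float64))

    return kl


def _as_array(V) -> tuple[np.ndarray, pd.Index | None, pd.Index | None]:
    if isinstance(V, ExpressionMatrix):
        return V.values.to_numpy(dtype=float), V.gene_ids, V.sample_ids
    arr = np.asarray(V, dtype=float)
    return arr, None, None


def fit_nmf_brunet(V, rank: int, seed: int = 0, max_iter: int = 2000,
                   conn_stop: int | None = 4, conn_interval: int = 10,
                   objective_interval: int = 10,
                   dtype=np.float64) -> NMFFactorization:
    """Single NMF fit with multiplicative KL updates.

    W and H are initialized i.i.d. Uniform(0, 1) scaled so the mean of the
    initial reconstruction matches the mean of V.  Iteration stops when the
    sample connectivity matrix (argmax-H co-membership) has been unchanged
    for ``conn_stop`` consecutive checks (every ``conn_interval``
    iterations) or after ``max_iter`` updates; ``conn_stop=None`` disables
    early stopping.  The KL divergence is
    recorded every ``objective_interval`` iterations (pass 1 to trace every
    update).
    """
    arr, gene_ids, sample_ids = _as_array(V)
    if (arr < 0).any():
        raise ValueError("V must be non-negative")
    if (arr.sum(axis=0) == 0).any():
        raise ValueError("V has an all-zero sample column")
    n_genes, n_samples = arr.shape
    if rank < 1 or rank > min(n_genes, n_samples):
        raise ValueError(f"rank must be in [1, {min(arr.shape)}]")

    rng = np.random.default_rng(seed)
    scale = 2.0 * np.sqrt(arr.mean() / rank)
    W = rng.uniform(0.0, scale, size=(n_genes, rank))
    H = rng.uniform(0.0, scale, size=(rank, n_samples))
    np.maximum(W, _EPS, out=W)
    np.maximum(H, _EPS, out=H)
    arr = arr.astype(dtype, copy=False)
    W = W.astype(dtype)             # init drawn in float64 first so the
    H = H.astype(dtype)             # starting point is dtype-independent
    kl = _make_kl(arr)

    trace: list[float] = [kl(np.maximum(W @ H, _EPS))]
    prev_labels = None
    stable_checks = 0
    n_iter = 0
    WH = np.empty_like(arr)         # reused buffers: the elementwise work
    Q = np.empty_like(arr)          # on gene x sample arrays dominates cost
    for it in range(1, max_iter + 1):
        np.matmul(W, H, out=WH)
        np.maximum(WH, _EPS, out=WH)
        np.divide(arr, WH, out=Q)
        H *= (W.T @ Q) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        np.matmul(W, H, out=WH)
        np.maximum(WH, _EPS, out=WH)
        np.divide(arr, WH, out=Q)
        W *= (Q @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        n_iter = it
        if it % objective_interval == 0 or it == max_iter:
            np.matmul(W, H, out=WH)
            np.maximum(WH, _EPS, out=WH)
            trace.append(kl(WH))
        if conn_stop is not None and it % conn_interval == 0:
            labels = H.argmax(axis=0)
            if prev_labels is not None and np.array_equal(labels, prev_labels):
                stable_checks += 1
                if stable_checks >= conn_stop:
                    break
            else:
                stable_checks = 0
            prev_labels = labels
    if n_iter % objective_interval != 0 and n_iter != max_iter:
        trace.append(kl(np.maximum(W @ H, _EPS)))
    return NMFFactorization(W=W.astype(np.float64), H=H.astype(np.float64),
                            rank=rank, objective_trace=trace,
                            seed=seed, n_iter=n_iter,
                            gene_ids=gene_ids, sample_ids=sample_ids)


def _safe_silhouette(X: np.ndarray, labels: np.ndarray,
                     metric: str = "euclidean") -> float:
    if len(np.unique(labels)) < 2:
        return float("nan")
    try:
        return float(silhouette_score(X, labels, metric=metric))
    except ValueError:
        return float("nan")


def consensus_over_runs(V, rank: int, n_runs: int = 80, base_seed: int = 0,
                        dtype=np.float32, **fit_kwargs) -> ConsensusResult:
    """Consensus matrix over ``n_runs`` NMF fits seeded base_seed + run.

    consensus[i, j] is the fraction of runs in which samples i and j share
    an argmax-H cluster.  The run with the lowest final KL divergence is
    kept as ``best_fit`` for downstream use; silhouettes are computed from
    that run's W (genes, by argmax program), H (samples, by cluster) and
    from the consensus dissimilarity 1 - consensus.

    The many repeated fits run in float32 by default: co-clustering and
    the ranking of runs by final divergence are insensitive to the extra
    precision, and the memory-bound updates run about twice as fast.  Pass
    ``dtype=np.float64`` for full-precision fits.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    arr, _, sample_ids = _as_array(V)
    n_samples = arr.shape[1]
    co = np.zeros((n_samples, n_samples))
    best: NMFFactorization | None = None
    for run in range(n_runs):
        try:
            fit = fit_nmf_brunet(V, rank, seed=base_seed + run,
                                 dtype=dtype, **fit_kwargs)
        except Exception as exc:              # annotate failing run index
            raise RuntimeError(f"NMF run {run} (rank {rank}) failed") from exc
        labels = fit.H.argmax(axis=0)
        co += (labels[:, None] == labels[None, :])
        if best is None or fit.final_divergence < best.final_divergence:
            best = fit
    consensus = co / n_runs
    np.fill_diagonal(consensus, 1.0)

    coph = cophenetic_coefficient(consensus)
    best_labels = best.H.argmax(axis=0)
    sil_cons = _safe_silhouette(1.0 - consensus, best_labels,
                                metric="precomputed")
    gene_labels = best.W.argmax(axis=1)
    sil_basis = _safe_silhouette(best.W, gene_labels)
    sil_coef = _safe_silhouette(best.H.T, best_labels)
    return ConsensusResult(rank=rank, consensus=consensus, cophenetic=coph,
                           silhouette_consensus=sil_cons,
                           silhouette_basis=sil_basis,
                           silhouette_coef=sil_coef, n_runs=n_runs,
                           best_fit=best, sample_ids=sample_ids)


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Cophenetic correlation of the consensus dissimilarity 1 - consensus.

    Average-linkage hierarchical clustering of the dissimilarity, then the
    Pearson correlation between the original pairwise dissimilarities and
    the dendrogram's cophenetic distances.  Returns NaN when the pairwise
    dissimilarities are constant (correlation undefined).
    """
    C = np.asarray(consensus, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("consensus must be square")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("consensus must be symmetric")
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    d = squareform(D, checks=False)
    if np.ptp(d) < 1e-15:
        return float("nan")
    Z = average(d)
    coph_d = cophenet(Z)
    # Pearson correlation computed explicitly; if the dendrogram collapses
    # to constant cophenetic distances the correlation is undefined
    if np.ptp(coph_d) < 1e-15:
        return float("nan")
    return float(np.corrcoef(d, coph_d)[0, 1])


def select_rank(results: list[ConsensusResult]) -> int:
    """Rank with the maximal cophenetic coefficient; ties -> smallest rank.

    Ranks whose coefficient is NaN are excluded with a warning.
    """
    if len(results) < 2:
        raise ValueError("need consensus results for at least 2 ranks")
    usable = []
    for res in sorted(results, key=lambda r: r.rank):
        if np.isnan(res.cophenetic):
            warnings.warn(
                f"rank {res.rank}: cophenetic coefficient undefined; "
                "excluded from rank selection", stacklevel=2)
        else:
            usable.append(res)
    if not usable:
        raise ValueError("cophenetic coefficient undefined at every rank")
    best = max(usable, key=lambda r: (r.cophenetic, -r.rank))
    return best.rank


def cophenetic_curve(results: list[ConsensusResult]) -> pd.DataFrame:
    """Per-rank stability metrics, for reporting alongside rank selection."""
    rows = [{"rank": r.rank, "cophenetic": r.cophenetic,
             "silhouette_consensus": r.silhouette_consensus,
             "silhouette_basis": r.silhouette_basis,
             "silhouette_coef": r.silhouette_coef,
             "n_runs": r.n_runs}
            for r in sorted(results, key=lambda r: r.rank)]
    return pd.DataFrame(rows).set_index("rank")


def assign_clusters(fact: NMFFactorization) -> SubtypeAssignment:
    """Cluster label = argmax of the sample's H column (1-based).

    Ties go to the lowest cluster index; membership is the column-normalized
    coefficient profile.
    """
    H = fact.H
    col_sums = H.sum(axis=0)
    if (col_sums == 0).any():
        raise ValueError("H has an all-zero sample column")
    labels = H.argmax(axis=0) + 1
    membership = (H / col_sums).T
    sample_ids = (fact.sample_ids if fact.sample_ids is not None
                  else pd.RangeIndex(H.shape[1]))
    return SubtypeAssignment(
        labels=pd.Series(labels, index=sample_ids, name="subtype"),
        membership=pd.DataFrame(membership, index=sample_ids,
                                columns=[f"cluster_{q+1}"
                                         for q in range(fact.rank)]))


def basis_specificity(fact: NMFFactorization) -> GeneSpecificity:
    """Entropy-based subtype specificity of each gene's basis profile.

    S_i = 1 + (1/log2 k) * sum_q p(i,q) log2 p(i,q) with 0 log 0 = 0;
    genes whose W row is entirely zero get S_i = NaN.
    """
    if fact.rank < 2:
        raise ValueError("specificity requires rank >= 2")
    W = fact.W
    row_sums = W.sum(axis=1)
    nonzero = row_sums > 0
    p = np.full_like(W, np.nan, dtype=float)
    p[nonzero] = W[nonzero] / row_sums[nonzero, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    S = np.full(W.shape[0], np.nan)
    S[nonzero] = 1.0 + plogp[nonzero].sum(axis=1) / np.log2(fact.rank)
    gene_ids = (fact.gene_ids if fact.gene_ids is not None
                else pd.RangeIndex(W.shape[0]))
    return GeneSpecificity(
        score=pd.Series(S, index=gene_ids, name="specificity"),
        profile=pd.DataFrame(p, index=gene_ids,
                             columns=[f"cluster_{q+1}"
                                      for q in range(fact.rank)]),
        k=fact.rank)


def top_specific_genes(spec: GeneSpecificity, m: int = 50) -> dict[int, list]:
    """Top ``m`` genes per cluster, ranked by S_i among genes whose profile
    peaks in that cluster."""
    peak = spec.profile.to_numpy()
    valid = spec.score.notna().to_numpy()
    out: dict[int, list] = {}
    for q in range(spec.profile.shape[1]):
        mask = valid & (np.nanargmax(np.nan_to_num(peak, nan=-1.0), axis=1) == q)
        genes = spec.score[mask].sort_values(ascending=False).index[:m]
        out[q + 1] = list(genes)
    return out
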