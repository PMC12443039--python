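"""Synthetic bulk RNA-seq cohorts with planted expression subtypes.

The generator emulates the statistical structure the downstream analysis
assumes: ``k`` latent subtypes, each with its own over-expressed gene
program; negative-binomial counts with per-sample library-size variation;
mitochondrial genes with high baseline expression; three disjoint
histological-lineage marker sets whose cross-lineage expression depends on
the subtype (one "chaotic-like" subtype expresses off-lineage markers
heavily); and subtype-linked proportional-hazards survival with independent
censoring and a stage-subtype association.

The negative binomial is parameterized by mean ``mu`` and dispersion
``phi`` with variance ``mu + phi * mu**2`` (the RNA-seq convention);
``phi = 0`` degenerates to Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix, LineageGeneSets

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_dataset",
    "generate_factorizable_matrix",
]

LINEAGE_NAMES = ("LUAD", "LUSC", "NET")


@dataclass
class SyntheticConfig:
    """Parameters of a planted-subtype synthetic cohort.

    Defaults describe a three-subtype cohort of 150 tumors: 2000 genes,
    200 program genes per subtype up-shifted 4-fold (log2fc = 2) in their
    own subtype, NB dispersion 0.2, and a third subtype that is
    chaotic-like (60% off-lineage marker expression, highest hazard,
    lowest stage-I probability).

    ``seed`` drives everything cohort-specific (sampling noise, library
    sizes, labels, survival); ``gene_param_seed`` drives the gene-level
    baseline means and is deliberately separate, so cohorts with different
    ``seed`` values are independent draws from one shared transcriptome —
    the setting in which signatures can transfer between cohorts.
    """

    n_subtypes: int = 3
    samples_per_subtype: list[int] = field(default_factory=lambda: [50, 50, 50])
    n_genes: int = 2000
    n_signature_genes_per_subtype: int = 200
    signature_log2fc: float = 2.0
    nb_dispersion: float = 0.2
    library_size_range: tuple[float, float] = (0.7, 1.4)
    n_mito_genes: int = 20
    lineage_set_sizes: tuple[int, int, int] = (30, 30, 30)
    cross_lineage_fraction: tuple[float, ...] = (0.05, 0.15, 0.60)
    baseline_hazards: tuple[float, ...] = (0.010, 0.020, 0.045)
    censoring_rate: float = 0.3
    stage_subtype_odds: tuple[float, ...] = (0.70, 0.50, 0.25)
    seed: int = 0
    gene_param_seed: int = 20090

    def __post_init__(self) -> None:
        k = self.n_subtypes
        if k < 1:
            raise ValueError("n_subtypes must be >= 1")
        if len(self.samples_per_subtype) != k:
            raise ValueError("samples_per_subtype must have one entry per subtype")
        if any(n < 1 for n in self.samples_per_subtype):
            raise ValueError("samples_per_subtype entries must be >= 1")
        for name in ("cross_lineage_fraction", "baseline_hazards",
                     "stage_subtype_odds"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} must have one entry per subtype")
        if any(not 0 <= p <= 1 for p in self.cross_lineage_fraction):
            raise ValueError("cross_lineage_fraction entries must be in [0,1]")
        if any(h <= 0 for h in self.baseline_hazards):
            raise ValueError("baseline_hazards must be strictly positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if any(not 0 <= p <= 1 for p in self.stage_subtype_odds):
            raise ValueError("stage_subtype_odds entries must be in [0,1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ValueError("library_size_range must satisfy 0 < lo <= hi")
        n_special = (k * self.n_signature_genes_per_subtype
                     + self.n_mito_genes + sum(self.lineage_set_sizes))
        if n_special > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for "
                f"{n_special} program/mito/lineage genes")


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    true_labels: pd.Series          # per-sample subtype index, 1..k
    survival: pd.DataFrame          # time, event, age, sex, stage
    lineage_sets: LineageGeneSets
    true_program_genes: dict[int, list[str]]   # subtype -> gene ids
    config: SyntheticConfig


def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """NB(mean, var = mean + phi mean^2); phi = 0 falls back to Poisson."""
    if dispersion == 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def _censoring_hazard(config: SyntheticConfig) -> float:
    """Exponential censoring rate whose expected censored fraction equals
    ``censoring_rate`` given the subtype mix: with event hazard h and
    censoring hazard c, P(censored) = c / (c + h)."""
    from scipy.optimize import brentq

    weights = np.asarray(config.samples_per_subtype, dtype=float)
    weights /= weights.sum()
    hazards = np.asarray(config.baseline_hazards, dtype=float)

    def expected_censored(c: float) -> float:
        return float(np.sum(weights * c / (c + hazards)))

    target = config.censoring_rate
    lo, hi = 1e-12, 1e6
    return float(brentq(lambda c: expected_censored(c) - target, lo, hi))


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one cohort from the configured generative process.

    Fully reproducible: the same config (including ``seed``) yields a
    bitwise-identical dataset.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_subtypes
    n_samples = sum(config.samples_per_subtype)
    G = config.n_genes

    gene_ids = pd.Index([f"G{i:05d}" for i in range(G)], name="gene_id")
    sample_ids = pd.Index([f"S{j:04d}" for j in range(n_samples)],
                          name="sample_id")

    # gene roles: per-subtype programs first, then mito, then lineage sets
    cursor = 0
    program: dict[int, list[str]] = {}
    for s in range(k):
        n_prog = config.n_signature_genes_per_subtype
        program[s + 1] = list(gene_ids[cursor:cursor + n_prog])
        cursor += n_prog
    mito_genes = list(gene_ids[cursor:cursor + config.n_mito_genes])
    cursor += config.n_mito_genes
    lineage: dict[str, list[str]] = {}
    for name, size in zip(LINEAGE_NAMES, config.lineage_set_sizes):
        lineage[name] = list(gene_ids[cursor:cursor + size])
        cursor += size

    # baseline means: log2-normal(4, 2); mitochondrial genes high (log2 ~ 9).
    # Drawn from gene_param_seed, not seed: baseline expression is a
    # property of the simulated transcriptome, shared by every cohort drawn
    # from the same generative process (so signatures transfer across
    # cohorts the way they do between real studies).
    rng_genes = np.random.default_rng(config.gene_param_seed)
    log2_mu = rng_genes.normal(4.0, 2.0, size=G)
    mu = np.power(2.0, log2_mu)
    mito_idx = gene_ids.get_indexer(mito_genes)
    mu[mito_idx] = np.power(2.0,
                            rng_genes.normal(9.0, 1.0, size=len(mito_genes)))

    labels = np.repeat(np.arange(1, k + 1), config.samples_per_subtype)

    # per-gene x per-subtype multiplicative effects
    effect = np.ones((G, k))
    fc = 2.0 ** config.signature_log2fc
    for s in range(k):
        effect[gene_ids.get_indexer(program[s + 1]), s] = fc
    marker_boost = 8.0     # lineage markers sit above baseline so the
    for s in range(k):     # scores are marker-driven, not noise-driven
        c = config.cross_lineage_fraction[s]
        shares = {"LUAD": 1.0 - c, "LUSC": c / 2.0, "NET": c / 2.0}
        for name in LINEAGE_NAMES:
            idx = gene_ids.get_indexer(lineage[name])
            effect[idx, s] = marker_boost * shares[name] + 1e-3

    lib = rng.uniform(*config.library_size_range, size=n_samples)
    mean_matrix = mu[:, None] * effect[:, labels - 1] * lib[None, :]
    counts = _nb_sample(rng, mean_matrix, config.nb_dispersion)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    is_mito = pd.Series(False, index=gene_ids)
    is_mito.loc[mito_genes] = True

    # survival: exponential with subtype hazard; independent exponential
    # censoring, its rate solved so the expected censored fraction equals
    # censoring_rate (dependent censoring would bias downstream Cox fits)
    hazards = np.asarray(config.baseline_hazards)[labels - 1]
    t_event = rng.exponential(1.0 / hazards)
    if config.censoring_rate > 0:
        c_rate = _censoring_hazard(config)
        t_cens = rng.exponential(1.0 / c_rate, size=n_samples)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    else:
        event = np.ones(n_samples, dtype=int)
        time = t_event
    time = np.maximum(time, 1e-6)

    stage_p1 = np.asarray(config.stage_subtype_odds)[labels - 1]
    r = rng.random(n_samples)
    stage = np.where(r < stage_p1, 1,
                     2 + rng.integers(0, 3, size=n_samples))
    age = rng.normal(65.0, 10.0, size=n_samples)
    sex = rng.integers(0, 2, size=n_samples)

    survival = pd.DataFrame(
        {"time": time, "event": event, "age": age, "sex": sex,
         "stage": stage},
        index=sample_ids)

    return SyntheticDataset(
        counts=CountMatrix(counts_df, is_mito),
        true_labels=pd.Series(labels, index=sample_ids, name="subtype"),
        survival=survival,
        lineage_sets=LineageGeneSets(lineage),
        true_program_genes=program,
        config=config,
    )


def generate_factorizable_matrix(n_genes: int, n_samples: int, rank: int,
                                 seed: int = 0) -> ExpressionMatrix:
    """Strictly positive V = W0 @ H0 with an exact factorization of ``rank``.

    Used as an oracle input for NMF: the global optimum of the KL objective
    on this matrix is zero.
    """
    if rank > min(n_genes, n_samples):
        raise ValueError(
            f"rank {rank} exceeds min(n_genes, n_samples) = "
            f"{min(n_genes, n_samples)}")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    rng = np.random.default_rng(seed)
    W0 = rng.uniform(0.5, 1.5, size=(n_genes, rank))
    H0 = rng.uniform(0.5, 1.5, size=(rank, n_samples))
    V = W0 @ H0
    df = pd.DataFrame(V,
                      index=[f"G{i:05d}" for i in range(n_genes)],
                      columns=[f"S{j:04d}" for j in range(n_samples)])
    return ExpressionMatrix(df)


def config_to_dict(config: SyntheticConfig) -> dict:
    return asdict(config)
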