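# subtypekit

Consensus-NMF discovery of tumor expression subtypes from bulk RNA-seq,
minimal nearest-centroid gene signatures, lineage-infidelity scoring, and
centroid-distance prognostic Cox models — packaged as a tested, fully
reproducible pipeline.

## The problem

Bulk RNA-seq cohorts of tumors (the motivating setting is lung
adenocarcinoma in never-smokers) are routinely stratified into molecular
subtypes that differ in biology and outcome. The workflow implemented
here:

1. **Normalization and gene selection.** Raw counts are library-size
   corrected by median-of-ratios size factors; genes with median
   normalized level > 1, excluding mitochondrial genes, are ranked by
   variance and the top 5000 feed the factorization.
2. **Consensus NMF.** The expression matrix `V` (genes × samples) is
   factorized as `V ≈ W·H` with non-negative `W`, `H` by multiplicative
   Kullback–Leibler updates. For each candidate rank `k`, many random
   restarts are summarized in a consensus matrix `C`, where `C[i,j]` is
   the fraction of runs in which samples `i` and `j` share an argmax-`H`
   cluster. The cophenetic correlation of the dissimilarity `1 − C`
   measures stability; the rank maximizing it is selected, and samples
   take the cluster of their largest `H` coefficient.
3. **Gene specificity.** Each gene's basis profile
   `p(i,q) = W[i,q] / Σ_q W[i,q]` is scored by normalized entropy,
   `S_i = 1 + (1/log₂k) Σ_q p(i,q) log₂ p(i,q)`:
   0 for a gene loading all programs equally, 1 for a single-program gene.
4. **Minimal signature (ClaNC-style).** Genes are ranked per class by
   class-vs-rest pooled t-statistics, each gene is owned by the class
   maximizing |t|, and the top `N` per class form a `k·N`-gene signature
   with per-class centroids (`N = 20, k = 3` gives the canonical 60-gene
   signature). Signature size is chosen by repeated stratified 70/30
   cross-validation; new samples are classified to the nearest centroid
   (Euclidean), or by highest Pearson correlation to the centroids after
   per-gene median centering.
5. **Lineage-mixing score.** With disjoint marker sets for the LUAD, LUSC
   and NET histological lineages, `S_type` is the fraction of total marker
   expression carried by that lineage's markers and
   `S_mix = 1 − max(S_LUAD, S_LUSC, S_NET)` quantifies lineage infidelity
   (0 = pure lineage, 2/3 = uniform mixing for three lineages).
6. **Prognostic models.** The subtype enters survival models as three
   continuous features — the Euclidean distances of each sample's
   signature-gene vector to the three subtype centroids. Nine Cox
   proportional-hazards model variants (stage, driver mutations, grade,
   expression distances and their combinations) are trained on one cohort,
   transferred coefficient-for-coefficient to a second, and compared by
   Harrell's concordance index and likelihood-ratio tests.

The cohort data such analyses are usually run on is controlled-access, so
the package ships a first-class synthetic-data module: negative-binomial
counts (variance `μ + φμ²`) with planted subtype gene programs,
library-size variation, high-baseline mitochondrial genes, subtype-
dependent cross-lineage marker expression, and subtype-linked exponential
survival with independent censoring and a stage–subtype association. Gene-
level baselines live on their own seed so that independently seeded cohorts
are draws from one shared transcriptome — the setting in which signatures
transfer between studies.

## Worked example

```python
from subtypekit import (SyntheticConfig, generate_dataset, normalize_counts,
                        select_genes, consensus_over_runs, select_rank,
                        assign_clusters, build_signature, lineage_score)
from sklearn.metrics import adjusted_rand_score

cohort = generate_dataset(SyntheticConfig(seed=7))   # 3 subtypes x 50 tumors
selected = select_genes(normalize_counts(cohort.counts))
results = [consensus_over_runs(selected, rank, n_runs=20, base_seed=100 * rank)
           for rank in (2, 3, 4)]
for r in results:
    print(f"rank {r.rank}: cophenetic = {r.cophenetic:.4f}")
k = select_rank(results)
best = next(r for r in results if r.rank == k).best_fit
labels = assign_clusters(best).labels
print(f"selected rank: {k}")
print(f"ARI vs planted subtypes: "
      f"{adjusted_rand_score(cohort.true_labels, labels):.3f}")
sig = build_signature(selected, labels, n_per_class=20)
print(f"signature: {len(sig.genes)} genes ({sig.n_per_class} per subtype)")
smix = lineage_score(normalize_counts(cohort.counts),
                     cohort.lineage_sets)["S_mix"]
print("mean S_mix by subtype:")
print(smix.groupby(cohort.true_labels).mean().round(3).to_string())
```

prints

```
rank 2: cophenetic = 0.9944
rank 3: cophenetic = 1.0000
rank 4: cophenetic = 0.9989
selected rank: 3
ARI vs planted subtypes: 1.000
signature: 60 genes (20 per subtype)
mean S_mix by subtype:
subtype
1    0.022
2    0.068
3    0.373
```

The consensus is most stable at the planted rank 3, the cluster
assignment reproduces the planted labels exactly, and the third
("chaotic-like") subtype — simulated with 60% off-lineage marker
expression — stands out with a five-fold higher mean lineage-mixing score.

## Command line

Each stage is also a subcommand of the `subtypekit` console script
(`simulate`, `normalize`, `subtype`, `signature`, `classify`, `lineage`,
`risk`, `all`), exchanging gene × sample TSVs, clinical TSVs and signature
JSON. `subtypekit all --config cfg.yaml` runs every stage and writes a
manifest with SHA-256 checksums of all artifacts; identical configurations
and seeds yield bitwise-identical manifests.

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical choices, and what the synthetic generator does and does not
emulate.
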