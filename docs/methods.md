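# Methods

This note documents the statistical models, defaults and numerical
choices behind subtypekit, and what the synthetic-data generator does and
does not emulate.

## Normalization and gene selection

Size factors are median-of-ratios: with reference genes `R` (genes with
positive counts in every sample), sample `j`'s factor is
`median_{g∈R} counts[g,j] / geomean_g`. If no gene is positive everywhere
the estimator is undefined; an explicit `allow_pseudo_reference` flag
switches to geometric means over positive entries only. A counts-per-
million mode is provided as an alternative. Size factors of an already
normalized matrix are constant — normalization is idempotent up to a
global scale.

Gene selection keeps genes with median normalized expression above a
floor (default 1) that are not mitochondrial, ranked by variance.
Variance is computed on the normalized linear scale by default, with an
opt-in `log_variance` mode (variance of log2(x+1)); the appropriate scale
depends on how heavy-tailed the data are, and both are exposed rather
than hard-coding one. Variance ties break lexicographically by gene id so
selection is deterministic.

## Consensus NMF

Factorization uses the classical multiplicative updates for the
generalized Kullback–Leibler divergence, which are monotone
non-increasing in the objective. Choices:

- **Initialization**: `W`, `H` i.i.d. Uniform(0, s) with `s = 2·sqrt(mean(V)/k)`,
  so the initial reconstruction matches the scale of `V`; each run is
  seeded `base_seed + run`.
- **Stopping**: the sample connectivity matrix (argmax-`H` co-membership)
  is checked every 10 iterations; the fit stops after 4 consecutive
  unchanged checks or `max_iter` (default 2000). This label-based rule is
  the natural criterion when the factorization is used for clustering.
- **ε-guard**: denominators and logs are clamped at 1e-12 to avoid 0/0.
- **Objective trace**: KL divergence recorded every 10 iterations by
  default (`objective_interval=1` traces every update; the trace is
  non-increasing within 1e-10).
- **Precision**: single fits default to float64. The consensus loop
  defaults to float32: the updates are memory-bandwidth-bound and run
  about twice as fast, while co-clustering indicators and the ranking of
  runs by final divergence are insensitive to the extra precision (the
  cophenetic coefficients agree with float64 to the printed digits on the
  test configurations). `dtype=np.float64` restores full precision.

The consensus matrix over runs is symmetric with unit diagonal. Stability
is summarized by the cophenetic correlation: average-linkage clustering of
the dissimilarity `1 − C`, then the Pearson correlation between the
pairwise dissimilarities and the dendrogram's cophenetic distances
(NaN when either is constant). The selected rank maximizes the
coefficient; ties go to the smallest rank (parsimony), and NaN ranks are
excluded with a warning. Silhouette summaries are computed three ways:
on `1 − C` (precomputed metric), on `H` columns, and on `W` rows, with
cluster/program labels from the best run.

Among the runs at the selected rank, the run with the lowest final
divergence is the model used downstream (cluster assignment, specificity,
signature training). Assignment is argmax of the sample's `H` column,
ties to the lowest cluster index; membership profiles are column-
normalized `H`.

Basis specificity is the normalized-entropy score
`S_i = 1 + (1/log₂k) Σ_q p(i,q) log₂ p(i,q)` with `0·log 0 = 0`; genes
with an all-zero `W` row are flagged NaN. `S_i` is invariant to global
rescaling of `W` and bounded in [0, 1]. For reporting, "subtype-specific
genes" are the top `m` (default 50) genes by `S_i` among genes whose
profile peaks in the cluster.

## Nearest-centroid signature

Per-class gene ranking uses the two-sample pooled t-statistic
(class vs rest). Ownership is by maximal |t|; |t| ties go to the class
where the gene is up-regulated (`t > 0`) — necessary because with two
classes the class-vs-rest statistics are exactly antisymmetric and every
gene ties — then to the first class in order. Zero pooled variance yields
signed infinities that rank above all finite statistics. The per-class
top `N` owned genes (ties by gene id) form the signature; the per-class
centroids are class means of all `k·N` genes.

Classification is Euclidean nearest centroid on the raw normalized
expression by default; an opt-in standardized mode z-scores genes (and
centroids) by the training mean/sd. Raw distance is the default because
it is the more transparent contract, but on data whose baseline
expression spans orders of magnitude the standardized mode is markedly
more robust to sampling noise in high-mean genes, and is recommended for
cross-cohort transfer. Correlation-based classification (per-gene median
centering, then highest Pearson correlation to a centroid) is provided
for transferring externally published centroids; it is invariant to
per-sample affine rescaling, which Euclidean distance deliberately is
not.

Signature size is selected by repeated stratified 70/30 splits (default
100 repeats): for each `N` in 1–30 the signature is rebuilt on the
training split and misclassification against the input labels is
recorded on both splits. The chosen `N` is the smallest whose mean test
error is within one standard error of the minimum (one-SE parsimony
rule). With planted, well-separated subtypes the error curve is flat near
zero, so the scanned range matters more than the exact rule.

## Lineage scores

For disjoint marker sets of the LUAD, LUSC and NET lineages,
`S_type = Σ expr(type markers) / Σ expr(all markers)`; the three scores
are non-negative and sum to one, and are invariant to global rescaling of
a sample. `S_mix = 1 − max(S)` is 0 iff one lineage carries all marker
expression and maximal (2/3 for three lineages) iff the scores are equal.
Samples with zero total marker expression are flagged and scored NaN.

## Survival models

Cox proportional-hazards fits use Efron tie handling (lifelines); on
monotone-likelihood non-convergence the fit retries once with a small L2
penalty (1e-4) and is flagged. Stage enters as an ordinal integer 1–4 by
default. The concordance index is Harrell's c: pairs are comparable when
the earlier time is an observed event (a death tied in time with a
censoring precedes it); tied risks count one half.

The model registry trains each of nine covariate sets — stage (A),
driver mutations/fusions (B), expression subtype as the three centroid
distances (C), histologic grade (D), and their combinations (E–I) — on a
training cohort and applies the coefficients unchanged to a test cohort.
Models whose covariates are missing from the training table are skipped
with a reason; models whose covariates are missing only in the test table
(typically grade) are evaluated on the training cohort alone. For models
adding the expression distances to a single-modality model, the
likelihood-ratio p-value against that nested model is reported (for C,
against the null model). All three centroid distances are entered despite
their correlation; the ridge fallback covers the rare degenerate fit.

Follow-up horizons (e.g. 5- or 10-year analyses) are implemented as
administrative censoring: events after the horizon become censorings at
the horizon; a horizon beyond the last observed time changes nothing.
Kaplan–Meier curves are product-limit estimates exported as step
coordinates.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

- **Counts**: NB with variance `μ + φμ²` (φ = `nb_dispersion`, default
  0.2; φ = 0 is Poisson). Baseline means are log-normal (log2 mean ~
  Normal(4, 2)), giving a realistic dynamic range and nonzero medians so
  the median filter is consequential. Mitochondrial genes draw high
  baselines (log2 ~ Normal(9, 1)) so their exclusion matters.
- **Subtypes**: `k` disjoint program gene sets (default 3 × 200 genes),
  up-shifted by `2^signature_log2fc` (default 4×) in their own subtype
  only. Per-sample library factors are Uniform(0.7, 1.4).
- **Lineages**: three disjoint marker sets; in subtype `s` with
  cross-lineage fraction `c_s`, LUAD markers carry a `1 − c_s` share of a
  fixed marker boost and LUSC/NET split `c_s` — so a subtype's expected
  `S_mix` tracks `c_s`. Defaults (0.05, 0.15, 0.60) make the third
  subtype chaotic-like.
- **Survival**: exponential event times with per-subtype hazards
  (defaults 0.010/0.020/0.045 per month: the chaotic-like subtype is the
  most aggressive), independently censored by an exponential time whose
  rate is solved numerically so the expected censored fraction equals
  `censoring_rate` (default 0.3). Stage I probability is subtype-linked
  (defaults 0.70/0.50/0.25) with the remaining mass uniform on II–IV; age
  and sex are independent noise covariates.
- **Seeding**: the cohort `seed` drives sampling noise, library sizes,
  labels and survival. Gene-level baselines are drawn from a separate
  `gene_param_seed` (fixed by default) so differently seeded cohorts
  share one transcriptome; this is what makes cross-cohort signature
  transfer meaningful, mirroring a signature trained in one study and
  validated in another.

What the generator does **not** emulate: batch effects, fusions and
driver mutations (registry models needing them are skipped on purely
synthetic tables), deconvolvable cell-type mixtures, tumor purity
variation, or gene–gene correlation beyond the planted programs. Tests
passing on this generator therefore demonstrate that the machinery
recovers the structure it targets under its own model assumptions — not
that real cohorts satisfy those assumptions.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` exercise the study
configuration (three subtypes × 50 samples, 2000 genes) for rank/cluster
recovery (30 consensus runs per rank over ranks 2–6, ten cohort seeds)
and cross-cohort transfer, with smaller cohorts and run counts for unit
tests; Cox parameter recovery uses 200 simulations at n = 500 and 1000.
These sizes give stable pass/fail behavior for the statistical
assertions while keeping a full run to a few minutes.

## Known limitations

- Rank selection by cophenetic maximum can tie: on very clean data both
  rank 2 (stably merging the same two subtypes) and the true rank 3 reach
  a coefficient of exactly 1.0; the documented tie-break prefers the
  smaller rank. Inspecting the full curve (`cophenetic_curve`) alongside
  the silhouettes is recommended over trusting the argmax alone.
- The multiplicative updates converge sublinearly; exact factorizations
  are recovered to high precision but slowly (thousands of iterations
  with early stopping disabled).
- Cross-validated error rates are estimated against the input labels, so
  they measure signature fidelity to the discovery clustering, not
  against an external truth.
- Efron tie handling makes "duplicate every sample" only approximately
  neutral for coefficient estimates (duplication creates ties), unlike
  under Breslow.
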