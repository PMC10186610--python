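# Methods

This note documents the statistical models, the synthetic-data generators,
the numerical choices, and the design decisions behind `lhasig`.

## Differential expression

Counts are normalized by median-of-ratios size factors: the reference per
gene is its geometric mean across samples, computed over genes positive in
every sample (falling back to genes positive in ≥ 90 % of samples with
per-sample available ratios when no gene is positive everywhere), and the
factors are rescaled to geometric mean 1.  Expression is
`log2(count/sf + 1)`; the pseudocount of 1 keeps zeros at zero.

The two-group test is ordinary least squares on the log scale with the
group indicator plus nuisance covariates (sex, batch, library type) in the
design; the group coefficient is the log2 fold change (case − control) and
its t statistic gives a two-sided p with the residual degrees of freedom.
This is a deliberate substitution for negative-binomial Wald testing: it is
fully specified, dependency-light, and its type-I calibration is verified
on null simulations (the fraction of nominal p < 0.05 on 2,000 null genes
at n = 30+30 lies in [0.04, 0.06]).  Genes with zero residual variance get
t = 0 and p = 1 instead of being dropped, so the gene universe stays
aligned across cohorts.  DEG calling uses strict inequalities — p < 0.05
and linear fold change > 1.2 — so genes exactly at a threshold are not
called; a
p-only mode (p < 0.01, direction from the fold-change sign) mirrors the
rule used for microarray validation cohorts.  Nuisance covariates may
alternatively be removed beforehand by per-gene OLS residualization (with
the gene grand mean restored); `group` and `age` are refused in that
design so the biological contrast can never be absorbed.

## Consensus sets and the permutation overlap null

Consensus DEGs are the exact k-way intersection of directional per-cohort
sets.  The null repeatedly draws, for each cohort, a same-sized gene set
uniformly without replacement from the **universe of genes tested in all
cohorts** (the intersection of the DE tables — the natural default when no
universe is stated) and records the intersection size; the analytic
expectation is N·∏(nᵢ/N), and the empirical p uses the add-one rule
(1 + #{null ≥ observed})/(n_perm + 1), which cannot be zero.  Up- and
down-regulated sets are permuted separately.  Sampling is uniform; no
expression-matched (detectability-preserving) sampling is attempted.

## Age-trajectory selection

Age association is a nested-model F test (decade-bin factor over
covariates-only), BH-adjusted, significant at padj < 0.05; all six decade
bins (20–29 … 70–79, the brackets of population expression resources) must
hold at least two samples.  Profiles are per-gene z-scores across samples
averaged within bins (a constant gene scores 0).  Grouping is
average-linkage agglomerative clustering on 1 − Pearson of the profiles,
cut at height 0.3 (minimum within-group correlation 0.7); agglomerative
clustering replaces divisive clustering because it is deterministic and its
recovery is tested (ARI ≥ 0.9 on planted archetypes).  Ties and ordering
are fixed by lexicographic gene id.

The slope statistic is the product of the last two consecutive bin-mean
differences; the product form is what makes "positive slope = consistent
change beyond 50" true, since a sign change between the last two
differences flips the product negative.  Selection rules, in order:

* groups smaller than `min_size = 3` are never selected (a two-gene group
  is discarded regardless of slope);
* a group whose 70–79 mean exceeds every earlier bin by
  `spike_delta = 0.5` z-units is selected as late-induction — an explicit
  numeric rule for patterns that would otherwise require selection by
  inspection;
* otherwise a group needs slope > 0 **and** |m₇₀₋₇₉ − m₆₀₋₆₉| ≥
  `flat_epsilon = 0.05`.  The epsilon is calibrated so that a near-flat
  trajectory whose final-decade gap is ≈ 0.04 z-units (e.g. bin means
  −0.16494 then −0.20438) is rejected even though its slope is positive,
  while all monotone archetypes pass with a wide margin.

Direction is the sign of m₇₀₋₇₉ − m₅₀₋₅₉.  LHA sets are the consensus sets
minus the union of selected aging sets and any external aging list; every
removal is logged with its source.

## GSEA

Pre-ranked, weighted Kolmogorov–Smirnov running sum: hits increment by
|score|^p normalized over in-set scores (p = 1 by default, p = 0 reduces to
the classic KS statistic and is retained for oracle testing), misses
decrement by 1/(N − m); ES is the signed maximal deviation.  The null
permutes gene labels (equivalently, draws random same-sized sets) — sample
permutation is impossible on a pre-ranked input.  NES divides ES by the
mean magnitude of same-sign null scores; the p-value is the same-sign
empirical tail with the add-one rule and is exactly discrete-uniform under
the null (verified by KS test).  Fewer than three same-sign null scores
yields NES/p = None with a warning.  Cell-type rankings use mean expression
in the target type minus the mean over all other cells, ties broken by
gene id — the documented default where no ranking metric is prescribed.

## Deconvolution

Per-sample non-negative least squares of the bulk profile on the signature
columns over the shared genes (≥ 10 required), then normalization to sum 1.
NNLS substitutes the ν-SVR used by web-based deconvolution services: it is
deterministic,
dependency-light, and recovers noise-free mixtures to machine precision
whenever the signature has full column rank; the substitution is recorded
in the estimate metadata.  Active-set zeros are exact, so the
zero-proportion filter drops cell types estimated at 0 in more than 50 % of
samples (tolerance 1e-10) and renormalizes the rest, preserving ratios
among retained types.  Group comparisons are per-type Wilcoxon rank-sum
with BH correction.

## Co-expression modules

Unsigned adjacency |cor|^β.  The scale-free fit regresses log10 degree
density on log10 degree over ten equal-occupancy bins — density, i.e. bin
fraction divided by bin width, since equal-occupancy bins make raw
fractions constant by construction — with the R² negated when the slope is
positive; the smallest power reaching R² ≥ 0.8 is chosen, else the max-R²
power.  The topological overlap matrix is
TOMᵢⱼ = (Σᵤ aᵢᵤaᵤⱼ + aᵢⱼ)/(min(kᵢ, kⱼ) + 1 − aᵢⱼ) with unit diagonal.
Modules come from average-linkage clustering on 1 − TOM with a *static*
cut at height 0.99 — a simpler, deterministic replacement for dynamic tree
cutting; clusters below 30 genes fall into module 0, and modules whose
eigengenes correlate above 0.9 are merged iteratively (the 0.1
dissimilarity threshold acts as this module-merge height).  A module eigengene is the first right
singular vector (over samples) of the standardized module submatrix,
sign-fixed to correlate non-negatively with the module's mean profile so
results are reproducible across linear-algebra backends.  Sample outliers
are flagged by standardized sample connectivity (sum of inter-sample
correlations) below −3 — a concrete stand-in for an unspecified
"unsupervised clustering" criterion.

## Methylome

Delta beta is mean(group B) − mean(group A) per probe (direction
configurable; the default puts the long-lived group second so that global
demethylation appears as negative skew).  Skewness is the biased
Fisher–Pearson g1 = m₃/m₂^{3/2}.  DMP calling is Welch's t per probe on
beta values (an M-value mode is provided, since beta variance is
heteroscedastic near the boundaries), BH-adjusted, with strict cuts
|Δβ| > 0.1 and padj < 0.01.  Calling is probe-level with probe→gene
mapping; no spatial merging of adjacent probes into regions is attempted
(the region definition is unstated).  Genes hit in both directions are
reported in both sets with a conflict flag.

## Regulatory analyses

Intervals are 0-based half-open throughout (BED convention; 1-based inputs
are converted at the reader).  Promoters are TSS − 2000 to TSS + 500,
strand-aware and clipped at zero — the window is a configurable default
since "core promoter" carries no coordinates.  Overlap uses a
per-chromosome sorted sweep verified against the all-pairs oracle.
Insulin-response classification is the Pearson correlation with the
reference gene across ≥ 3 stimulus conditions, classified by sign at
|r| ≥ 0.3 (an exposed default).  TF specificity
shifts all scores to a positive scale (global minimum + 0.1) and keeps TFs
whose minimum over phagocyte types strictly exceeds `fold_cut` times their
maximum elsewhere; a score ratio exactly at the cut is rejected (pinned by
test).  TF-target and binding-ratio enrichment use the shared upper-tail
hypergeometric test.

## Synthetic data: what it emulates, and what it does not

The generators emulate the statistical structure of the pipeline's
real-world inputs:

* **Multi-cohort counts** — negative binomial with log-normal gene means
  (median ≈ 100 counts, log-sd 1), a single dispersion (0.1; variance
  μ + 0.1μ²), per-sample library-size factors in [0.7, 1.3], planted
  multiplicative case effects 2^1.0 on shared genes, and multiplicative
  log-normal sex/batch/library effects (sd 0.3 on the log2 scale — strong
  enough that covariate adjustment is necessary for calibration).  Batch
  and library labels alternate with different periods so the nuisance
  design is full rank.
* **Age series** — six decade bins, 20 samples per bin by default, planted
  genes following named archetypes (monotone up/down beyond 50,
  rise-then-fall peaking at 60–69, late spike confined to 70–79, flat)
  defined on the z scale and converted to log2 fold units by an amplitude
  of 1.
* **Cell profiles** — Gaussian log-expression with disjoint elevated marker
  programs per type and program blocks elevated in designated type groups.
* **Methylomes** — betas as the inverse logit (base 2) of Gaussian
  M-values (baseline sd 2, noise sd 0.5); planted probes shift group B on
  the M scale so the expected beta difference equals the ±0.2 target; a
  configurable fraction of probes receives an exponentially distributed
  negative M shift, producing global hypomethylation with negative
  delta-beta skew.
* **Mixtures** — signature × proportions with multiplicative log-normal
  noise (sd 0.1), Dirichlet(2) proportions.
* **Co-expression** — latent-factor blocks (loading 0.9) plus independent
  noise genes; one block's factor is tied to sample age (loading 0.8).

Not emulated: read-level sequencing artifacts, real gene identities or
annotations, cross-cohort batch-integration pathologies, probe spatial
autocorrelation, and cell-type proportions' compositional coupling to
expression.  Passing tests therefore demonstrate correctness and
calibration of the algorithms under the stated generative assumptions, not
performance on any particular real cohort.

## Problem sizes and reproducibility

The recovery experiments run at the conditions stated above (2,000 genes,
three cohorts of 30+30, 100 planted genes per class, 20 samples per decade
bin, 2,000 probes at 20 per group, three 50-gene blocks among 250 genes);
the bundled demo pipeline uses a 800-gene universe so a full run completes
in seconds.  Every random draw flows from an explicit seed through stable
per-stage sub-seeds (SHA-256 of "seed:stage"), k-means uses a fixed seed
with 10 restarts, and all file output uses fixed numeric formatting, so a
rerun with the same seed is byte-identical — which the test suite asserts.

## Known limitations

* The OLS t-test loses power relative to count models at very low counts;
  calibration, not power, is its design goal.
* The static tree cut can split elongated modules that dynamic cutting
  would keep; the merge step compensates only when eigengenes correlate.
* The permutation overlap null assumes exchangeable genes; detectability
  matching would require per-gene inclusion probabilities.
* Probe-level DMP calling with gene mapping cannot reproduce region counts
  from spatially merged definitions.
* The spike rule and flatness epsilon are explicit numeric rules for
  pattern judgements that are often made by inspection; both are exposed
  in the configuration and reported per group in the selection report.
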