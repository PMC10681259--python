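# Methods

## RIP-seq enrichment model

Counts Y_gj for gene g in sample j are modelled as negative binomial with
mean μ_gj = s_j · exp(β_{g,cond(j)}) and variance μ + α_g μ² (dispersion
parameterisation). The contrast of interest is IP versus input;
log₂FC_g = (β_{g,IP} − β_{g,input}) / ln 2.

**Size factors** are median-of-ratios: for the genes with strictly positive
counts in every sample, each sample's factor is the median of its counts
divided by the per-gene geometric mean, rescaled so the factors' geometric
mean is 1. Genes with any zero are excluded from the reference only — they
are still normalised and tested. A matrix with no all-positive gene is
rejected rather than silently falling back to another scheme.

**Dispersion** is per-gene method of moments on normalised counts:
α̂ = (s² − m̄)/m̄² within each condition with ≥ 2 replicates, averaged across
conditions and floored at 1e-8. No empirical-Bayes shrinkage toward a
mean–dispersion trend is applied: the estimator is deliberately the simplest
defensible one, and the tests measure its consequences (null calibration and
parameter recovery at 3 vs 3) rather than asserting agreement with any
particular shrinkage scheme. The practical consequence, visible in the test
suite: with 3 replicates per group the Wald p-values are slightly
non-uniform under the null (KS ≈ 0.07 at 2000 genes) purely from dispersion
noise — supplying the true α, or using 10 replicates, restores KS ≈ 0.02 —
but the downstream error rates that matter (BH at 0.05, Vfactor at 50)
remain conservative.

**Fitting.** With a two-group design and offsets, the groups decouple into
one-parameter NB GLMs solved by Fisher scoring (score Σ(y−μ)/(1+αμ),
expected information Σ μ/(1+αμ)), initialised at the log normalised mean,
steps clipped to ±10, convergence |Δβ| < 1e-8, max 100 iterations,
vectorised across genes. Standard errors come from the observed-at-MLE
expected information; the Wald p is the two-sided normal tail. Zeros are
handled by the likelihood — no pseudocounts. A condition whose counts are
all zero makes the MLE diverge: such genes are flagged `degenerate`, get NA
p, and report a half-count log₂FC ((m̄_IP+0.5)/(m̄_input+0.5) on normalised
means) so downstream tables stay finite. Non-convergence is flagged, never
silent.

**Vfactor selection.** Vfactor = log₂FC × (−log₁₀ p) with p floored at
1e-300; the raw Wald p is used by default (the adjusted p is available by
flag — with three-replicate designs the raw-p reading is the literal one and
drives selection). The threshold is a strict inequality: Vfactor must exceed
50, a value exactly at 50 is excluded. Depleted genes get negative Vfactors
and are never selected. BH adjustment is standard step-up with monotonicity,
NA-propagating, applied across all tested genes (no independent filtering or
outlier replacement; at these scales the effect on padj is marginal and the
simpler behaviour is easier to reason about).

## AP-MS interactor calling

The pipeline is a fixed, order-enforced chain; each stage checks that its
predecessor ran, so e.g. imputing before the valid-value filter raises.

1. **Evidence filter** — groups with < 2 razor+unique peptides, reverse
   hits, or potential contaminants are removed; counts go to a filter log.
2. **log₂ transform** — LFQ 0 (and NaN) become explicit missing; intensity
   1 maps to log₂ = 0 and stays valid.
3. **Valid-value filter** — keep a group if ≥ 60% of bait samples or ≥ 60%
   of control samples are quantified (≥ on the exact fraction).
4. **Down-shifted imputation** — per sample j with observed mean m_j and SD
   s_j (computed after the valid-value filter, on that sample only), missing
   values ~ N(m_j − 1.8 s_j, (0.3 s_j)²), seeded. The probability an imputed
   value exceeds m_j is Φ(−6) ≈ 1e-9. The imputation presumes left-censored
   (MNAR) missingness; the generator plants exactly that mechanism so the
   premise is testable. Width and downshift are in per-sample SD units.
5. **Moderated test** — pooled-variance Student t per group (Welch by flag);
   d = Δ/(se + s₀) with s₀ = 0.1 by default. s₀ damps small fold changes
   with fluky-small variance estimates; it is the curvature of the volcano
   significance boundary.
6. **Permutation FDR** — null |d| from distinct bait/control label
   assignments, excluding the observed one (its statistics are the observed
   values, not null draws) and counting a split and its complement once when
   group sizes are equal. All splits are enumerated when fewer than n_perm
   (default 250) exist — 83 for 6 vs 3 — otherwise sampled without
   replacement, seeded. The cutoff is the smallest c with
   FDR(c) = mean-per-permutation #{|d_null| ≥ c} / #{|d_obs| ≥ c} ≤ FDR
   target, after enforcing FDR(c) non-increasing in c (median aggregation by
   flag). Enrichment-side groups (Δ > 0, |d| ≥ c) are the reported
   interactors; depleted-side hits are classed separately, mirroring the
   right-side reading of the volcano.

A measured operating characteristic worth knowing: with 6 vs 3 samples the
row variances have 7 df, and a planted interactor at 5 within-SD units tops
the d ranking in ~98 of 100 runs, not always — about 2% of runs pair a
~4-sigma null mean difference with a collapsed variance estimate, or an
unlucky planted draw. The property test asserts the ≥ 95/100 rate the
statistic actually achieves at s₀ = 0.1. Sensitivity for planted
interactors is measured against those surviving the evidence and
valid-value filters: a group deliberately removed for having one peptide is
not a miss of the statistic.

## Set statistics

Over-representation is the one-sided upper-tail hypergeometric
P[X ≥ k | N, K, n] (one-sided Fisher exact), summed in log space over the
feasible support via log-gamma, so p-values far below 1e-100 are exact
rather than underflowing. The universe defaults to the tested genes
(overridable); BH is applied across categories. The composition figure
reported alongside p is k/n, the in-category fraction of the query.
Intersections and overlap counts are exact set operations; overlap p is
computed only when a universe is stated.

Densitometry: per-lane relative abundance = target band / reference band;
each overexpression replicate's fold change is its relative abundance over
the mean control relative abundance (the pairing is against the control
mean, as no lane pairing is assumed); the test is a two-sided one-sample t
on log fold changes against 0, requiring ≥ 3 replicates per condition.

## Synthetic data

`simulate_ripseq` draws baseline means from a log-normal (median 200,
log-SD 1), library factors uniform on [0.7, 1.4], and NB counts (variance
μ + αμ², α = 0.05 default; α = 0 is exactly Poisson) for 3 input and 3 IP
replicates over 2000 genes; 5% of genes get a planted log₂FC of 3 in IP.
`simulate_proteome` draws latent log₂ intensities N(25, 2²) per group with
within-group SD 0.5 over 1000 groups for 6 bait and 3 control samples; 5%
of groups get +3 log₂ in bait; each value is observed with logistic
probability 1/(1+e^{−(x−21)}) (midpoint 21, slope 1 — detection odds double
per log₂ unit), unobserved values stored as LFQ 0; 5% of groups get exactly
one razor+unique peptide and 1% a contaminant flag to exercise the filters.
`simulate_annotation` assigns background category membership at 3% and
inflates it 8-fold (to ~24%) inside a designated target list. All three are
pure functions of (config, seed) and return the planted truth alongside the
data.

What the generators do not emulate: count outliers and batch effects,
mean–dispersion trends, protein-group co-quantification structure,
match-between-runs artefacts, or any sequence-level biology. Passing
recovery tests therefore demonstrate the statistics' behaviour under their
own assumptions at realistic sizes, not robustness to everything real data
can do.

## Numerical and design choices

- p floored at 1e-300 before −log₁₀ (recorded above); α floored at 1e-8.
- Fisher-scoring steps clipped at ±10 to survive wild initialisations.
- Ties at the Vfactor threshold: strict ">", exactly as the selection rule
  is stated.
- IP and input are independent groups — no pairing term.
- Two-sample t with zero variance on both sides: t = 0, p = 1 for equal
  means; infinite t with p = 0 (degenerate, visible in the statistic) for
  unequal means.
- TSV dialect: tab-separated, UTF-8, "." decimal, NA token "NA"; gene ids
  case-sensitive, systematic names canonical.
- Problem sizes throughout (2000 genes, 1000 protein groups, ≤ 100-seed
  repetition suites) are the study's design geometry and keep the full test
  suite under ten seconds.

## Known limitations

- The NB test is not a bit-for-bit reimplementation of any published
  differential-expression package: no dispersion shrinkage, no independent
  filtering, no outlier replacement. Its contract is calibration and
  recovery, which the acceptance suite measures.
- The permutation-FDR estimator is the counting estimator; with very few
  distinct permutations (small designs) its resolution is limited to
  multiples of 1/n_perm.
- The s₀ parameter is not auto-tuned; 0.1 is a conventional default and the
  right value for a given dataset depends on its variance structure.
- Densitometry pairing assumes replicates are exchangeable within condition;
  if lanes are paired across conditions a paired design would be sharper.
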