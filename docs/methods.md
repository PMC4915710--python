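# Methods

## Model and assumptions

`grsmr` implements two-sample Mendelian randomization with a weighted
genetic risk score (GRS) as the instrumental variable, operating on GWAS
summary statistics. The instrument assumptions are the usual three: each
SNP is associated with the exposure (relevance), independent of
confounders of the exposure–outcome relation (exchangeability), and
affects the outcome only through the exposure (exclusion). The estimator
additionally assumes the SNPs are mutually uncorrelated (no LD between
instrument SNPs) and that exposure and outcome effects come from
non-overlapping samples, so their estimation errors are independent.

Under these assumptions the per-SNP ratio β_j/ω_j estimates the same
causal slope α for every j, and the inverse-variance-weighted (IVW)
combination

    α̂ = Σ ω_j β_j se_j⁻² / Σ ω_j² se_j⁻² ,  se(α̂) = (Σ ω_j² se_j⁻²)^(−1/2)

is the maximum-likelihood slope of a weighted regression of β on ω through
the origin with fixed weights se_j⁻² (the uncertainty in ω is ignored, the
standard summary-statistics convention; with a strong exposure GWAS the
attenuation is well under 1% at the default simulated conditions).
Inference is Wald with the standard-normal reference; the 95% CI
multiplier is Φ⁻¹(0.975) = 1.959964 at full precision, rounded only in
report tables.

The canonical effect scale is per one-unit increase in the natural-log
exposure. Because ln-scale effects are symmetric percentages (sympercents,
1 unit = 100 s%), presentation "per 10 s% increase" is an exact rescaling
by 0.1 of both α and se(α) (`MRResults.rescale(0.1)`); the Wald z and
p-value are scale-invariant.

## Harmonization

Instrument and outcome tables are joined by rsid. Allele matching is by
nucleotide identity only — no strand inference: consortium summary files
are assumed strand-aligned, and silent strand flips are better surfaced
than guessed at. Records coded on the opposite allele have β sign-flipped;
allele sets matching neither orientation are dropped with reason
`allele_mismatch`; palindromic (A/T, C/G) SNPs are retained but flagged,
or dropped in strict mode. A SNP absent from the outcome table is replaced
by the eligible proxy with the highest LD, requiring r² strictly above 0.9
(configurable), ties broken by smallest distance then lexicographic rsid;
with no eligible proxy the SNP is dropped with reason `missing`, which is
also the default when no proxy table is supplied. Because a proxy is a
different variant, allele reorientation against the original SNP is only
attempted when the nucleotides happen to match; otherwise the proxy record
is taken as supplied (assumed pre-oriented to the exposure-raising allele)
and flagged in the audit table. Every decision is written to a
per-analysis audit TSV (`rsid, action, reason`).

## Heterogeneity and pruning

Pleiotropy manifests as dispersion of the per-SNP ratios about the fitted
slope. Cochran's Q with IVW weights,

    Q = Σ se_j⁻² (β_j − α̂ ω_j)² ,  df = M − 1,

is referred to the chi-square upper tail; p_het < 0.05 (uncorrected,
deliberately conservative) flags heterogeneity. Pruning removes the single
SNP with the largest Q contribution at the current fit, refits α, and
repeats until p_het ≥ the threshold; ties break lexicographically by rsid
so the trace is deterministic. Refitting after each removal (rather than
holding α fixed) matches the repeat-the-analysis reading of the procedure.
Pruning never goes below 2 markers (Q needs df ≥ 1); reaching that floor
while still heterogeneous sets a warning flag on the trace rather than
raising. Leave-one-out sensitivity refits the estimate once per excluded
SNP; the individual-level analogue reports the Nagelkerke ΔR² per
18-minus-one subset.

## Individual-level stage

Per-person scores are Σ_j ω_j g_ij over SNPs passing each exposure
p-value threshold (default scan: 1e-4, 0.001, 0.01, 0.05, 0.1), then
z-standardized within cohort (population SD) — standardization is
per-cohort because the analysis is per-cohort-then-meta, so each cohort's
OR is per 1 SD of its own score distribution. Association is logistic:
case status on intercept + score + principal components (up to 10; however
many the cohort provides), fitted by IRLS via `statsmodels`
GLM–Binomial (≤100 iterations, parameter tolerance 1e-8); non-convergence
or non-finite standard errors raise with diagnostics. Variance explained
is Nagelkerke's max-rescaled Cox–Snell pseudo-R², `R²_CS / (1 − exp(2
ll_null / n))` with `R²_CS = 1 − exp(2(ll_null − ll_full)/n)`, comparing
the covariates-only and covariates-plus-score models. Cohorts are pooled
by fixed-effects inverse-variance meta-analysis; the pooled ΔR² is the
sample-size-weighted mean of cohort values (a presentation convenience —
the pooling rule for pseudo-R² is not standardized).

## Synthetic data

The generators encode exactly the assumptions the estimator makes, so the
calibration tests are a closed loop: if the estimator's coverage or test
size drifted, it would be an implementation fault, not model
misspecification.

Summary-level (`simulate_summary`): effect-allele frequencies are
Uniform(0.05, 0.5); true weights are half-normal draws jointly scaled so
Σ ω² · 2f(1−f) equals the target score R² on a unit-variance ln exposure;
reported weights add Normal noise with the per-allele GWAS standard error
`se_ω = (2f(1−f) n_exposure)^(−1/2)`; outcome effects are
`β_j ~ N(α_true ω_j + δ_j, se_β,j)` with
`se_β = (2f(1−f) n_eff)^(−1/2)`, `n_eff = n_cases n_controls / n_total`
for binary outcomes, and δ_j a direct (pleiotropic) effect drawn
N(0, pleiotropy_sd) for a seeded subset of round(fraction · M) SNPs.
Exposure-side and outcome-side noise use independent child streams of one
seed, making the two-sample structure explicit; a truth record carries all
latent values.

Defaults are the flagship conditions of the analysis the package
implements: M = 18, exposure GWAS n = 66,185 (the scale of the CRP
discovery meta-analysis), score R² = 0.05 (0.02 for the four-SNP
gene-region instrument), and 34,241 cases / 45,604 controls
(schizophrenia-scale). For planted-outlier experiments, pleiotropy_sd
defaults to 0.25 on the log-OR scale — at the default sample sizes this is
roughly 10–25× the per-SNP se_β, i.e. the "direct effect much larger than
sampling noise" regime those experiments are defined for.

Individual-level (`simulate_cohort`): dosages are Binomial(2, f); the
latent ln exposure is the centered true-weight score plus Gaussian noise
scaled so the score explains `grs_r2_target` of its unit variance;
principal components are standard normal with N(0, pc_effect_sd) liability
coefficients; case status is Bernoulli with logistic probability, the
intercept solved numerically (Brent) so the expected case fraction matches
the target. The desk-scale direction-recovery conditions are 6 cohorts ×
3,000 individuals with α_true = −0.15 — a deliberately scaled-down
analogue of a 36-cohort consortium stage; at these sizes the pooled
direction is recovered in ≈98–99% of replicates.

What the generators do *not* emulate: LD between instrument SNPs,
population stratification beyond simple PC covariates, sample overlap
between exposure and outcome GWAS, winner's-curse in weight selection, and
family structure. Passing tests therefore demonstrate correctness of the
estimators and procedures under their own assumptions, not robustness of
real-data conclusions to violations of those assumptions.

## Panel orchestration and multiple testing

A panel run crosses each instrument with each outcome: harmonize →
estimate → F-statistic → Q, then a second pass re-estimates every
heterogeneous analysis (p_het below the pruning threshold) after stepwise
pruning. The Bonferroni threshold is the global level divided by the
number of independent outcome sample sets (32 for the reference panel:
0.05/32 = 0.0016 at 4-decimal presentation), not by instruments ×
outcomes, because each sample set contributes one primary test.
Significance tiers use inclusive boundaries: p ≤ Bonferroni is
significant, Bonferroni < p ≤ 0.05 is nominal evidence, p > 0.05 is none.
Per-analysis failures (bad tables, empty joins) are recorded in the run
log and skipped. Reruns with the same config and seed are byte-identical.

The bundled panel metadata (`grsmr.datasets.outcome_panel`) transcribes
the 32-outcome consortium panel's sample sizes; two totals (small-vessel
ischemic stroke, amyotrophic lateral sclerosis) are printed inconsistently
across the source's own tables and are stored as the internally consistent
cases + controls sums (6,552 and 12,263). The coronary-artery-disease
F-values printed in the source tables cannot be reproduced from that
panel's n = 184,305 under the stated formula (they correspond to an
earlier data release) and are not treated as reference values here.

## Numerical choices

- Degenerate inputs raise typed errors: empty instruments, all-zero
  weights, zero-variance scores, single-class phenotypes, se ≤ 0.
- Q on a single marker is undefined and reported as absent rather than 0.
- Tie-breaks (proxy choice, pruning order) are deterministic and
  documented above; identical inputs give identical outputs, and
  permuting SNP order changes results only in the last floating-point ulp
  (summation order).
- All simulation randomness flows through `numpy.random.SeedSequence`
  spawning, so cohort sets and replicate streams are reproducible and
  mutually independent.

## Problem sizes

The test suite and the reproduction script use 1,000 replicates for
estimator/Q calibration and coverage, 200 for pruning recovery, 100
(× 6 cohorts × 3,000 individuals) for meta-analyzed direction recovery,
and 200 single cohorts for null p-value uniformity — sizes at which the
binomial Monte-Carlo error of each rate is comfortably inside the band
being asserted, while a full run stays around a minute on one core.

## Known limitations

- No MR-Egger, weighted-median or mode-based estimators; pruning is the
  only pleiotropy handling, and it can over-prune when heterogeneity has
  non-pleiotropic causes.
- No LD-aware modelling: correlated instruments would understate se(α̂).
- Proxy handling trusts the supplied LD table; no remote panel lookup.
- The subthreshold SNP sets fed to the polygenic-score scan are taken as
  given (no clumping/pruning of the candidate list).
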