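# Methods

## The model

gremlite estimates the fraction of case-control disease risk explained by
genotyped SNPs (SNP heritability) and dissects where in the genome and in
which variant classes that heritability lives.

The forward model is the liability-threshold model. Each individual carries a
latent liability

    l = sum_i z_i b_i + e,    e ~ N(0, 1 - h2),

where `z_i` are standardized dosages of causal SNPs and an individual is a
case iff `l` exceeds `t = Phi^-1(1 - K)` for population prevalence `K`. The
analysis inverts this model without knowing the causal SNPs: relatedness at
genotyped SNPs is summarised by the genetic relatedness matrix (GRM)

    A_jk = (1/N_jk) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

with allele frequencies `p_i` estimated from the analysis sample (cases and
controls pooled) and sums taken pairwise-complete over SNPs called in both
members (`N_jk` recorded per pair; imputing zeros instead would bias the
diagonal). The phenotype — 0/1 status on the observed scale, or any
quantitative trait — is fit by the mixed linear model

    y = X b + g + e,    var(y) = V = sum_r A_r s2_r + I s2_e,

with one random effect per GRM, so a single fit can carry one genome-wide
component or a partition (per chromosome, per MAF bin, genic vs intergenic,
eQTL vs non-eQTL, region vs background) whose components are estimated
jointly and are therefore additive.

## REML optimizer

Variance components maximise the restricted likelihood

    logL_R = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1.

The ascent is average-information (AI) quasi-Newton with:

* expectation-maximisation steps for the first 3 iterations (robust far from
  the optimum) and whenever the AI system is singular;
* step-halving when an AI step would decrease the likelihood;
* variance floors at `1e-8 * var(y)`; a component pinned at the floor with a
  negative score is frozen (active-set handling), so boundary solutions
  (h2 -> 0) terminate cleanly;
* convergence when successive restricted log-likelihoods differ by < 1e-8,
  capped at 100 iterations with an explicit non-convergence flag — never a
  silent return.

Standard errors come from the inverse AI matrix at the optimum; per-component
`h2_r = s2_r / sum(s2)` carries a delta-method SE using the full
variance-component covariance.

For a single GRM the model is rotated into the eigenbasis of `B'AB`, where
`B` spans the orthogonal complement of `X`. All REML quantities become sums
over scalars; the reported `logL` subtracts `1/2 log|X'X|` so it equals the
dense-matrix criterion exactly. The rotation depends only on `(A, X)`, so
permutation tests re-fit each shuffled phenotype in O(n) — this is what makes
1,000-permutation heritability significance tests routine. The test suite
checks the optimizer against an exhaustive grid search of the dense criterion
(step 0.001) computed through an independent eigendecomposition route.

Identifiability guards: a GRM numerically equal to the identity (genetic and
residual variance inseparable) and duplicated GRMs in a joint fit (collinear
components) raise immediately.

## Liability scale and ascertainment

Observed-scale (0/1) heritability is mapped to the liability scale with the
closed-form probit correction for case-control ascertainment:

    h2_lia = h2_obs * K^2 (1 - K)^2 / (z^2 P (1 - P)),

where `K` is population prevalence, `P` the sample case fraction, and
`z = phi(Phi^-1(1 - K))`. At the symmetric point `K = P = 1/2` the factor is
exactly `pi/2`; at the melanoma study regime `K = 0.02`, `P = 0.66` it is
0.7303. SEs are scaled by the same factor. The GRM calibration (below) is
applied before REML and the liability transform after; the two only commute
approximately, and this order mirrors how a GCTA-style workflow composes
them.

## GRM calibration (imperfect tagging)

A GRM built from a filtered SNP subset predicts relatedness at unobserved
causal loci with error, biasing h2 downward. The attenuation is measured by
regressing subset-GRM off-diagonals `G_jk` on full-GRM off-diagonals `A_jk`:

    beta = 1 - (c + 1/N) var(A_jk)  =>  c = (1 - beta)/var(A_jk) - 1/N,

and the correction rescales the subset GRM by the predicted slope: off-
diagonals times `beta` (<= 1), diagonals `1 + (A_jj - 1) beta`. Shrinking the
off-diagonals raises the fitted genetic variance by ~1/beta, undoing the
downward bias; `c = 0` is an exact identity and a negative estimated `c`
(sampling noise) is clamped to zero with a warning. The exact transformation
GCTA's `--grm-adj` applies internally is not published; this implementation
follows the printed beta relation with the direction fixed by the
correction's purpose (it must raise, not lower, the estimate), verified in a
simulation where low-frequency causal variants are only tagged through LD:
the calibrated estimate lands closer to truth than the raw subset estimate in
20/20 replicates.

## Association scan

Per-SNP logistic regression with additive 0/1/2 coding alongside the fixed
covariates (age, sex, leading PCs; optionally ordinal skin color 1-10,
dropping — only from that model — samples missing it). Newton iterations run
batched across SNPs with per-SNP missingness masks, so one scan is a handful
of vectorised passes; a permutation-based enrichment analysis (1,000
label-shuffled scans) is then tractable on one CPU. P-values are two-sided
Wald tests; separated (|log-odds| >= 15) or non-converged SNPs are flagged
with a score-test fallback p rather than a fabricated Wald value;
monomorphic SNPs are flagged untested. The scan reports
`lambda = median(chi2)/0.4549`; 5e-8 and 1e-5 are reporting annotations only.

## Permutation procedures

Both permutation tests shuffle the case/control labels only: genotypes stay
fixed (preserving LD among SNPs) and covariates stay attached to their
samples (preserving covariate structure under the null of no
genotype-phenotype association). Empirical p-values count ties as
exceedances by default; the strict more-than rule is available but is
anti-conservative in degenerate cases (when the annotation saturates the
top-k list, every permutation ties the observed count and the strict rule
returns 0 where inclusive returns 1). Failed permutation fits are dropped
and the effective number of permutations reported.

## Synthetic cohorts

The generator produces exactly the structure the analysis assumes, with
ground truth recorded for recovery tests:

* **Genotypes** — biallelic dosages under HWE; MAF uniform on a range
  (default 0.01-0.5) or explicit per SNP. Optional LD by a Gaussian copula:
  within blocks of consecutive SNPs the two haplotype draws share an
  exchangeable latent correlation (`ld_r`, default 0.5), then threshold to
  alleles. Chromosome sizes taper (linspace weights) so physical lengths
  differ and length regressions are non-degenerate.
* **Phenotype** — liability model above. Causal SNPs are drawn per partition
  (`causal_fraction` of the eligible pool); effects are i.i.d. normal on
  standardized genotypes then rescaled so each partition's realized genetic
  variance equals its target h2 exactly, removing Monte-Carlo drift from
  acceptance comparisons.
* **Ascertainment** — a super-population sized
  `ceil(n * max(P/K, (1-P)/(1-K)) * 1.35)` is simulated (roughly 45x the
  cohort at the study regime K = 2%, P = 66%), then exactly `round(n * P)`
  cases and the matching controls are drawn uniformly within class. Sizing
  is deterministic so runtimes are predictable.
* **Skin color** — `round(5.5 + sum_l effect_l (dose_l - 1) + noise)` clipped
  to [1, 10]. The analysis treats skin color as an ordinal covariate, so any
  monotone construction suffices; the link between skin color and disease
  liability is deliberately a free parameter (shared loci can be designated,
  or not) because the real-world coupling is unknown.
* **Annotations** — genic flags and synthetic cis-eQTL p-values drawn so
  that the sub-threshold sets are nested by construction and hit
  `round(fraction * m)` exactly (defaults 49% genic; 23%/10%/6% at
  thresholds 0.01/0.001/0.0001).

What the generator does **not** emulate: realistic human LD maps,
recombination, demography, imputation error, genotyping batch artifacts, or
any pigmentation biology. Passing tests therefore demonstrate that the
estimators are correct and calibrated under their own model assumptions —
not that real-cohort estimates are unbiased in the presence of structure the
model omits.

## QC conventions

Two preset regimes: standard (MAF < 0.02, missingness > 2%, HWE p <= 1e-4,
call rate <= 95%) and stringent (MAF < 0.01, missingness > 5%, HWE p < 0.05,
differential case/control missingness p < 0.05, call rate <= 99%,
relatedness > 0.05), the latter used before heritability estimation because
case-control allele-frequency artifacts inflate h2. Filters compose in a
fixed, logged order (autosomes, missingness, MAF, HWE, differential
missingness), comparisons are strict as printed, and re-running on filtered
output is a no-op. HWE uses the exact conditional test when any expected
class count is below 5 (else 1-df chi-square on genotype counts), pooled
across cases and controls by default with a controls-only option.
Relatedness pruning is greedy — drop the lower-call-rate member of the worst
pair, ties to the later sample — so one removal can resolve a chain.

## Problem sizes

Simulation-backed checks run at sizes a single CPU handles comfortably:
parameter recovery at n = 2,000 / m = 2,000 over 20 replicates; ascertained
case-control recovery at n = 1,500; permutation-null calibration at
n = 120 / m = 300 with B = 99 over 100 replicates; the structured-null
genomic-inflation check at n = 2,000 / m = 20,000. `scripts/acceptance.py`
uses n around 1,200 with 3-4 replicates per quantity.

## Known limitations

* The AI-REML SEs are asymptotic; at n of a few hundred the 2-SE coverage
  used in recovery tests is approximate.
* The liability correction is the closed-form probit approximation; under
  extreme ascertainment with large h2 it is known to retain a modest
  downward bias, visible as mean estimates a few points under truth in the
  case-control recovery suite.
* The eQTL enrichment permutations re-use the observed covariate design and
  SNP set (no re-QC inside permutations), matching the intended null.
* PLINK I/O covers the SNP-major binary dialect only; VCF/BGEN and dosage
  probabilities are out of scope.
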