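# Methods

## Problem and model

A diallelic SNP genotyped on *n* individuals yields counts
(n_AA, n_AB, n_BB) plus no-calls. Deviation from Hardy-Weinberg
proportions (HWP) is parametrized by the inbreeding coefficient *f*:
with minor allele frequency *p* and *q* = 1 − *p*,

    (P_AA, P_AB, P_BB) = (p² + pqf,  2pq(1 − f),  q² + pqf).

*f* is admissible on [max(−p/q, −q/p), 1]; *f* = 0 is exact HWP. The
name "inbreeding coefficient" is historical — in QC practice a nonzero
*f* usually reflects genotyping error or chance, not inbreeding.

The ML estimator from observed counts is f̂ = 1 − (n_AB/n)/(2p̂q̂) with
p̂ from allele counts. Its large-sample (Weir) variance is

    Var(f̂) = (1 − f̂)²(1 − 2f̂)/n_var + f̂(1 − f̂)(2 − f̂)/(2 n_var p̂ q̂),

which reduces to 1/n_var at f̂ = 0. The sample size in the variance,
`n_var`, is selectable: `"observed"` (the genotyped individuals, the
standard complete-case choice, and the default) or `"total"` (the full
panel including no-calls). The total convention is what
multiple-imputation pooling requires — every completed dataset has the
full sample size — and it is also the convention under which the
complete-case worked example's published confidence interval
reproduces to three decimals at both endpoints.

Tests: the classical 1-df chi-square goodness-of-fit test without
continuity correction (the statistic equals n·f̂² algebraically, and
this identity is property-tested); the two-sided exact test sums
Levene–Haldane conditional probabilities of all heterozygote counts no
more probable than the observed one (the standard two-sided
convention; mid-p is out of scope). Monomorphic markers raise a typed
error (`MonomorphicError`) rather than propagating NaN.

## MCAR diagnostics

If no-calls are MCAR, the missing group is a random subsample, so its
intensity distribution and the genotype distribution of linked markers
match the called group. Implemented comparisons:

* two-sample Student *t* per intensity channel, pooled-variance and
  Welch (Satterthwaite df) variants;
* Hotelling *T²* on the bivariate (A, B) means — pooled covariance
  with the exact F(2, n₁+n₂−3) reference, and Yao's approximate-df F
  for the heteroscedastic case (the heteroscedastic method is a
  package choice; several approximations exist and differ little at
  these group sizes);
* a 2×k contingency test of covariate-marker genotypes across
  missingness status: chi-square when every expected cell exceeds 5,
  otherwise Fisher's exact test (2×2) or a margin-conditioned
  Monte-Carlo p (2×3). The strict >5 rule is deliberate so that
  boundary tables (expected exactly 5) take the exact path.

Diagnostics refuse to run when the missing group has fewer than 15
members (configurable), below which the tests are unstable.
Calibration (type-I error within the binomial 3σ band at α = 0.05 over
1000 MCAR replicates) is asserted in the acceptance suite. Rejection
discredits MCAR but cannot distinguish MAR from MNAR — no observable
test can.

## Imputation

**Model.** Missing calls are imputed from a multinomial logit for the
genotype categories, reference = most frequent genotype; with two
observed categories it reduces to binary logistic regression (verified
against an independent fit). Predictors: the marker's two intensity
channels (linear, untransformed; a log option exists but is off — no
transform is the default because intensity clouds are roughly isotropic
on the raw scale here) and/or covariate SNPs entered as drop-first
dummies. Covariates are selected by dosage-correlation r² ≥ 0.5
(composite-LD proxy; phase-free), strongest first, capped at 10; the
target's perfect duplicates (r² = 1) are excluded because a perfectly
related predictor yields a diagonal contingency structure that adds no
usable information. If nothing passes and intensities exist, the model
falls back to intensities only.

**Separation.** Intensities or a tight covariate often predict the
genotype without error; unpenalized logit coefficients then diverge.
A small always-on ridge (default 1e-4, slopes only — so the
intercept-only model reproduces observed frequencies exactly) keeps
the optimum finite. The fit maximizes the penalized multinomial
log-likelihood with an analytic gradient (L-BFGS) and reports the
inverse penalized observed information as coefficient covariance. The
fit is self-authored because proper imputation needs that covariance,
which off-the-shelf penalized classifiers do not expose.

**Proper imputation.** Parameter uncertainty must enter each
imputation or the between-imputation variance B is understated. Two
mechanisms are provided. The default, `param_draw="bootstrap"`, refits
the model on a resample of the observed rows before drawing each
missing genotype from the fitted category probabilities. The
alternative, `"normal"`, draws coefficients from N(θ̂, Σ̂). Bootstrap
is the default because under separation the normal approximation's
covariance is penalty-dominated (sd ≈ 1/√ridge per separating
direction), producing absurdly diffuse draws and a fraction of missing
information near 1 even when the predictors classify perfectly;
bootstrap refits remain separated and give λ in the plausible range.

**Chained equations.** Missingness is non-monotone (covariate SNPs
have no-calls too), so imputation sweeps the incomplete variables of
the chain ({target} ∪ covariates): initialize all missing entries by
marginal draws, then for a fixed number of sweeps (default 10) visit
variables in order of increasing missingness, refit on the current
completions of the others, and redraw. Visit order and initialization
are conventional choices. Each of the m streams records the target's
per-sweep f̂ for convergence inspection (`convergence_trace`); the
final iterates are exactly the pooled per-imputation estimates, so the
trace's between-stream variance equals Rubin's B.

A model can only assign categories it has seen: markers with no
observed heterozygotes never receive one, which drives the pooled f̂
to 1 — a known, documented limitation of sample-based imputation (a
reference-panel imputer would not share it). Exactly collinear
predictor columns are dropped with a warning; a target with a single
observed category is reported as unimputable and skipped by panel-level
drivers.

`impute_random` draws every missing call from the marker's observed
empirical genotype distribution — the "assume MCAR" baseline.

## Pooling

Per-imputation estimates Q_i with within variances U_i combine as
q̄ = mean(Q_i), W̄ = mean(U_i), B = sample variance of Q_i (m−1
divisor), T = W̄ + (1+1/m)B, r = (1+1/m)B/W̄, ν = (m−1)(1+1/r)²,
λ = (r + 2/(ν+3))/(r+1). The null statistic q̄/√T is referred to
Student t(ν) (the standard small-m reference; it reproduces the
worked example's published p-value from its printed interval and r).
B = 0 degenerates gracefully to complete-data normal inference. An
all-boundary run (every f̂ = ±1, Weir variance 0) is reported as the
all-missing-information limit (W̄ = 0, λ = 1) by `pool_imputed`.

Because f̂ is an intraclass correlation, pooling can optionally be
done on the Fisher-z scale z = atanh f (delta-method within-variance
Var z = Var f/(1−f²)²), back-transforming the estimate and CI by tanh.
Identity scale is the default; for moderate f the two agree to < 0.01.

## Synthetic data

The generator emulates an array-genotyping panel and is the test bed
standing in for real study data.

* **Genotypes**: independent markers are trinomial draws from the
  (p, f) law above (n = 150 individuals and maf uniform on [0.2, 0.5]
  by default, a typical candidate-region panel scale). LD blocks come
  from a haplotype chain: alleles Bernoulli(p) with inter-locus
  correlation r = √r²; genotype = sum of two independent haplotypes,
  so block loci are at HWP (f = 0) and adjacent-dosage r² hits the
  target (checked within ±0.1). All loci of a block share one allele
  frequency — a two-point chain can reach high r² only when the
  frequencies at linked loci are close, and equal frequencies make any
  r² feasible. This is far simpler than coalescent simulation and
  sufficient for covariate-selection and imputation testing; it does
  not produce realistic decay of LD with distance.
* **Intensities**: per genotype, centroid + isotropic Gaussian noise;
  defaults AA → (2, 0.2), AB → (1.1, 1.1), BB → (0.2, 2), sd 0.25 —
  three well-separated clouds (a linear classifier recovers the
  genotype with > 95% accuracy). The geometry is invented but shaped
  like real two-channel cluster plots.
* **Missingness**: affected markers are chosen uniformly
  (`snp_fraction`); MCAR deletes each call with one probability, MNAR
  with genotype-specific probabilities (π_AA, π_AB, π_BB). The
  MAR-intensity regime deletes with probability
  mar_max·exp(−(z/width)²), where the no-call score
  z = (d₂ − d₁) + max(0, total − median total) combines classification
  ambiguity (d₁, d₂ = distances to the two nearest genotype centroids;
  zero on a decision boundary) with signal dimness. Both ingredients
  matter: ambiguity alone concentrates crosses between clouds but —
  because deletion is then symmetric around each centroid — barely
  moves the missing group's mean intensity vector, which would make
  the mechanism undetectable by mean-based diagnostics; the dimness
  term shifts the missing group along the low-variance total-intensity
  direction, as real failed calls are. At width 0.8 and n = 150 the
  pooled Hotelling test rejects MCAR in ~2/3 of replicates. The
  pre-deletion truth is returned for scoring, and double missings
  (target and covariate) arise naturally because regimes apply
  per-marker.

What passing tests on this generator do **not** show: performance on
panels with realistic MAF spectra, LD decay, batch effects, or
cluster-shaped (non-isotropic, overlapping) intensity clouds. The
simulation results are qualitative orderings (imputation beats
discarding under MNAR; λ falls when informative covariates are added),
not transferable error magnitudes.

## Simulation harness

`run_regime` degrades a complete panel, re-estimates each affected
marker's f̂ by discarding and by MI, and scores both against the
complete-data f̂ (not the generative f — the question is the distortion
added by missing-data handling, not sampling noise) by RMSE over
affected markers only, so the fraction of affected markers does not by
itself move the score. Markers rendered monomorphic-observed by
deletion are skipped and counted. `significance_reversal_report`
classifies each marker by the (discard-test, imputed-test) significance
pair and reports the reversal percentage. Desk-scale defaults (≈ 200
markers × 150 individuals, 20 replicates) were chosen as the smallest
sizes at which the qualitative orderings are stable.

## Numerical choices and degenerate inputs

* Exact-test PMF via log-gamma; ties in "no more probable than
  observed" use a 1 + 1e-12 relative tolerance.
* Wald intervals are not truncated to [−1, 1] (published intervals
  print negative lower bounds).
* Yao's T² returns p = 1 outright when the mean difference is exactly
  zero (the df formula divides by T²).
* Monomorphic / all-missing / single-category markers raise typed
  errors at the operation level; panel-level drivers skip and count
  them.
* ν is computed in IEEE arithmetic so r → 0 gives ν = ∞ (normal
  reference) rather than overflow.
* Reproducibility: every stochastic routine takes an explicit seed;
  identical spec + seed gives bitwise-identical imputations, and CLI
  outputs embed their configuration and seed in a commented header.

## Scale of the shipped checks

The test and acceptance suites run the worked example exactly; the
stochastic checks use n = 1000 × 500 replicates (estimator recovery,
MCAR unbiasedness), n = 80 000 (analytic MNAR reweighting), 20
replicates at n = 150 (MNAR chained-MI vs discarding), and 1000 / 200
replicates (diagnostic calibration / MAR detection) — sizes at which
each assertion's Monte-Carlo band is decisive, as stated per test.
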