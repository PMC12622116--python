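# Methods

## The problem

Genome-wide gene-environment interaction (GEI) scans in related samples
usually fit one linear mixed model (LMM) per trait and then score-test
each variant.  The model-based variance of those score tests assumes
the mean model is right; when an environmental main effect is
misspecified — most commonly a nonlinear effect (e.g. BMI²) modeled as
linear — the GEI variance is underestimated and type-I error inflates.
The problem is worse in families when the exposure itself is heritable,
because the omitted term is then correlated within families.  A popular
workaround, fitting the LMM once and re-using its residuals as the
outcome of an ordinary linear model ("two-step"), trades that inflation
for deflation whose size is hard to predict.

This package implements a robust mixed-model score test (RoM): the
usual LMM score for the genetic main effect and GEI terms, combined
with a Huber-White sandwich variance whose empirical score covariance
is accumulated over *family clusters*.  It also implements the
comparison strategies used to characterise the problem (model-based
LMM, individual-cluster sandwiches on the LMM, the two-step approach,
and a plain linear model), a family-based simulation engine that
reproduces the misspecification phenomenon end to end, and the
calibration metrics used to judge them.

## Model and test statistics

Null model (per trait, fitted once):

    y = X alpha + r + eps,     r ~ N(0, sum_l lambda_l Psi_l),
                               eps ~ N(0, lambda_0 I)

with X the covariates (exposures included), Psi_l block-diagonal
relatedness matrices nested in a family/cluster partition, and
Sigma = sum_l lambda_l Psi_l + lambda_0 I.  Writing
P = Sigma⁻¹ − Sigma⁻¹X(XᵀSigma⁻¹X)⁻¹XᵀSigma⁻¹ and R = P y = Sigma⁻¹(y − X α̂)
(the scaled residuals), each variant with genotype g and interaction
design K = g∘E contributes W = (g, K) and

    score       u = Wᵀ R
    bread       B_J = (Wᵀ P W)⁻¹ ;  B_I = (Kᵀ H K)⁻¹ with
                H = P − P g (gᵀPg)⁻¹ gᵀP  (equals the K-block of B_J)
    effects     ζ̂ = B_J u = (β̂, γ̂)
    meat        M_J = Σ_j ( Σ_{i∈c_j} S_i )ᵀ ( Σ_{i∈c_j} S_i ),
                S_i = R_i · W̃_i ,  W̃ = W − X(XᵀSigma⁻¹X)⁻¹XᵀSigma⁻¹W
    covariance  cov(ζ̂) = B_J M_J B_J ;  cov(γ̂) = B_I M_I B_I
                (M_I is the K-block of M_J)
    statistics  T_J = ζ̂ᵀ cov(ζ̂)⁻¹ ζ̂  ~ χ²(1+q)   (joint)
                T_I = γ̂ᵀ cov(γ̂)⁻¹ γ̂  ~ χ²(q)     (GEI)

The subject-level score S_i multiplies the scaled residual by the
*covariate-adjusted* design row W̃_i (the GLS residual of W on X).
Summed over all subjects this reproduces u exactly (XᵀR = 0), and the
cluster sums match the exact decomposition of Var(WᵀPy) over
independent clusters, Σ_j (PW)_jᵀ Cov(y_j) (PW)_j, up to the low-rank
covariate correction.  Two naive alternatives fail measurably: using
the raw design rows (S_i = R_i W_i) misattributes the covariate
projection across clusters and overestimates the score variance by a
factor around two in the simulation design (because K = g·E projects
heavily onto the exposure covariate), while using marginal residuals on
the projected design behaves identically for family clusters but makes
the individual-cluster variants drift away from their two-step
counterpart.  The adjusted-design form also has two exact reductions we
verify in tests: with singleton clusters, identity working covariance
and OLS covariates it *is* the textbook HC0 robust score test, and it
makes the two-step strategy's statistics numerically equivalent to the
individual-cluster LMM sandwich (the two rows that tabulate identically
in the motivating study).

Because the robust statistic can be written T = uᵀ M⁻¹ u whenever the
bread is invertible, it is invariant to any rescaling of the working
covariance — which is why the two-step statistics do not depend on the
step-2 residual variance estimate.

### Comparison strategies

* **RoM** — sandwich with family clusters (the method itself).
* **LMM-MB** — model-based statistics t = ζ̂ᵀB⁻¹ζ̂ (negative control:
  inflates under misspecification).
* **LMM-ICB** — same LMM, singleton clusters (each subject its own
  cluster; misspecified clustering for families).
* **Two-step-ICB** — step 1: covariates-only LMM; step 2: its
  conditional residuals (y − Xα̂ − BLUP(r), which equal
  lambda_0 · R algebraically) become the outcome of an OLS model on the
  same covariates, tested with the singleton-cluster sandwich.  A flag
  switches to marginal residuals y − Xα̂, which makes the strategy
  collapse onto LM-ICB.
* **LM-ICB** — no random effects at all, singleton clusters.
* **marginal** — genetic main effect score test (gᵀR)²/(gᵀPg), χ²(1).

## REML fitting

Variance components are estimated by average-information (AI) REML:
score_l = −½(tr(PΨ_l) − (Py)ᵀΨ_l(Py)), AI_kl = ½ (Ψ_k Py)ᵀ P (Ψ_l Py),
Newton steps with step-halving accepted only if the restricted
likelihood does not decrease; if no step improves it, a Nelder-Mead
search on the REML criterion over log-components takes over.
Components are floored at 1e-10·Var(y) so Sigma stays invertible;
convergence is a relative parameter change below `tol` (default 1e-6,
`max_iter` 100).  A fit that still has not converged is returned with
`converged=False`, never silently.  With no relatedness components the
fit short-circuits to OLS with the unbiased variance estimate, which is
exactly the REML answer.

All linear algebra is per family block.  Clusters are bucketed by size
and processed with numpy's stacked (batched) Cholesky/inverse, so a fit
or projection costs O(N) for bounded family sizes; the genome scan
additionally shares the per-block projections between all strategies
that use the same null fit.  Random slopes are expressed as an extra
component D·Ψ·D with D = diag(exposure), and repeated measures as
within-subject blocks of ones — both reuse the same machinery, no
special-case code paths.

## The simulation engine

The generator reproduces a family GWAS design: 12,750 nuclear families
(2 founder parents, 2 offspring) and 2,000 three-generation extended
families — 2 founder grandparents, 3 second-generation offspring each
married to a founder spouse, 3 grandchildren per couple (17 members, 5
founders) — for 85,000 individuals and 35,500 founders in total.  The
extended-family shape is the unique simple three-generation structure
with three offspring per generation that reproduces both printed
totals.  Kinship uses the standard recursion (founder self-kinship
0.5); founder genotypes are Binomial(2, MAF) with MAF ~ U(0.05, 0.5)
per variant (the MAF law is otherwise unspecified; uniform over the
common range is the neutral choice), and descendants inherit one
uniformly chosen haplotype per parent per variant (unlinked variants).

Traits follow

    y_i = 1 + a1·x1_i + a2·x1_i² + a3·x2_i + a4·x2_i² + r_i + eps_i

with x1 ~ N(0, 2Ψ) (heritable exposure; unit variance per subject
because diag(2Ψ) = 1), x2 ~ N(0, 2I), r ~ N(0, 2Ψ), eps ~ N(0, I).
Effect sizes are calibrated in closed form so the four exposure terms
explain 10/5/10/5% of trait variance: for x ~ N(0, s), Cov(x, x²) = 0
and Var(x²) = 2s², so the terms are orthogonal and
Var(y) = (1 + 1)/(1 − 0.3) = 2/0.7, giving a_j = sqrt(p_j·Var(y)/basis_j)
with basis = (1, 2, 2, 8).  Note the deliberate asymmetry: x1 has unit
per-subject variance but x2 has variance 2, so a1 ≠ a3.  The
misspecified null keeps the intercept and the *linear* x1, x2 terms
only.  We verified empirically that dropping the intercept as well is
not a viable reading (inflation by two orders of magnitude), and that
the calibration's variance bookkeeping matters less than a percent to
the headline inflation factors.

What the generator does **not** emulate: linkage disequilibrium,
sex-specific transmission, genotyping error or missingness,
ascertainment, or binary traits.  Passing tests therefore demonstrate
correctness of the estimators under the stated stochastic model, not
robustness to real-data artefacts such as LD-induced dependence between
neighbouring tests.

## Problem sizes used by the tests and the acceptance script

Everything calibration-related runs at one tenth of the full design —
1,275 nuclear + 200 extended families (8,500 individuals, preserving
the family-type proportions) — which we found large enough for the
inflation factors to be scale-stable: re-running the two-step analysis
at 17,000 and 34,000 individuals moves the pooled joint-test
lambda_GC by less than 0.04.  The acceptance script pools 20 replicates
of 10,000 null variants each; the in-suite misspecification study pools
5 replicates of 8,000 variants, and the correctly-specified calibration
check pools 2 replicates of 50,000 variants.  The genome-wide tail
comparison is run at alpha = 1e-3 on the pooled misspecification scans,
which is the smallest threshold at which the expected exceedance counts
(tens per strategy) resolve the strategy ordering cleanly.

## Numerical choices and edge cases

* Variants with minor allele count < 1 or gᵀPg < 1e-8·N are skipped
  with reason "zero genetic variance"; interaction designs collinear
  with the genotype, and non-positive-definite sandwiches, are skipped
  with their own machine-readable reasons.  Skipped variants appear in
  the output with NaN statistics, never with fabricated p-values.
* Missing genotypes are mean-imputed per variant before products are
  taken (the simulation produces none).
* p-values use the chi-square survival function; −log10 p is also
  emitted via the log-survival function to survive underflow at extreme
  significance.
* Positive-definiteness checks use a relative eigenvalue floor of
  1e-10.
* One master seed; exposures, traits, MAFs and genotypes draw from
  deterministically spawned substreams, so replicates are reproducible
  and independent of execution order.
* Genotypes stream in variant blocks (`genotype_blocks`, `scan`); the
  full individuals-by-variants matrix is never required and results are
  invariant to the block size.

## Known limitations

* Only quantitative traits and the Gaussian LMM; no binary-trait
  (GLMM) extension and no rare-variant aggregate tests.
* The sandwich needs many clusters to be trustworthy; with few families
  the robust variance is itself noisy (a known small-sample property of
  cluster-robust estimators), and no small-sample correction (e.g.
  HC2/HC3-style leverage adjustments) is implemented.
* The two-step inflation factors reproduce the documented deflation
  direction and approximate magnitude; at one-tenth scale the pooled
  joint-test lambda_GC for the heritable exposure sits a few hundredths
  above the full-scale published value, a gap that persists across
  scales and seeds in our runs.
* The REML fitter targets block-diagonal relatedness (families,
  repeated measures).  A dense GRM over all samples would make every
  sample one cluster and is out of scope.
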