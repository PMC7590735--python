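# Methods

## Generative model for trio cohorts

`synthetic_data.simulate_trios` draws, for each of `M` SNPs, an allele
frequency `f_j ~ Uniform(maf_range)` (default 0.05–0.5: common variants,
matching the post-QC frequency spectrum the trio design is used on), then
parental genotypes `Binomial(2, f_j)` under random mating and child
genotypes by Mendelian transmission (one allele from each parent, each
transmitted with probability `g/2`). Per-SNP effect pairs follow an
infinitesimal (jointly Gaussian) model:

    Var(delta_j) = v_delta / M        (direct, child genotype)
    Var(eta_j)   = v_eta / (2M)       (nurture, parental-sum genotype)
    Cov(delta_j, eta_j) = c / (2M)

The scalings follow from standardizing the child score to variance one and
the parental-sum score to variance two, and from the per-SNP covariance of
the two standardized scores being exactly one under random mating (a fact
verified by Monte-Carlo in the test suite before the recovery experiments
are trusted). With the phenotype

    y = Z_o delta + Z_par eta + e,    e ~ N(0, v_e),

the variance decomposes exactly as `v_delta + v_eta + c + v_e`, which the
generator requires to equal 1. Validity requires
`|c| <= sqrt(2 v_delta v_eta)` (a correlation bound); parameter sets
violating it are rejected.

The architecture choice is a genuine design decision — the trait data the
design targets carry no information about per-SNP effect-size distributions
— and only second moments matter for the estimators studied here, so the
Gaussian choice is without loss for recovery experiments.

### The mediated nurture pathway

The nurture effect is split as `eta = eta_med + eta_res` with variance
fractions `mediated_fraction` and `1 - mediated_fraction` of `v_eta`, the
two parts uncorrelated with each other. The measured maternal mediator is
`m = Z_par eta_med + noise`, with the noise scaled so the squared
correlation between `m` and its error-free part equals
`mediator_reliability`; five independently noised copies of the same index
are emitted as repeated measurements for the factor-score pathway.

Where the direct-nurture covariance sits relative to the split matters.
Ideally `eta_med` is independent of `delta`, so that adjusting for the
mediator touches only the nurture component; the covariance then lives
entirely on `eta_res`. That is only possible while

    |c| <= sqrt(2 v_delta (1 - mediated_fraction) v_eta),

a Cauchy-Schwarz bound no effect distribution can evade. When the requested
`mediated_fraction` exceeds it — which happens at this package's default
depression conditions (0.19, 0.14, -0.16) with 9/14 of nurture mediated —
`split_covariance` places as much of `c` on the unmediated part as the
joint positive-semidefiniteness of `(delta, eta_med, eta_res)` permits and
spills the smallest admissible remainder onto the mediated part. The spill
is small (c_med ≈ -0.023 of the -0.16 at the default conditions) and has
two consequences, both verified in the tests: the direct component is
exactly untouched by mediator adjustment (the mediator has no child-score
channel), and the adjusted nurture component lands slightly above the naive
`(1 - mediated_fraction) * v_eta` (≈ 0.051 rather than 0.050 at the
defaults) because the regression coefficient on the mediator is shrunk by
its covariance with the direct pathway.

Optional knobs: a uniform genotype missingness rate (default 0 — quality
control upstream of this design removes low-call-rate data), and
assortative mating implemented as rank-based mate matching on a heritable
mate phenotype (default off: the trio model itself assumes random mating,
and the knob exists to study violation, not to be part of the default
conditions).

### Relative pairs

`simulate_pedigree_pairs` draws each class's phenotype pairs from a
bivariate normal with unit variances and correlation `a_r A + c_r C`. The
default classes mirror the observed pair counts of the study sample: 233
identical twins, 11,375 siblings/fraternal twins, 175 maternal
half-siblings, 15,227 cousins.

### What the generator does and does not emulate

It reproduces the statistical structure the estimators assume: Mendelian
segregation, linkage equilibrium, homogeneous ancestry, Gaussian phenotypes,
one child per family. It does not simulate linkage disequilibrium,
population stratification, rare variants, non-additive effects, sibling
indirect effects, or skewed symptom-scale distributions. Passing recovery
tests therefore demonstrate correctness of the estimators under the model's
own assumptions — not robustness to the ways real cohort data violate them.
The LD-pruning, relatedness-cutoff and PC-covariate code paths are exercised
on this null data (pruning on independent SNPs, PCA on a homogeneous
cohort) rather than on simulated structure.

## Relatedness matrices

Allele frequencies are estimated from the parents — the founder generation
is the statistically independent one, and using the same estimates for both
generations keeps the child-parent score covariance identity exact. Each
SNP is standardized individually ("average of ratios"): child dosages map
to `(g - 2f)/sqrt(2f(1-f))`, parental sums to `(g - 4f)/sqrt(2f(1-f))`
(variance two). Missing dosages are mean-imputed (zero after centering) at
standardization time only; files keep the missing codes. Monomorphic SNPs
are dropped with a report. The three matrices are

    K_oo = Z_o Z_o' / M
    K_pp = Z_par Z_par' / (2M)
    K_x  = (Z_o Z_par' + Z_par Z_o') / (2M)

The symmetrized cross matrix enters the covariance once (coefficient `c`,
no extra factor of two — the 2M normalization absorbs it); the recovery
experiments confirm this convention against the generative truth.

LD pruning is a greedy left-to-right scan (later SNP of a violating pair is
dropped; deterministic) and the relatedness cutoff greedily removes the
individual in the most violating pairs, ties to the lower index. Genotype
PCs are the top left-singular directions of the standardized child matrix,
unit-variance scores, sign fixed by the largest-magnitude loading.

## REML

`reml_fit` maximizes the restricted likelihood of
`y ~ N(X beta, sum_k theta_k V_k)` by average-information (AI) updates:
score `-(tr(P V_k) - y'P V_k P y)/2`, AI matrix `y'P V_a P V_b P y / 2`,
one Cholesky factorization (and explicit inverse) of Sigma per iteration —
dense linear algebra is the right regime at desk scale (n of a few
thousand). Ascent is enforced by step-halving (up to 30 halvings); if no
AI step is admissible the update falls back to a backtracking gradient
step — the classical expectation-maximization fallback is undefined for the
sign-free covariance component, so a gradient step takes its role.
Initialization splits the covariate-adjusted phenotypic variance equally
across components (a neutral start for an unconstrained problem).
Convergence: relative log-likelihood change below 1e-6, cap 200 iterations;
a non-converged fit is returned flagged, never silently. Genetic components
are unconstrained in sign; the residual is floored at `1e-6 * Var(y)`.
Standard errors come from the inverse AI matrix at the optimum. A singular
AI matrix (e.g. duplicated relatedness matrices) raises a
non-identifiability error. Variance shares divide by the sum of fitted
components — consistent with the diagonal-one normalization of the K
matrices — and the covariate-adjusted sample variance is reported alongside
so the alternative denominator is always recoverable.

`he_regression` is the independent method-of-moments route used to
cross-check REML: covariate-residualized phenotype products over all pairs
(self-pairs included) regressed on the matching relatedness entries plus an
identity regressor, solved in closed form. The two estimators agree in
expectation under the model; the suite checks the mean difference across
replicates.

Fixed effects always include an intercept. The fitted example in the tests
adds pure-noise covariates and checks estimates move only at the O(1/n)
level that losing one degree of freedom implies.

## Pedigree ACE

`ace_fit` maximizes the pairwise bivariate-normal likelihood over `(A, C)`
with `E = 1 - A - C`, phenotypes standardized in the pooled sample.
Optimization: Nelder-Mead from five deterministic starts, best kept, then a
quasi-Newton polish; standard errors from the numerical Hessian. The
pairwise likelihood treats pairs as independent even though individuals
recur across pairs, so standard errors are mildly optimistic — the point
estimates are the object of interest here. Components are unconstrained by
default, with a non-negativity option (boundary solutions flagged). A
single relationship class is rejected as non-identifiable.

## Factor scores and mediation

`factor_score` fits a one-factor model to standardized repeated
measurements by maximum likelihood on the available-case correlation matrix
(L-BFGS-B over loadings and log-uniquenesses, uniquenesses floored at 1e-4
with Heywood flagging), and scores individuals by the regression method
using each row's observed subset; scores are standardized and the sign set
so the mean loading is positive. Columns with no detectable common factor
(leading correlation eigenvalue within sampling distance of one) trigger a
degenerate-factor warning and a row-mean fallback score.

`mediate` is deliberately not a causal-mediation estimator: it mirrors the
covariate-attenuation contrast — fit the trio model without and with the
mediator among the fixed effects and report the drop in the nurture
component, on both the share and raw scales (the attenuation fraction is
undefined and reported as NaN when the unadjusted nurture estimate is not
positive, which happens in single small-sample replicates).

## Problem sizes and numerical choices

The recovery experiments use 20 replicates of 2,000 trios by 2,000 SNPs
(and the observed 27,010 relative pairs), sizes at which the per-component
sampling error (~0.06-0.08 per replicate; Monte-Carlo SE of the mean
~0.015) cleanly separates signal from failure while a full experiment runs
in minutes on one core. Estimates at these sizes are unbiased within
Monte-Carlo resolution; recovery is judged at two Monte-Carlo standard
errors of the replicate mean. Determinism: every stochastic step flows from
a single integer seed through `numpy.random.default_rng`; identical
parameters and seed give bit-identical cohorts.

## Known limitations

* The trio REML is dense O(n^3) per iteration: appropriate up to ~10^4
  individuals, not biobank scale.
* Genetic nurture here aggregates both parents; separating maternal and
  paternal pathways needs a different parameterization.
* The pairwise pedigree likelihood double-counts individuals (see above).
* Binary traits are fitted on the observed scale; no liability
  transformation is provided.
* The PLINK reader loads the whole fileset into memory.
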