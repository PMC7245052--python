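# Methods

## Model

For `n` mother–offspring dyads, let `y1` be the standardized offspring
phenotype, `y2` the standardized maternal phenotype and `A` the genetic
relatedness matrix computed from the *offspring's* hard-call genotypes,

```
A_jk = (1/m_jk) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i)),
```

summing over the `m_jk` SNPs non-missing in both members of the pair,
with `p_i` the sample allele-1 frequency. The bivariate model stacks the
traits, `y = Xβ + g + e`, with

```
g ~ N(0, Σ_g ⊗ A),   e ~ N(0, Σ_e ⊗ I),
Σ_g = [[σ²_g1, σ_g12], [σ_g12, σ²_g2]],   Σ_e likewise.
```

The restricted log-likelihood is

```
ℓ(θ) = −½ [ log|V| + log|X'V⁻¹X| + y'Py ] − ½ (N − p) log 2π,
V = Σ_g ⊗ A + Σ_e ⊗ I,   P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹,
```

with `N = 2n` and `p = rank(X)`. The full `log 2π` constant is included
so values are directly comparable with a dense-matrix evaluation of the
same criterion (used as an independent cross-check in the tests). The
fit is unconstrained: components may go negative and derived ratios may
leave `[0, 1]` / `[−1, 1]`; they are reported as-is with a defined/flag
convention rather than clamped or truncated.

The covariance partition takes `Cov_P` as the *sample* covariance of the
standardized pair (equal to the Pearson correlation), `Cov_G = σ̂_g12`,
and `Cov_E = Cov_P − Cov_G`, so additivity is exact by construction. The
model-implied total `σ̂_g12 + σ̂_e12` is stored as a consistency
diagnostic (`model_cov_p`), not used in the ratio.

Both `Cov_G` and the standardization that makes `Cov_P` a correlation
assume the analysis sample: allele frequencies for GRM centring/scaling
come from the analysis sample itself, and phenotype standardization is
over the pooled dataset, not per cohort.

## Estimation

AI-REML with the iteration schedule: one EM-REML step from the start
`Σ_g = Σ_e = S/2` (`S` = sample covariance matrix of the traits),
then average-information updates

```
score_i = −½ [tr(P V̇_i) − y'P V̇_i P y],     AI_ij = ½ y'P V̇_i P V̇_j P y,
```

with up to 10 step-halvings whenever a proposed step leaves the feasible
region or decreases the likelihood, and a full EM-REML update
(`Σ_new = Σ + (1/n) Σ [Q − T] Σ`, the matrix form of the classical EM
update) for any iteration in which the AI step fails or the AI matrix is
singular. Convergence requires `|Δ logL| < 1e-4` and
`max |Δθ|/(|θ|+1) < 1e-4`. The sampling covariance of the estimates is
the inverse AI matrix at the optimum.

All per-iteration algebra runs in the eigenbasis of `A`: with
`A = U D U'`, rotating traits and design columns by `U'` makes `V`
block-diagonal with one 2×2 block `d_i Σ_g + Σ_e` per eigenvalue, so
each iteration costs `O(n)` after a single `O(n³)` eigendecomposition.
The eigenbasis path agrees with the dense formulation to well below
1e-6 (tested).

### Numerical design near the boundary of the parameter space

Two safeguards address a failure mode specific to unconstrained
variance-component REML at small `n`: the optimum can sit *on* the
boundary of the positive-definite cone (some rotated block of `V`
exactly singular). Near that boundary, float64 evaluation of the
likelihood is unreliable — a block that is analytically indefinite can
pass a Cholesky factorization through rounding and return a spuriously
inflated log-likelihood.

1. **Conditioning floor.** Every likelihood evaluation requires each
   block's smallest eigenvalue to exceed `1e-8` times the largest block
   eigenvalue (and to be positive). Points below the floor are treated
   as infeasible (`SingularVError`). This makes the maximization
   well-posed: the supremum over the floored region is attained where
   the likelihood is still computable to ~1e-6, for the AI updates and
   for any direct optimizer run on the same surface alike.
2. **Stationarity check with derivative-free polish.** At exit, the
   Newton decrement `½ s'AI⁺s` (AI projected to the PSD cone) is
   computed; if it predicts a likelihood gain above 1e-3 — which happens
   when AI steps stall against the boundary — the fit is refined by
   chained Nelder-Mead runs on the same eigenbasis likelihood, from the
   current iterate, the default start and seeded dispersed starts,
   restarting from the incumbent until improvement stops. The AI-based
   sampling covariance is recomputed at the final point.

Interior-optimum fits (in practice, everything at `n ≳ 300` in the
simulations here) never trigger the polish and are unaffected by the
floor. Boundary-press fits at `n = 40` are where both safeguards earn
their keep; such fits may carry `converged = False` even when the
likelihood is at its constrained maximum, because the decrement stays
large where the AI matrix degenerates.

Per-dyad-subset refits (jackknife replicates) warm-start from the
full-data optimum; warm and cold starts agree within 1e-4 on fixtures
(tested).

## Pipeline defaults

| Step | Default | Why |
|---|---|---|
| SNP filters | MAF > 0.01, info r² > 0.3 (absent ⇒ directly genotyped, passes), HWE exact P > 1e-6 | the thresholds of the analysis this package operationalizes |
| Hard-call ties | toward the lower genotype index | deterministic; the upstream imputation software's rule is unspecified |
| HWE test | exact conditional test, two-sided by probability mass | matches the exact-test convention; chi-square agrees within 0.02 at balanced counts ≥ 100/cell |
| Relatedness pruning | greedy-by-degree at threshold 0.05, seeded tie-breaks | removes the fewest individuals on hub-like structures; reproducible |
| Ancestry PCs | top 20 eigenvectors of the post-pruning GRM | stratification adjustment; computed after exclusions, mirroring the pipeline order exclusions → GRM → prune → PCs → fit |
| Fixed effects, offspring trait | intercept, cohort, sex, age at measurement (gestational age for birth weight) + PCs | |
| Fixed effects, maternal trait | intercept, cohort + PCs | sex/age are offspring covariates; no maternal-specific covariates are assumed (configurable) |
| Plausibility bounds | maternal BMI [13, 60], offspring BMI [8, 60] kg/m², birth weight [200, 6500] g | the cleaning rule needs concrete cut-offs; these bracket physiologic ranges, configurable |
| Inverse-normal transform | Blom offset 3/8, average ranks for ties | standard choice |
| Standardization | pooled sample, n−1 denominator | makes Cov_P the pooled Pearson correlation |
| Jackknife | loo, or block(b) with seeded random blocks; CI = point ± 1.96·SE | block(20) is the desk-scale default (b refits instead of n) |
| Half-genome split | alternating by SNP index within chromosome | balanced halves; `by_position` and `random` exposed for sensitivity |
| PC-sensitivity grid | {0, 10, 20, 50} | desk-scale cap of the wider scan |

## Synthetic dyads: what they emulate, and what they do not

**Model mode** draws offspring genotypes at independent SNPs
(`p_i ~ U(maf_low, maf_high)`, counts `Binomial(2, p_i)`), per-SNP
effect pairs `(a_i, b_i)` bivariate normal with covariance `Σ_g/m` on
the column-standardized scale, and residual pairs from `Σ_e` — data
generated exactly under the estimator's own model, with every component
known. The "maternal" trait here simply loads on the same offspring
genotypes; this is the correct-specification testbed, not a claim about
mothers.

**Mechanistic mode** draws maternal and paternal genotypes at
Hardy-Weinberg proportions and transmits one allele per parent
(`Bernoulli(g/2)` per SNP), giving a true parent–offspring genotypic
correlation of ½ at each SNP. The maternal phenotype has heritability
`h2` (`n_causal` causal SNPs, equal per-SNP variance `h2/n_causal` on
the theoretically standardized scale); the offspring phenotype adds the
same causal effects on the offspring's genotypes plus the environmental
transmission path `c_env · y2`, with the offspring residual variance
completed analytically to `1 − h2 − c_env² − c_env·h2` so that the
offspring trait has unit variance *and* `h2`, `c_env` keep their meaning
as variance proportions (an after-the-fact rescaling would distort
both; the construction rejects parameter combinations whose implied
residual variance is negative). Closed forms used by the tests:
`Cov_P = h2/2 + c_env`; the SNP-tagged covariance is exactly 0 when
`h2 = 0`, asymptotically `h2/2` when `c_env = 0` (validated against a
brute-force transmission simulation at n = 50 000), and approximately
`(h2/2)(1 + c_env/2)` in the mixed case (projection argument; treated
as approximate).

Both modes attach two synthetic cohorts (half split), sex, measurement
age ~ N(15, 0.5²) years and gestational age ~ N(40, 1.8²) weeks as
*neutral* covariates — they do not enter the phenotype models, which
keeps the closed-form expectations exact while still exercising the
fixed-effect and meta-analysis machinery.

Not emulated: linkage disequilibrium, MAF/LD-dependent architectures,
assortative mating, X chromosome, imputation uncertainty, missing
genotypes beyond what QC injects, genuine cohort heterogeneity. Passing
tests therefore demonstrate correctness of the estimator and pipeline
under the stated generating processes, not robustness of GREML to the
violations listed above.

## Uncertainty, meta-analysis, diagnostics

The jackknife deletes one dyad (loo) or one of `b` seeded-random blocks
(delete-d) at a time, reruns the full statistic (GRM rows/columns
dropped, model refit), and uses the delete-d variance
`(n−d)/(d·g) Σ (θ̂_(j) − θ̄)²`, which reduces to `(n−1)/n Σ(·)²` for
loo; for the sample mean this reproduces `s/√n` exactly (tested to
1e-12). Replicates that fail to converge are excluded and counted; more
than 5% failures flags the estimate.

A coverage simulation (model mode → GRM → fit → jackknife CI for the
ratio, repeated) measures empirical CI coverage against the true ratio
`σ_g12/(σ_g12 + σ_e12)`. **Measured behaviour at desk scale (n = 300,
200 replicates, block(20), components 0.3/0.15/0.7):** coverage ≈ 0.99,
i.e. conservative rather than nominal. The dyad-deletion jackknife SE
is inflated by ~1.3–1.6× relative to the Monte-Carlo SD of the
statistic (measured across SNP-panel sizes 300–2400 and at n = 300 and
600; loo inflates as much as block), while the AI/curvature SE is well
calibrated (0.052 vs MC SD 0.049 at n = 600). The diagnosis: with
unrelated dyads, the GREML covariance estimate is driven by *pair*
terms `A_jk y1_j y2_k` — a near-degenerate degree-2 U-statistic (the
familiar `SE ∝ 1/n` scaling of SNP-heritability estimates in unrelated
samples) — and observation-level jackknives are upward-biased for such
statistics; the inflation does not vanish with n. The practical
reading: these CIs never under-cover in correctly specified
simulations, but they are conservative, and the package reports the
AI-based SEs alongside for comparison.

The DerSimonian–Laird estimator uses fixed weights `w_i = 1/se_i²`,
`Q = Σ w_i (θ_i − θ̄_w)²`, `τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw))`,
re-weights `1/(se_i² + τ²)`. One-stage pooled analysis merges dyads,
standardizes on the merged data, prunes and computes PCs on the pooled
GRM, and adds cohort fixed effects; the two-stage route (per-cohort fits
→ DL) is run alongside as the heterogeneity sensitivity check.

The half-genome inflation diagnostic fits the univariate model with
each of two disjoint SNP halves and with the full set;
`delta = (h²_half1 + h²_half2) − h²_full` is ≈ 0 without confounding
and positive when stratification or cryptic relatedness contributes
signal to both halves. `delta_se` combines the three delta-method SEs
in quadrature — an approximation, since the three estimates share the
phenotype; the result is reported as a band, not a verdict.
The model-vs-sample covariance diagnostic `|model_cov_p − cov_p|`
converges only when the marker panel's resolution keeps pace with the
sample (measured: medians 0.0057 → 0.0007 over n = 100 → 1600 with
m = 2n, but no trend when m is fixed and n grows past it).

## Problem sizes used by the acceptance script and test suite

Wald-CI example: closed form (n = 2894, as printed). Oracle
equivalence: 5 fixtures, n = 40, m = 300, Nelder-Mead from 5 random
starts. Recovery: 30 replicates, n = 1000, m = 2000. Coverage: 200
replicates, n = 300, m = 600, block(20). Mechanistic checks: n = 1500,
m = 1200, 300 causal SNPs. Half-genome: n = 800, m = 2000 (null);
2×400 with genome-wide frequency shifts (stratified). Invariants:
n = 500, m = 2000. These sizes keep a full run to a few minutes on one
CPU; the mean recovery estimate at these sizes sits ~1 MC SE below the
generating σ_g12 (a small attenuation consistent with the
sample-scaling mismatch between the simulation's column-standardized
effects and the GRM's allele-frequency scaling; it is well inside the
recovery tolerance and vanishes in the ratio's denominator).

## Known limitations

* Single GRM only: no MAF- or LD-stratified components, no multi-GRM
  models, no dosage GRMs, no BLUP prediction.
* The jackknife CIs are conservative at desk scale (see above); the
  behaviour at full cohort scale (n ≈ 10⁴, m ≈ 10⁶) is not directly
  measurable here.
* The maternal-genotype model that would separate genetic confounding
  from indirect maternal genetic effects is out of scope; as in the
  analysis this package follows, `Cov_G` conflates the two paths.
* `delta_se` in the half-genome test ignores the dependence between the
  three fits.
* Phenotype cleaning bounds and the maternal-trait covariate set are
  configurable conventions, not estimated quantities.
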