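# Methods

## Data model and admissibility

An `MPMRecord` stores one population's projection matrix `A` (columns =
stage at time t, rows = stage at t+1, 0-based everywhere) with optional
`U`/`F`/`C` parts and study metadata. When `A` is given it is
authoritative; `U+F+C` consistency is checked to 1e-8 but never overwrites
`A`. When `A` is absent it is reconstructed from the parts. Age- and
stage-classified models are pooled into one `"stage"` category for the
models' state-variable random factor; size-and-stage combinations are
recorded as `"stage"` upstream and size-only models stay `"size"`.

Admissibility uses the life-cycle digraph with an edge `j -> i` whenever
`A[i,j] > tol` (`tol = 1e-12` by default; floating-point zeros from matrix
arithmetic motivate a nonzero tolerance, and the value is configurable
because no canonical choice exists): irreducibility is strong
connectivity, primitivity adds aperiodicity (gcd of cycle lengths 1), and
ergodicity requires the left dominant eigenvector to be strictly positive
after normalization. A zero matrix fails all three with an explicit
reason.

Filtering retains wild, unmanipulated, annual-interval records that pass
all three screens. Replicate matrices of one population may be encoded
with a `"|"` suffix in `population_id` (`"popA|1999"`, `"popA|mean"`);
within a group, individual records are preferred — several individuals are
collapsed to their arithmetic elementwise mean — and a stored mean matrix
is used only when no individual record survives. Arithmetic (not
geometric) averaging matches the convention of the compiled demographic
databases this exchange format mirrors.

## Transient metrics

All three resilience components are computed on `Â = A/λ₁`. Compensation
is the induced 1-norm (max column sum), resistance is `1 − minCS(Â)`, and
both are exactly the extreme one-step totals over stage-biased unit
disturbance vectors — the oracle used in the tests. Resilience is computed
on the full `A` including clonality, since the transient measures are
defined on the whole projection matrix; reproduction-specific quantities
use `F` only.

Recovery time defaults to `t_x = log(x)/log(λ₁/‖λ₂‖)`, the time at which
the dominant eigenvalue's contribution exceeds the subdominant's by the
factor `x` (default 10). The reciprocal-in-log variant
`log(λ₁/‖λ₂‖)/log(x)` appears in parts of the transient-dynamics
literature; it is available behind `form="as-printed"` for auditability.
Both are monotone transforms of the damping ratio, so rankings across
populations are identical. `t_x` is undefined (flagged, NaN in tables) for
1×1 matrices and for imprimitive matrices (damping ratio 1, structure
never converges). When several eigenvalues tie at the subdominant modulus
(including complex pairs), `‖λ₂‖` is that shared modulus — only the
modulus enters the formula.

Zero resistance (a column-stochastic `Â`) is legal but flagged, because
its logarithm is undefined downstream; flagged rows are excluded from
log-scale modelling with a logged count rather than patched with a
pseudo-count.

## Life-history traits

`R₀` is the dominant eigenvalue of `F N` with the fundamental matrix
`N = (I − U)⁻¹`; this is the only closed form defensible from a U/F
decomposition, and it is validated against an individual-based
lifetime-offspring simulation in the tests. It requires a dissipative `U`
(spectral radius < 1); violations raise an error. Generation time
`T = log R₀ / log λ₁` is flagged undefined when `λ₁ = 1` within 1e-10 or
`R₀ = 0`; flagged records are excluded from trait models with logged
counts (no limit substitution is attempted). `φ` weights the column sums
of `F` by the stable stage structure; clonality never contributes.
Records without a U/F split keep their resilience values but are excluded
from trait-based models.

## Phylogeny

Trees are Newick, rooted, with branch lengths in time units. Polytomies
are resolved into random dichotomies (seeded) whose inserted internal
branches get length `epsilon = 1e-6 ×` tree height — "very close to zero"
made concrete; every pairwise covariance then moves by at most the number
of insertions times epsilon. The VCV entry (i, j) is the shared
root-to-MRCA path length; by default it is standardized to correlation
form (unit diagonal) before entering the models, the common convention for
covariance random effects, with the raw form behind a flag. Species names
are matched between tree and tables after whitespace/underscore
normalization; populations of one species share the species' VCV row,
population-level variation being carried by the species/population random
effect. Kingdoms are processed with separate trees and separate fits
throughout.

## Models and priors

All responses (and trait predictors) are natural-log transformed and
z-scored (sample sd, ddof 1). Shared random-effect structure: phylogeny
`u_phylo ~ MVN(0, σ²_p V)` with the standardized VCV `V`; species iid
`N(0, σ²_s)`; state variable iid `N(0, σ²_k)`.

1. *Variance partitioning (phylogenetic signal).* Intercept-only Gaussian
   model per component. Priors: intercept `N(0, 10)`, all scales
   `Exponential(1)` — the stated variance priors interpreted on the scale
   (standard deviation) parameter, following the convention of the
   regression framework this model family mirrors. The random effects are
   marginalized analytically, leaving a five-parameter posterior
   `(β₀, σ_p, σ_s, σ_k, σ_e)` sampled with an affine-invariant stretch
   ensemble (one independent 32-walker ensemble per chain, batched through
   a single vectorized likelihood). With one population per species the
   marginal covariance is `σ_p²V + (σ_s²+σ_e²)I + σ_k² Z_k Z_kᵀ`, which is
   evaluated in O(n·K) per proposal via the eigenbasis of `V` plus a
   rank-K Woodbury correction; otherwise a dense `slogdet`/solve path is
   used. The phylogenetic signal is the per-draw share
   `σ_p²/(σ_p²+σ_s²+σ_k²+σ_e²)`; a config switch drops the state term from
   the denominator. The full denominator is the default because it is the
   standard phylogenetic-heritability analogue.

2. *Residual correlations.* Trivariate intercept-only model with a
   Student-t likelihood (robust to multivariate outliers), ν ~ Gamma(2,
   rate 0.1), intercepts `N(0, 10)`, scale priors `Exponential(1)`, and an
   LKJ(1) (uniform) prior over the 3×3 residual correlation matrix — the
   correlation prior is not fixed by the design and uniform is the neutral
   choice. Sampling is Metropolis-within-Gibbs using the scale-mixture
   representation of the t distribution. Four reparametrization devices
   keep the chains well mixed (split-Rhat ≤ 1.01 at the run sizes used):
   exact interweaving (translation) draws along the
   intercept/random-effect-mean direction, which the likelihood cannot
   identify; a joint draw of the phylogenetic and species effects (same
   level, weakly separated); partially collapsed slice updates of the
   phylo/species scales with the species-level effects integrated out and
   immediately redrawn; and a collapsed (mixing-weights-integrated) update
   of ν. Residual-scale and correlation conditionals use explicit 3×3
   adjugate algebra.

3. *Trait regression.* The same trivariate machinery with a Gaussian
   likelihood and fixed effects per response: standardized generation
   time, standardized reproductive output, their interaction, and
   standardized matrix dimension as a covariate. Priors: intercept
   `N(0, 1)`, slopes `N(0, 10)`, scales half-`N(0, 1)`. Slopes are fixed
   effects with random intercepts only; giving every slope its own
   phylogenetic/species/state departure was considered and rejected as
   unidentifiable at the sample sizes this package targets. A collinearity
   warning fires when |cor(G, R)| > 0.95.

Defaults are 8000 iterations with 800 warmup and 4 chains — the warmup is
deliberately short in that convention and the config allows longer; for
the ensemble sampler, `iterations` counts kept walker-draws per chain, so
the draws-count contract `chains × (iterations − warmup)` is preserved.
Convergence is assessed with rank-normalized split-Rhat (via arviz) on
every monitored quantity; a fit whose worst Rhat exceeds the threshold
(default 1.01) is reported as non-passing and the pipeline marks its
outputs accordingly instead of summarizing silently.

## Null simulation

Random MPMs remove life-history structure: each survival column's total is
uniform on (0.2, 0.95) and split across destination stages by a symmetric
Dirichlet; a log10-uniform fecundity on (−1, 1.5) is placed on a random
row of each reproductive column (one reproductive stage by default);
matrices are rejection-resampled until admissible. The single-reproductive-
stage default matters: compensation (a maximum column sum) and φ (a
stable-structure-weighted sum) both increase with fecundity magnitude,
which is the mathematical coupling the null exists to demonstrate, but
when fecundity is spread over a varying number of reproductive stages the
max-versus-sum structure of the two quantities anticorrelates them
strongly enough to cancel and even invert the overall correlation
(measured here: +0.17 with one reproductive stage, −0.44 with four). The
number of reproductive stages is a `NullSimConfig` field, so either regime
is available. Survival totals are capped below 1 (a biological
constraint worth keeping even in the null) and survival and fecundity are
drawn independently, which is what "no trade-offs" operationalizes — the
tests verify the absence of survival-fecundity covariance across matrices.
Component-trait Pearson correlations are computed on log-z-scored values
with seeded 1000-resample bootstrap intervals; empirical and null
intervals can be joined side by side, non-overlap of the 95% intervals
marking a correlation as credibly different from the algebraic baseline.
The positive compensation–reproductive-output correlation in these
structure-free matrices is the canonical example of a mathematical rather
than biological association.

## Synthetic data

Synthetic MPMs are Leslie (age-classified) because their traits have
closed forms: maturity age `a`, pre-maturity survival `p`, adult self-loop
`q`, terminal fecundity `f` give `R₀ = f p^(a−1)/(1−q)`, and the
semelparous limit `q = 0` gives `T = a` exactly. The self-loop makes
default collections primitive (cycle lengths `a` and 1), so every emitted
record passes the screens; the semelparous variant is kept for closed-form
checks and is deliberately imprimitive (damping ratio 1, recovery time
undefined). A "dirty" collection variant always contains one record per
exclusion path. Yule trees are pure-birth, scaled to unit height, tips
named to match generated species.

Trait simulation draws exactly the signal model's data-generating process.
Two conditioning switches exist for recovery studies, both off by default:
`exact_variances` rescales each simulated component to its nominal sample
variance, and `exact_correlation` / `exact_effects` whiten-and-recolor
residuals (or project noise orthogonal to the design) so the realized
sample correlation / least-squares coefficients equal the nominal truth.
Rationale: a single correlated draw on one 100-tip tree has realized
component variances dispersed enough that nominal-truth recovery checks
would mostly measure simulation noise; conditioning pins the estimand so
they measure the estimator. The unit tests verify the pinning exactly.

What the generators do not emulate: sampling error in matrix entries,
taxonomic imbalance, missing-data patterns, non-ultrametric trees, or any
dependence between life history and phylogeny beyond the simulated
variance components. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated model, not robustness to
real-data pathologies.

## Problem sizes and numerical choices

Validation runs use 1000 random MPMs (dimensions 2–8) for the metric
oracles, 20 replicate 100-tip signal fits per truth condition, and n = 300
populations (100 species × 3 populations) for the trivariate models —
sizes chosen to match the scale of the study design the package targets
while keeping a full validation run in the tens of minutes on one CPU.
Ensemble fits use 160k kept walker-draws per chain; Gibbs fits 2500 sweeps
per chain with 500 warmup. Degenerate inputs are handled by flags rather
than exceptions wherever a record can remain useful (undefined recovery
time, zero resistance, undefined generation time); errors are reserved for
structurally unusable input. Jitter of 1e-8 to 1e-12 stabilizes inversions
of standardized VCVs whose near-duplicate tips (resolved polytomies) make
them nearly singular.

## Known limitations

- The ensemble sampler reports Rhat across independent ensembles; walkers
  within an ensemble are interacting, so effective-sample-size estimates
  from these draws would be optimistic and are not reported.
- The Gibbs sampler's collapsed scale updates cost O(S³) per sweep and
  would need profiling beyond a few thousand species.
- Imprimitive matrices are excluded by design (their recovery time is
  undefined); analyses of periodic life cycles need seasonal matrix
  products, which are out of scope.
- The null generator is one defensible choice among many; its parameters
  sit in `NullSimConfig` so alternative nulls are one config away.
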