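# demres

Demographic resilience of structured populations: transient metrics from
matrix population models (MPMs), life-history traits, phylogenetically
informed Bayesian multilevel models, and a random-matrix null analysis.

## The problem

A matrix population model projects a stage- (or age- or size-) structured
population one time step forward, `n_{t+1} = A n_t`, with `A = U + F + C`
(survival/development, sexual reproduction, clonality). Its dominant
eigenvalue λ₁ is the asymptotic growth rate; the right eigenvector **w** is
the stable stage structure. A disturbance that knocks the structure away
from **w** triggers short-term *transient* dynamics, which summarize a
population's intrinsic ability to cope with disturbance — its *demographic
resilience*. On the λ₁-normalized matrix `Â = A/λ₁` (so stationary growth
is factored out), three components are computed per population:

- **compensation** `ρ̄₁ = ‖Â‖₁` — the maximum column sum: the fastest
  one-step relative growth any stage-biased disturbance can produce;
- **resistance** `1 − minCS(Â)` — one minus the minimum column sum, so
  values near 1 mean the worst-case one-step decline is small;
- **recovery time** `t_x = log(x) / log(λ₁/‖λ₂‖)` — the time for the
  dominant eigenvalue's contribution to exceed the subdominant's by a
  factor x (default x = 10), a damping-ratio convergence time.

Life-history traits from the same matrices place each species on the
fast–slow continuum: generation time `T = log R₀ / log λ₁` with
`R₀ = λ_max(F (I − U)⁻¹)` the net reproductive rate, and mean reproductive
output `φ = Σ_j colsum(F)_j w_j`.

The statistical layer asks how resilience components covary with each
other and with these traits across many species, while accounting for
shared ancestry. Three Bayesian multilevel model families share random
effects for phylogeny (multivariate normal with the standardized
phylogenetic variance–covariance matrix), species, and the MPM state
variable: (1) intercept-only variance partitioning per component, whose
phylogenetic variance share is the *phylogenetic signal*; (2) a trivariate
Student-t model whose residual correlations measure component trade-offs;
(3) a trivariate Gaussian regression of the components on generation time,
reproductive output, their interaction, and matrix dimension. Because
traits and resilience metrics come from the same matrix, some correlations
are algebraic rather than biological; a random-MPM null simulation
(independent survival and fecundity draws, no trade-offs, no phylogeny)
quantifies that baseline.

## Worked example

```python
import numpy as np
from demres.mpm import MPMRecord, eigen_analysis, normalize
from demres.resilience import compensation, resistance, recovery_time
from demres.life_history import net_reproductive_rate, generation_time

rec = MPMRecord("Example sp.", "pop1", "animal",
                mat_A=np.array([[0.2, 1.6], [0.4, 0.5]]))
eig = eigen_analysis(rec)
a_hat = normalize(rec)
print(f"lambda1      = {eig.lambda1:.6f}")
print(f"compensation = {compensation(a_hat):.6f}")
print(f"resistance   = {resistance(a_hat):.6f}")
print(f"recovery t10 = {recovery_time(eig, 10.0):.6f}")
```

prints

```
lambda1      = 1.163941
compensation = 1.804215
resistance   = 0.484510
recovery t10 = 2.503328
```

The population grows 16.4% per year at equilibrium; after the worst-case
disturbance it can grow at most 80.4% above, or fall at most 48.5% below,
that stationary rate in one step, and the damping ratio puts the return to
a stable structure at about 2.5 years.

An end-to-end synthetic run (generate a collection and a tree, filter,
compute metrics, fit all three models, compare against the null):

```bash
demres simulate --n-species 20 -o synth/
demres resilience synth/collection.json > metrics.csv
demres -v run-all config.yaml      # config points at collection + tree
```

`filter_collection` applies the study-design screens (wild, unmanipulated,
annual projection interval) and the admissibility screens (irreducible,
primitive, ergodic) with a per-record exclusion log.

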