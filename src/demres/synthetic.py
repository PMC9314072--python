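"""Synthetic study systems with known ground truth.

Everything the pipeline consumes — MPM collections spanning a fast-slow
life-history gradient, ultrametric phylogenies, and traits with controlled
phylogenetic signal or residual correlation — can be generated here from a
seed, so every stage is testable without external databases.

Synthetic MPMs are age-classified (Leslie) models because their life-history
traits have closed forms: with maturity age ``a``, pre-maturity survival
``p``, adult survival ``q`` and fecundity ``f``, the net reproductive rate
is ``R0 = f p^(a-1) / (1 - q)`` and, in the semelparous limit ``q = 0`` with
reproduction only at the terminal age, generation time is exactly ``a``.
The adult self-loop (``q > 0``) makes the life cycle aperiodic, so default
collections pass the primitivity screen; the semelparous variant is kept
for closed-form checks.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .mpm import MPMCollection, MPMRecord
from .phylo import vcv_from_tree

__all__ = [
    "LifeHistoryGradientConfig",
    "TraitSimConfig",
    "leslie_record",
    "semelparous_leslie",
    "generate_leslie_collection",
    "generate_dirty_collection",
    "generate_yule_tree",
    "simulate_phylo_traits",
    "simulate_correlated_components",
    "simulate_regression_dataset",
]


@dataclass
class LifeHistoryGradientConfig:
    """A gradient of maturity ages crossed with survival/fecundity draws."""

    n_species: int = 20
    populations_per_species: int = 2
    maturity_age_range: tuple[int, int] = (1, 6)
    survival_range: tuple[float, float] = (0.3, 0.9)
    adult_survival_range: tuple[float, float] = (0.1, 0.8)
    fecundity_range: tuple[float, float] = (0.5, 20.0)
    population_noise_sd: float = 0.03
    kingdom: str = "animal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.populations_per_species < 1:
            raise ValueError("need at least one species and one population")
        if not (0 < self.survival_range[0] <= self.survival_range[1] < 1):
            raise ValueError("survival_range must sit inside (0, 1)")


@dataclass
class TraitSimConfig:
    """Ground-truth variance components for trait simulation."""

    sigma2_phylo: float = 0.8
    sigma2_species: float = 0.0
    sigma2_resid: float = 0.2
    intercept: float = 0.0
    exact_variances: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2_phylo + self.sigma2_species + self.sigma2_resid <= 0:
            raise ValueError("at least one variance must be positive")

    @property
    def true_phylo_share(self) -> float:
        total = self.sigma2_phylo + self.sigma2_species + self.sigma2_resid
        return self.sigma2_phylo / total


def leslie_record(
    a: int,
    p: float,
    f: float,
    q: float = 0.0,
    species_name: str = "synthetic",
    population_id: str = "synthetic_pop0",
    kingdom: str = "animal",
    state_variable: str = "age",
    **meta,
) -> MPMRecord:
    """Age-classified MPM: survival p to the next age, adult loop q, fecundity f.

    Reproduction happens only in the terminal (adult) age class.  With
    ``q = 0`` the life cycle is a single loop of length ``a``
    (semelparous, imprimitive); with ``q > 0`` it is aperiodic.
    """
    if a < 1:
        raise ValueError("maturity age must be >= 1")
    U = np.zeros((a, a))
    for j in range(a - 1):
        U[j + 1, j] = p
    U[a - 1, a - 1] = q
    F = np.zeros((a, a))
    F[0, a - 1] = f
    return MPMRecord(
        species_name=species_name,
        population_id=population_id,
        kingdom=kingdom,
        mat_U=U,
        mat_F=F,
        state_variable=state_variable,
        **meta,
    )


def semelparous_leslie(a: int, p: float = 0.5, f: float = 4.0) -> MPMRecord:
    """Terminal-reproduction Leslie matrix with generation time exactly ``a``."""
    return leslie_record(a, p, f, q=0.0, population_id=f"semelparous_a{a}")


def generate_leslie_collection(
    config: LifeHistoryGradientConfig,
) -> MPMCollection:
    """A collection spanning slow (late-maturing) to fast (early-maturing) species.

    Maturity ages are spread evenly across ``maturity_age_range``; survival
    and fecundity are drawn per species; populations of a species get small
    multiplicative seeded noise.  All records carry metadata that passes the
    study-design filters and matrices that pass the admissibility screens.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC3]))
    lo_a, hi_a = config.maturity_age_range
    ages = np.round(np.linspace(lo_a, hi_a, config.n_species)).astype(int)
    records = []
    for i in range(config.n_species):
        name = f"sp{i:04d}"
        p = rng.uniform(*config.survival_range)
        q = rng.uniform(*config.adult_survival_range)
        f = rng.uniform(*config.fecundity_range)
        for k in range(config.populations_per_species):
            noise = rng.normal(1.0, config.population_noise_sd, size=3).clip(0.5, 1.5)
            records.append(
                leslie_record(
                    int(ages[i]),
                    min(p * noise[0], 0.99),
                    f * noise[2],
                    q=min(q * noise[1], 0.99),
                    species_name=name,
                    population_id=f"{name}_pop{k}",
                    kingdom=config.kingdom,
                    state_variable="age" if ages[i] > 1 else "stage",
                )
            )
    return MPMCollection(records=records, provenance=f"synthetic gradient seed={config.seed}")


def generate_dirty_collection(config: LifeHistoryGradientConfig) -> MPMCollection:
    """The gradient collection plus one record per exclusion path.

    Adds a captive record, a manipulated record, a non-annual record, a
    reducible matrix and a stored mean matrix, so filter tests always
    exercise every rejection reason.
    """
    clean = generate_leslie_collection(config)
    extra = [
        leslie_record(3, 0.5, 4.0, q=0.3, species_name="sp_captive",
                      population_id="dirty_captive", captive=True),
        leslie_record(3, 0.5, 4.0, q=0.3, species_name="sp_manip",
                      population_id="dirty_manipulated", treatment="manipulated"),
        leslie_record(3, 0.5, 4.0, q=0.3, species_name="sp_seasonal",
                      population_id="dirty_seasonal", periodicity_years=0.5),
        MPMRecord(
            species_name="sp_reducible",
            population_id="dirty_reducible",
            kingdom=config.kingdom,
            mat_U=np.array([[0.5, 0.0], [0.3, 0.8]]),
            mat_F=np.zeros((2, 2)),
        ),
        leslie_record(3, 0.5, 4.0, q=0.3, species_name="sp_meanonly",
                      population_id="sp_meanonly|mean", is_mean_matrix=True),
    ]
    return MPMCollection(
        records=list(clean.records) + extra,
        provenance=clean.provenance + " + dirty records",
    )


def generate_yule_tree(n_tips: int, seed: int = 0) -> dendropy.Tree:
    """Pure-birth ultrametric tree, height scaled to 1, tips named sp0000..."""
    if n_tips < 2:
        raise ValueError("a tree needs at least 2 tips")
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=random.Random(seed),
    )
    tree.seed_node.edge.length = None  # drop the stem: depth measured from the root
    height = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= height
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i:04d}"
    tree.is_rooted = True
    return tree


def simulate_phylo_traits(
    tree: dendropy.Tree,
    config: TraitSimConfig,
    populations_per_species: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Traits with known phylogenetic signal on a given tree.

    ``y = intercept + u_phylo + u_species + e`` with
    ``u_phylo ~ MVN(0, sigma2_phylo * V)`` (V standardized), species effects
    and residuals iid normal; populations replicate within species.  Returns
    the trait table (species_name, population_id, state_variable, y) and a
    truth record including the true phylogenetic variance share.

    With ``exact_variances`` each drawn component is rescaled so its sample
    variance equals its target exactly, pinning the realized variance share
    to the nominal one.  A single correlated draw on one tree otherwise has
    a widely dispersed realized variance, so recovery studies that compare
    posteriors against the nominal share use this conditioned variant.
    """
    vcv = vcv_from_tree(tree, standardize=True)
    S = len(vcv.labels)
    n = S * populations_per_species
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD4]))
    L = np.linalg.cholesky(vcv.matrix + 1e-10 * np.eye(S))
    u_phylo = np.sqrt(config.sigma2_phylo) * (L @ rng.standard_normal(S))
    u_species = np.sqrt(config.sigma2_species) * rng.standard_normal(S)
    resid = np.sqrt(config.sigma2_resid) * rng.standard_normal(n)

    def pin(x: np.ndarray, target: float) -> np.ndarray:
        if not config.exact_variances or target == 0 or x.std(ddof=1) == 0:
            return x
        return (x - x.mean()) * np.sqrt(target) / x.std(ddof=1)

    u_phylo = pin(u_phylo, config.sigma2_phylo)
    u_species = pin(u_species, config.sigma2_species)
    resid = pin(resid, config.sigma2_resid)
    rows = []
    states = ("stage", "size")
    pos = 0
    for i, label in enumerate(vcv.labels):
        for k in range(populations_per_species):
            rows.append(
                {
                    "species_name": label,
                    "population_id": f"{label}_pop{k}",
                    "state_variable": states[(i + k) % 2],
                    "y": config.intercept + u_phylo[i] + u_species[i] + resid[pos],
                }
            )
            pos += 1
    truth = {
        "sigma2_phylo": config.sigma2_phylo,
        "sigma2_species": config.sigma2_species,
        "sigma2_resid": config.sigma2_resid,
        "true_phylo_share": config.true_phylo_share,
    }
    return pd.DataFrame(rows), truth


def simulate_correlated_components(
    n: int,
    correlation_matrix: np.ndarray,
    random_effect_shares: dict[str, float] | None = None,
    seed: int = 0,
    tree: dendropy.Tree | None = None,
    populations_per_species: int = 3,
    exact_correlation: bool = False,
) -> tuple[pd.DataFrame, dendropy.Tree, dict]:
    """Trivariate responses with a known residual correlation matrix.

    Residuals are multivariate normal with unit variances and the given 3x3
    correlation; independent phylogenetic/species/state random effects (one
    set per response) are layered on top with the variances given in
    ``random_effect_shares`` (relative to the unit residual variance).
    Returns the data table, the tree used, and the truth record.

    With ``exact_correlation`` the residual draw is empirically whitened and
    re-colored so its sample correlation equals the target exactly
    (conditioned simulation: recovery studies then measure the estimator,
    not the draw-to-draw spread of a finite sample's realized correlation).
    """
    Rm = np.asarray(correlation_matrix, dtype=float)
    if Rm.shape != (3, 3) or np.abs(Rm - Rm.T).max() > 1e-12:
        raise ValueError("correlation_matrix must be symmetric 3x3")
    if np.abs(np.diag(Rm) - 1.0).max() > 1e-12:
        raise ValueError("correlation_matrix must have a unit diagonal")
    eigmin = float(np.linalg.eigvalsh(Rm).min())
    if eigmin < -1e-10:
        raise ValueError(f"correlation_matrix is not PSD (min eigenvalue {eigmin:.3g})")
    shares = {"phylo": 0.3, "species": 0.2, "state": 0.05}
    if random_effect_shares:
        shares.update(random_effect_shares)

    n_species = max(2, int(np.ceil(n / populations_per_species)))
    if tree is None:
        tree = generate_yule_tree(n_species, seed=seed)
    vcv = vcv_from_tree(tree, standardize=True)
    S = len(vcv.labels)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE5]))
    Lv = np.linalg.cholesky(vcv.matrix + 1e-10 * np.eye(S))
    Lr = np.linalg.cholesky(Rm + 1e-12 * np.eye(3))

    sp_of_row = np.array([i % S for i in range(n)])
    states = ("stage", "size")
    st_of_row = [states[i % 2] for i in range(n)]
    up = np.sqrt(shares["phylo"]) * (Lv @ rng.standard_normal((S, 3)))
    us = np.sqrt(shares["species"]) * rng.standard_normal((S, 3))
    uk = np.sqrt(shares["state"]) * rng.standard_normal((2, 3))
    eps = rng.standard_normal((n, 3))
    if exact_correlation:
        eps = eps - eps.mean(axis=0)
        C_emp = np.linalg.cholesky(np.cov(eps, rowvar=False, ddof=1))
        eps = np.linalg.solve(C_emp, eps.T).T  # whiten to exact unit sample cov
    eps = eps @ Lr.T
    Y = up[sp_of_row] + us[sp_of_row] + uk[[i % 2 for i in range(n)]] + eps

    table = pd.DataFrame(
        {
            "species_name": [vcv.labels[s] for s in sp_of_row],
            "population_id": [f"{vcv.labels[s]}_pop{i}" for i, s in enumerate(sp_of_row)],
            "state_variable": st_of_row,
            "compensation": Y[:, 0],
            "resistance": Y[:, 1],
            "recovery_time": Y[:, 2],
        }
    )
    truth = {"correlation_matrix": Rm, "random_effect_shares": shares}
    return table, tree, truth


def simulate_regression_dataset(
    n: int,
    beta_g: float,
    beta_r: float,
    beta_interaction: float = 0.0,
    beta_dim: float = 0.0,
    random_effect_shares: dict[str, float] | None = None,
    predictor_correlation: float = 0.3,
    seed: int = 0,
    exact_effects: bool = False,
) -> tuple[pd.DataFrame, dendropy.Tree, dict]:
    """Trivariate responses with known fixed effects of two standardized traits.

    ``y_m = beta_g*G + beta_r*R + beta_interaction*G*R + beta_dim*D + noise``
    per response, with the same effect sizes in every response and noise made
    of independent phylogenetic/species/state effects plus unit residuals.
    ``G`` and ``R`` are z-scored with correlation ``predictor_correlation``;
    ``D`` is a z-scored integer matrix dimension.

    With ``exact_effects`` the noise is projected orthogonal to the design
    columns, so the realized least-squares coefficients equal the nominal
    effects exactly (conditioned simulation; same rationale as
    ``exact_correlation`` above).
    """
    shares = {"phylo": 0.1, "species": 0.1, "state": 0.02}
    if random_effect_shares:
        shares.update(random_effect_shares)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF6]))

    def z(x):
        return (x - x.mean()) / x.std(ddof=1)

    G = z(rng.standard_normal(n))
    R = z(
        predictor_correlation * G
        + np.sqrt(1 - predictor_correlation**2) * rng.standard_normal(n)
    )
    D = z(rng.integers(2, 9, n).astype(float))
    X = np.column_stack([np.ones(n), G, R, G * R, D])
    beta = np.array([0.0, beta_g, beta_r, beta_interaction, beta_dim])

    table, tree, _ = simulate_correlated_components(
        n, np.eye(3), shares, seed=seed, exact_correlation=exact_effects
    )
    noise = table[["compensation", "resistance", "recovery_time"]].to_numpy()
    if exact_effects:
        proj = X @ np.linalg.lstsq(X, noise, rcond=None)[0]
        noise = noise - proj
    Y = (X @ beta)[:, None] + noise
    for j, comp in enumerate(("compensation", "resistance", "recovery_time")):
        table[comp] = Y[:, j]
    table["generation_time_z"] = G
    table["reproductive_output_z"] = R
    table["matrix_dimension_z"] = D
    truth = {
        "beta_g": beta_g,
        "beta_r": beta_r,
        "beta_interaction": beta_interaction,
        "beta_dim": beta_dim,
        "random_effect_shares": shares,
    }
    return table, tree, truth
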