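"""Bayesian multilevel models linking resilience components, phylogeny and traits.

Three model families are fitted, all sharing the random-effect structure
*phylogeny* (multivariate normal with the standardized phylogenetic VCV as
correlation), *species* (iid) and *matrix state variable* (iid):

1. **Variance partitioning / phylogenetic signal** — an intercept-only
   Gaussian model per response.  The random effects are integrated out
   analytically, leaving a 5-parameter marginal posterior (intercept and
   four scales) sampled with an affine-invariant stretch ensemble.  The
   phylogenetic signal is the posterior share of variance attributed to the
   phylogenetic component.
2. **Residual correlations** — a trivariate intercept-only model with a
   Student-t likelihood (robust to multivariate outliers) whose 3x3
   residual correlation matrix measures association among compensation,
   resistance and recovery time after removing the shared random effects.
   Fitted by Metropolis-within-Gibbs (conjugate updates for location
   parameters and random effects via the Student-t scale-mixture
   representation; slice updates for scales, correlations and the degrees
   of freedom).
3. **Life-history regression** — the same trivariate machinery with a
   Gaussian likelihood and fixed effects: generation time, mean
   reproductive output, their interaction, and matrix dimension as a
   covariate.

Priors follow the study design: intercepts Normal(0, 10) (Normal(0, 1) in
the regression model), slopes Normal(0, 10), scale parameters
Exponential(1) (half-Normal(0, 1) in the regression model), degrees of
freedom Gamma(2, 0.1), and a uniform (LKJ shape 1) prior over residual
correlation matrices.  Convergence is assessed with rank-normalized
split-Rhat on every monitored quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import gammaln

from .phylo import PhyloVCV, normalize_species_name
from .samplers import EnsembleStretch, slice_sample

__all__ = [
    "ModelConfig",
    "PosteriorSamples",
    "VarianceDecomposition",
    "ResidualCorrelations",
    "preprocess_responses",
    "fit_signal_model",
    "phylogenetic_signal",
    "fit_residual_correlation_model",
    "fit_lifehistory_model",
    "check_convergence",
]

RESPONSE_NAMES = ("compensation", "resistance", "recovery_time")


class ModelError(ValueError):
    """Raised for invalid model inputs or failed sampling."""


@dataclass
class ModelConfig:
    """Sampler settings.  ``iterations`` counts warmup + kept draws per chain."""

    iterations: int = 8000
    warmup: int = 800
    chains: int = 4
    seed: int = 0
    rhat_threshold: float = 1.01

    def __post_init__(self) -> None:
        if not 0 < self.warmup < self.iterations:
            raise ModelError("need 0 < warmup < iterations")
        if self.chains < 1:
            raise ModelError("chains must be >= 1")


class PosteriorSamples:
    """Named posterior draws with shape (chains, draws) per quantity."""

    def __init__(self, draws: dict[str, np.ndarray], config: ModelConfig) -> None:
        self.draws = draws
        self.config = config
        shapes = {v.shape for v in draws.values()}
        if len(shapes) != 1:
            raise ModelError("all monitored quantities must share one shape")

    @property
    def names(self) -> list[str]:
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All draws of one quantity pooled across chains."""
        return self.draws[name].reshape(-1)

    def rhat(self) -> pd.Series:
        """Rank-normalized split-Rhat per monitored quantity."""
        if self.n_chains < 2:
            raise ModelError("Rhat requires at least 2 chains")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = az.rhat(az.from_dict(posterior=self.draws))
        return pd.Series({k: float(ds[k].values) for k in self.draws})

    def summary(self) -> pd.DataFrame:
        rh = self.rhat() if self.n_chains >= 2 else None
        rows = []
        for name, arr in self.draws.items():
            flat = arr.reshape(-1)
            rows.append(
                {
                    "quantity": name,
                    "mean": float(flat.mean()),
                    "sd": float(flat.std(ddof=1)),
                    "q2.5": float(np.quantile(flat, 0.025)),
                    "q97.5": float(np.quantile(flat, 0.975)),
                    "rhat": float(rh[name]) if rh is not None else np.nan,
                }
            )
        return pd.DataFrame(rows).set_index("quantity")


@dataclass
class VarianceDecomposition:
    """Per-draw variance shares of the random-effect components (sum to 1)."""

    shares: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        total = sum(self.shares.values())
        if np.abs(total - 1.0).max() > 1e-10:
            raise ModelError("variance shares must sum to 1 in every draw")

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.shares.items():
            flat = arr.reshape(-1)
            rows.append(
                {
                    "component": name,
                    "mean": float(flat.mean()),
                    "sd": float(flat.std(ddof=1)),
                    "q2.5": float(np.quantile(flat, 0.025)),
                    "q97.5": float(np.quantile(flat, 0.975)),
                }
            )
        return pd.DataFrame(rows).set_index("component")


@dataclass
class ResidualCorrelations:
    """Posterior summaries of the 3x3 residual correlation matrix."""

    table: pd.DataFrame  # index "a:b", columns mean, sd, q2.5, q97.5


# ---------------------------------------------------------------------------
# Preprocessing


def preprocess_responses(
    values: np.ndarray | Sequence[float], ids: Sequence[str] | None = None
) -> np.ndarray:
    """Natural log then z-score (sample sd, ddof=1).

    All responses and predictors enter the models on this scale.  Values
    <= 0 are an error (zeros must be flagged and excluded upstream), as is a
    constant vector.
    """
    x = np.asarray(values, dtype=float)
    bad = ~(x > 0) | ~np.isfinite(x)
    if bad.any():
        which = (
            [ids[i] for i in np.flatnonzero(bad)] if ids is not None else np.flatnonzero(bad).tolist()
        )
        raise ModelError(f"non-positive or non-finite values at {which}")
    lx = np.log(x)
    sd = lx.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ModelError("constant vector has zero variance; cannot z-score")
    return (lx - lx.mean()) / sd


def _index_factor(labels: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    levels = list(dict.fromkeys(labels))
    lookup = {l: i for i, l in enumerate(levels)}
    return np.array([lookup[l] for l in labels], dtype=int), levels


def _species_index(species_ids: Sequence[str], vcv: PhyloVCV) -> np.ndarray:
    lookup = {l: i for i, l in enumerate(vcv.labels)}
    idx = []
    missing = []
    for s in species_ids:
        key = normalize_species_name(s)
        if key in lookup:
            idx.append(lookup[key])
        else:
            missing.append(s)
    if missing:
        raise ModelError(f"species absent from the VCV: {sorted(set(missing))}")
    return np.array(idx, dtype=int)


# ---------------------------------------------------------------------------
# Model 1: marginalized variance-partitioning (phylogenetic signal) model


def fit_signal_model(
    response: np.ndarray,
    species_ids: Sequence[str],
    state_labels: Sequence[str],
    vcv: PhyloVCV,
    config: ModelConfig | None = None,
    prior_only: bool = False,
) -> PosteriorSamples:
    """Intercept-only Gaussian model with phylogeny/species/state random effects.

    The model is ``y = b0 + u_phylo + u_species + u_state + e`` with
    ``u_phylo ~ MVN(0, sigma_phylo^2 V)``; the random effects are
    marginalized, so the sampled posterior is over ``(b0, sigma_phylo,
    sigma_species, sigma_state, sigma_resid)`` only.  With ``prior_only``
    the likelihood is dropped (prior-predictive check).
    """
    config = config or ModelConfig()
    y = np.asarray(response, dtype=float)
    n = y.size
    sp = _species_index(species_ids, vcv)
    st, _ = _index_factor(state_labels)
    if len(sp) != n or len(st) != n:
        raise ModelError("response, species_ids and state_labels must align")

    V = vcv.matrix
    if np.linalg.eigvalsh(V).min() < -1e-10:
        raise ModelError("VCV is not positive semidefinite")
    K = int(st.max()) + 1

    def prior(theta: np.ndarray) -> np.ndarray:
        b0 = theta[:, 0]
        s = np.abs(theta[:, 1:5])  # reflection: scales live on |.|
        return -(b0**2) / 200.0 - s.sum(axis=1)  # N(0,10) intercept, Exp(1) scales

    one_pop_per_species = len(np.unique(sp)) == n
    if one_pop_per_species and not prior_only:
        # With one population per species the species component is iid, so the
        # marginal covariance is s2p*V + (s2s + s2e)*I + s2k*Zk Zk'.  Rotate
        # into the eigenbasis of V and absorb the rank-K state term by a
        # Woodbury/determinant-lemma correction: each evaluation is O(n*K)
        # instead of O(n^3), the standard mixed-model trick.
        lam_V, Q = np.linalg.eigh(V[np.ix_(sp, sp)])
        lam_V = lam_V.clip(0.0)
        Zt = Q.T @ np.eye(K)[st]
        Qty = Q.T @ y
        Qt1 = Q.T @ np.ones(n)
        eyeK = np.eye(K)

        def logpost(theta: np.ndarray) -> np.ndarray:
            b0 = theta[:, 0]
            s2 = theta[:, 1:5] ** 2
            s2k = s2[:, 2] + 1e-12
            d = s2[:, 0, None] * lam_V[None, :] + s2[:, 1, None] + s2[:, 3, None] + 1e-9
            r = Qty[None, :] - b0[:, None] * Qt1[None, :]
            a = r / d
            quad = (r * a).sum(axis=1)
            M = eyeK[None] / s2k[:, None, None] + np.einsum(
                "nk,bnl->bkl", Zt, Zt[None, :, :] / d[:, :, None]
            )
            t = np.einsum("nk,bn->bk", Zt, a)
            quad -= (t * np.linalg.solve(M, t[:, :, None])[:, :, 0]).sum(axis=1)
            _, ldM = np.linalg.slogdet(M)
            logdet = np.log(d).sum(axis=1) + ldM + K * np.log(s2k)
            return prior(theta) - 0.5 * (logdet + quad)

    else:
        Kp = V[np.ix_(sp, sp)]
        Ks = (sp[:, None] == sp[None, :]).astype(float)
        Kk = (st[:, None] == st[None, :]).astype(float)
        I = np.eye(n)

        def logpost(theta: np.ndarray) -> np.ndarray:
            lp = prior(theta)
            if prior_only:
                return lp
            s2 = theta[:, 1:5] ** 2
            C = (
                s2[:, 0, None, None] * Kp
                + s2[:, 1, None, None] * Ks
                + s2[:, 2, None, None] * Kk
                + (s2[:, 3, None, None] + 1e-9) * I
            )
            sign, logdet = np.linalg.slogdet(C)
            resid = y[None, :] - theta[:, 0, None]
            alpha = np.linalg.solve(C, resid[:, :, None])[:, :, 0]
            quad = np.einsum("ci,ci->c", resid, alpha)
            ll = -0.5 * (logdet + quad)
            ll[sign <= 0] = -np.inf
            return lp + ll

    # affine-invariant ensembles: one ensemble per chain, stretch moves batched
    walkers = 32
    warm_moves = max(1, -(-config.warmup // walkers))
    moves = warm_moves + -(-(config.iterations - config.warmup) // walkers)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x51]))
    sd_y = max(float(y.std(ddof=1)), 1e-3) if not prior_only else 1.0
    center = 0.0 if prior_only else float(y.mean())
    init = np.empty((config.chains, walkers, 5))
    init[:, :, 0] = rng.normal(center, 0.1 * sd_y, (config.chains, walkers))
    init[:, :, 1:] = np.abs(
        rng.normal(0.5 * sd_y, 0.15 * sd_y, (config.chains, walkers, 4))
    ).clip(1e-3)
    sampler = EnsembleStretch(logpost, init, seed=config.seed)
    raw = sampler.run(moves, warm_moves)  # (chains, kept*walkers, 5)
    raw = raw[:, : config.iterations - config.warmup, :]
    scales = np.abs(raw[:, :, 1:5])
    s2 = scales**2
    draws = {
        "beta0": raw[:, :, 0],
        "sigma_phylo": scales[:, :, 0],
        "sigma_species": scales[:, :, 1],
        "sigma_state": scales[:, :, 2],
        "sigma_resid": scales[:, :, 3],
        "phylo_share": s2[:, :, 0] / s2.sum(axis=2),
    }
    return PosteriorSamples(draws, config)


def phylogenetic_signal(
    posterior: PosteriorSamples, include_state: bool = True
) -> tuple[VarianceDecomposition, pd.DataFrame]:
    """Variance shares of the random-effect components, per posterior draw.

    The phylogenetic signal is the phylogeny share; by default the
    state-variable component is part of the denominator (set
    ``include_state=False`` to drop it).
    """
    s2 = {
        "phylogeny": posterior.draws["sigma_phylo"] ** 2,
        "species": posterior.draws["sigma_species"] ** 2,
        "state_variable": posterior.draws["sigma_state"] ** 2,
        "residual": posterior.draws["sigma_resid"] ** 2,
    }
    if not include_state:
        s2.pop("state_variable")
    total = sum(s2.values())
    decomposition = VarianceDecomposition({k: v / total for k, v in s2.items()})
    return decomposition, decomposition.summary()


# ---------------------------------------------------------------------------
# Models 2 & 3: trivariate Gibbs sampler


def _halfnormal_logp(s: float) -> float:
    return -0.5 * s * s


def _exponential_logp(s: float) -> float:
    return -s


class _TrivariateGibbs:
    """Metropolis-within-Gibbs for the trivariate multilevel models.

    Location parameters (fixed effects and random effects) have Gaussian
    full conditionals — for the Student-t likelihood, conditionally on the
    per-observation mixing weights ``lambda_i`` (t as a scale mixture of
    normals).  Scales, residual correlations and the degrees of freedom are
    updated by univariate slice sampling on their full conditionals.
    """

    def __init__(
        self,
        Y: np.ndarray,
        X: np.ndarray,
        sp_idx: np.ndarray,
        st_idx: np.ndarray,
        V: np.ndarray,
        student_t: bool,
        coef_names: Sequence[str],
        response_names: Sequence[str] = RESPONSE_NAMES,
        intercept_sd: float = 10.0,
        slope_sd: float = 10.0,
        scale_logp=_exponential_logp,
    ) -> None:
        self.Y = Y
        self.X = X
        self.n, self.p = X.shape
        self.S = V.shape[0]
        self.K = int(st_idx.max()) + 1
        self.sp = sp_idx
        self.st = st_idx
        self.student_t = student_t
        self.coef_names = list(coef_names)
        self.response_names = list(response_names)
        self.scale_logp = scale_logp
        jitter = 1e-8 * np.eye(self.S)
        self.Vinv = np.linalg.inv(V + jitter)
        self.Vinv_one = self.Vinv @ np.ones(self.S)
        self.one_Vinv_one = float(self.Vinv_one.sum())
        self.obs_species = np.flatnonzero(np.bincount(sp_idx, minlength=self.S) > 0)
        self.V_obs = V[np.ix_(self.obs_species, self.obs_species)]
        prior_sd = np.full(self.p, slope_sd)
        prior_sd[0] = intercept_sd
        self.coef_prior_prec = 1.0 / prior_sd**2

    # -- residual covariance helpers -------------------------------------
    @staticmethod
    def _corr(r12: float, r13: float, r23: float) -> np.ndarray:
        return np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])

    def _sigma_loglik(self, Sigma: np.ndarray, Sw: np.ndarray) -> float:
        # explicit 3x3 algebra: this sits inside slice-sampling loops where
        # LAPACK call overhead would dominate
        a, b, c = Sigma[0, 0], Sigma[0, 1], Sigma[0, 2]
        d, e, f = Sigma[1, 1], Sigma[1, 2], Sigma[2, 2]
        det = a * (d * f - e * e) - b * (b * f - e * c) + c * (b * e - d * c)
        if det <= 0 or a <= 0 or a * d - b * b <= 0:
            return -np.inf
        adj00 = d * f - e * e
        adj01 = -(b * f - c * e)
        adj02 = b * e - c * d
        adj11 = a * f - c * c
        adj12 = -(a * e - b * c)
        adj22 = a * d - b * b
        tr = (
            adj00 * Sw[0, 0]
            + adj11 * Sw[1, 1]
            + adj22 * Sw[2, 2]
            + 2.0 * (adj01 * Sw[0, 1] + adj02 * Sw[0, 2] + adj12 * Sw[1, 2])
        ) / det
        return -0.5 * (self.n * np.log(det) + tr)

    # -- one chain --------------------------------------------------------
    def run_chain(
        self, iterations: int, warmup: int, rng: np.random.Generator
    ) -> dict[str, np.ndarray]:
        n, p, S, K = self.n, self.p, self.S, self.K
        Y, X = self.Y, self.X
        sp, st = self.sp, self.st

        B, *_ = np.linalg.lstsq(X, Y, rcond=None)
        B = B + 0.05 * rng.standard_normal(B.shape)
        Up = np.zeros((S, 3))
        Us = np.zeros((S, 3))
        Uk = np.zeros((K, 3))
        sig_p = np.full(3, 0.3)
        sig_s = np.full(3, 0.3)
        sig_k = np.full(3, 0.3)
        sig_e = Y.std(axis=0, ddof=1).clip(1e-3)
        rho = np.zeros(3)  # r12, r13, r23
        nu = 30.0
        lam = np.ones(n)

        mu = X @ B + Up[sp] + Us[sp] + Uk[st]
        pairs = [(0, 1), (0, 2), (1, 2)]

        kept = iterations - warmup
        out: dict[str, np.ndarray] = {}
        for j, cn in enumerate(self.coef_names):
            for m, rn in enumerate(self.response_names):
                out[f"{cn}_{rn}"] = np.empty(kept)
        for m, rn in enumerate(self.response_names):
            for tag in ("sigma_phylo", "sigma_species", "sigma_state", "sigma_resid"):
                out[f"{tag}_{rn}"] = np.empty(kept)
        for a, b in pairs:
            out[f"rho_{self.response_names[a]}_{self.response_names[b]}"] = np.empty(kept)
        if self.student_t:
            out["nu"] = np.empty(kept)

        def sigma_now() -> np.ndarray:
            R = self._corr(*rho)
            return R * np.outer(sig_e, sig_e)

        for it in range(iterations):
            Sigma = sigma_now()
            Sinv = np.linalg.inv(Sigma)

            # mixing weights (Student-t as scale mixture of normals)
            eps = Y - mu
            if self.student_t:
                q = np.einsum("ij,jk,ik->i", eps, Sinv, eps)
                lam = rng.gamma(shape=(nu + 3.0) / 2.0, scale=2.0 / (nu + q))

            # location blocks, response by response
            for m in range(3):
                o = [k for k in range(3) if k != m]
                g = np.linalg.solve(Sigma[np.ix_(o, o)], Sigma[o, m])
                s2_cond = float(Sigma[m, m] - Sigma[m, o] @ g)
                c = (Y[:, o] - mu[:, o]) @ g
                w = lam / s2_cond

                # fixed effects
                t = Y[:, m] - (mu[:, m] - X @ B[:, m]) - c
                P = X.T @ (X * w[:, None]) + np.diag(self.coef_prior_prec)
                rhs = X.T @ (w * t)
                L = cho_factor(P, lower=True)
                mean = cho_solve(L, rhs)
                new = mean + np.linalg.solve(
                    np.linalg.cholesky(P).T, rng.standard_normal(p)
                )
                mu[:, m] += X @ (new - B[:, m])
                B[:, m] = new

                # phylogenetic + species effects and their scales: the two
                # components live at the same (species) level and are only
                # weakly separated by the VCV structure, so (a) their scales
                # are updated with the effects integrated out (the marginal
                # over species-level means is an S x S Gaussian), and (b) the
                # effects are then redrawn jointly, avoiding both the
                # scale/effect funnel and the phylo/species ridge
                t = Y[:, m] - (mu[:, m] - Up[sp, m] - Us[sp, m]) - c
                wsum = np.bincount(sp, weights=w, minlength=S)
                rhs_half = np.bincount(sp, weights=w * t, minlength=S)

                obs = self.obs_species
                tbar = rhs_half[obs] / wsum[obs]
                dvar = 1.0 / wsum[obs]

                def collapsed_logp(sp2: float, ss2: float) -> float:
                    M = sp2 * self.V_obs + np.diag(ss2 + dvar)
                    try:
                        Lm = np.linalg.cholesky(M)
                    except np.linalg.LinAlgError:
                        return -np.inf
                    half = solve_triangular(Lm, tbar, lower=True, check_finite=False)
                    return -np.log(np.diag(Lm)).sum() - 0.5 * float(half @ half)

                def logp_sp(ls: float) -> float:
                    s = np.exp(ls)
                    if not np.isfinite(s) or s > 1e3:
                        return -np.inf
                    return self.scale_logp(s) + ls + collapsed_logp(s * s, sig_s[m] ** 2)

                sig_p[m] = np.exp(slice_sample(np.log(sig_p[m]), logp_sp, rng, width=0.7))

                def logp_ss(ls: float) -> float:
                    s = np.exp(ls)
                    if not np.isfinite(s) or s > 1e3:
                        return -np.inf
                    return self.scale_logp(s) + ls + collapsed_logp(sig_p[m] ** 2, s * s)

                sig_s[m] = np.exp(slice_sample(np.log(sig_s[m]), logp_ss, rng, width=0.7))
                Dw = np.diag(wsum)
                P = np.block(
                    [
                        [self.Vinv / sig_p[m] ** 2 + Dw, Dw],
                        [Dw, np.diag(1.0 / sig_s[m] ** 2 + wsum)],
                    ]
                )
                rhs = np.concatenate([rhs_half, rhs_half])
                Lp = np.linalg.cholesky(P)
                mean = cho_solve((Lp, True), rhs, check_finite=False)
                new = mean + solve_triangular(
                    Lp, rng.standard_normal(2 * S), trans=1, lower=True, check_finite=False
                )
                mu[:, m] += (new[:S] + new[S:])[sp] - Up[sp, m] - Us[sp, m]
                Up[:, m] = new[:S]
                Us[:, m] = new[S:]

                # state-variable effects (iid prior)
                t = Y[:, m] - (mu[:, m] - Uk[st, m]) - c
                wsum_k = np.bincount(st, weights=w, minlength=K)
                rhs = np.bincount(st, weights=w * t, minlength=K)
                var = 1.0 / (1.0 / sig_k[m] ** 2 + wsum_k)
                new = var * rhs + np.sqrt(var) * rng.standard_normal(K)
                mu[:, m] += new[st] - Uk[st, m]
                Uk[:, m] = new

                # ASIS rescaling: complement the centered scale updates with
                # non-centered ones (scale and effects move together, the
                # whitened effects held fixed) to break the scale/effect
                # funnel that makes centered-only Gibbs sticky near zero
                for sig_vec, block, obs_of in (
                    (sig_p, Up, sp),
                    (sig_s, Us, sp),
                    (sig_k, Uk, st),
                ):
                    us = block[obs_of, m]
                    t = Y[:, m] - (mu[:, m] - us) - c
                    Bc = float(np.sum(w * t * us))
                    Cc = float(np.sum(w * us * us))
                    sig0 = sig_vec[m]

                    def logp_asis(ls: float, Bc=Bc, Cc=Cc, sig0=sig0) -> float:
                        s = np.exp(ls)
                        if not np.isfinite(s) or s > 1e3:
                            return -np.inf
                        r = s / sig0
                        return self.scale_logp(s) + ls + r * Bc - 0.5 * r * r * Cc

                    new_sig = np.exp(
                        slice_sample(np.log(sig0), logp_asis, rng, width=0.5)
                    )
                    ratio = new_sig / sig0
                    block[:, m] *= ratio
                    mu[:, m] += (ratio - 1.0) * us
                    sig_vec[m] = new_sig

            # interweaving: the likelihood is flat along joint shifts of the
            # intercept against a random-effect block (neither is separately
            # identified), so Gibbs-sample that direction exactly from the
            # priors to decorrelate beta0 from the random-effect means
            isd2 = self.coef_prior_prec[0]
            for m in range(3):
                # phylogenetic block
                a = isd2 + self.one_Vinv_one / sig_p[m] ** 2
                mean = (-B[0, m] * isd2 + (self.Vinv_one @ Up[:, m]) / sig_p[m] ** 2) / a
                delta = mean + rng.standard_normal() / np.sqrt(a)
                B[0, m] += delta
                Up[:, m] -= delta
                # species block
                a = isd2 + S / sig_s[m] ** 2
                mean = (-B[0, m] * isd2 + Us[:, m].sum() / sig_s[m] ** 2) / a
                delta = mean + rng.standard_normal() / np.sqrt(a)
                B[0, m] += delta
                Us[:, m] -= delta
                # state block
                a = isd2 + K / sig_k[m] ** 2
                mean = (-B[0, m] * isd2 + Uk[:, m].sum() / sig_k[m] ** 2) / a
                delta = mean + rng.standard_normal() / np.sqrt(a)
                B[0, m] += delta
                Uk[:, m] -= delta
            mu = X @ B + Up[sp] + Us[sp] + Uk[st]

            # state-variable scale: slice sample on log sigma (the phylo and
            # species scales were updated collapsed, above)
            for m in range(3):
                for sig_vec, u, dim, quad in (
                    (sig_k, Uk[:, m], K, float(Uk[:, m] @ Uk[:, m])),
                ):
                    def logp(ls: float, dim=dim, quad=quad) -> float:
                        s = np.exp(ls)
                        if not np.isfinite(s) or s > 1e3:
                            return -np.inf
                        # +ls: Jacobian of the log transform
                        return (
                            self.scale_logp(s) - dim * ls - quad / (2.0 * s * s) + ls
                        )

                    sig_vec[m] = np.exp(
                        slice_sample(np.log(sig_vec[m]), logp, rng, width=0.5)
                    )

            # residual scales and correlations
            eps = Y - mu
            Sw = (eps * lam[:, None]).T @ eps
            for m in range(3):
                def logp_e(ls: float, m=m) -> float:
                    s = np.exp(ls)
                    if not np.isfinite(s) or s > 1e3:
                        return -np.inf
                    se = sig_e.copy()
                    se[m] = s
                    Sigma = self._corr(*rho) * np.outer(se, se)
                    return self._sigma_loglik(Sigma, Sw) + self.scale_logp(s) + ls

                sig_e[m] = np.exp(slice_sample(np.log(sig_e[m]), logp_e, rng, width=0.3))
            for k in range(3):
                def logp_r(r: float, k=k) -> float:
                    if not -1.0 < r < 1.0:
                        return -np.inf
                    rr = rho.copy()
                    rr[k] = r
                    Sigma = self._corr(*rr) * np.outer(sig_e, sig_e)
                    return self._sigma_loglik(Sigma, Sw)  # LKJ(1): flat

                rho[k] = slice_sample(rho[k], logp_r, rng, width=0.3)

            # degrees of freedom, with the mixing weights collapsed out (the
            # conditional given lambda is too tight for Gibbs to move), then
            # a fresh lambda draw under the new nu
            if self.student_t:
                Sigma = sigma_now()
                Sinv = np.linalg.inv(Sigma)
                eps = Y - mu
                q = np.einsum("ij,jk,ik->i", eps, Sinv, eps)

                def logp_nu(lnu: float) -> float:
                    v = np.exp(lnu)
                    if not 1.0 < v < 500.0:
                        return -np.inf
                    ll = n * (
                        gammaln((v + 3.0) / 2.0) - gammaln(v / 2.0) - 1.5 * np.log(v)
                    )
                    ll -= (v + 3.0) / 2.0 * float(np.log1p(q / v).sum())
                    prior = np.log(v) - 0.1 * v  # Gamma(2, rate 0.1)
                    return ll + prior + lnu

                nu = float(np.exp(slice_sample(np.log(nu), logp_nu, rng, width=1.0)))
                lam = rng.gamma(shape=(nu + 3.0) / 2.0, scale=2.0 / (nu + q))

            if it >= warmup:
                t0 = it - warmup
                for j, cn in enumerate(self.coef_names):
                    for m, rn in enumerate(self.response_names):
                        out[f"{cn}_{rn}"][t0] = B[j, m]
                for m, rn in enumerate(self.response_names):
                    out[f"sigma_phylo_{rn}"][t0] = sig_p[m]
                    out[f"sigma_species_{rn}"][t0] = sig_s[m]
                    out[f"sigma_state_{rn}"][t0] = sig_k[m]
                    out[f"sigma_resid_{rn}"][t0] = sig_e[m]
                for (a, b), r in zip(pairs, (rho[0], rho[1], rho[2])):
                    out[f"rho_{self.response_names[a]}_{self.response_names[b]}"][t0] = r
                if self.student_t:
                    out["nu"][t0] = nu
        return out

    def run(self, config: ModelConfig) -> PosteriorSamples:
        seqs = np.random.SeedSequence([config.seed, 0x6B]).spawn(config.chains)
        per_chain = [
            self.run_chain(config.iterations, config.warmup, np.random.default_rng(s))
            for s in seqs
        ]
        draws = {
            k: np.stack([c[k] for c in per_chain], axis=0) for k in per_chain[0]
        }
        return PosteriorSamples(draws, config)


def _prepare_trivariate(
    responses: np.ndarray,
    species_ids: Sequence[str],
    state_labels: Sequence[str],
    vcv: PhyloVCV,
):
    if isinstance(responses, (list, tuple)):
        Y = np.column_stack([np.asarray(r, dtype=float) for r in responses])
    else:
        Y = np.asarray(responses, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 3:
        raise ModelError("expected three aligned response vectors")
    if not np.all(np.isfinite(Y)):
        raise ModelError("responses contain non-finite values; exclude flagged rows first")
    sp = _species_index(species_ids, vcv)
    st, _ = _index_factor(state_labels)
    if len(sp) != Y.shape[0] or len(st) != Y.shape[0]:
        raise ModelError("responses, species_ids and state_labels must align")
    return Y, sp, st


def fit_residual_correlation_model(
    responses,
    species_ids: Sequence[str],
    state_labels: Sequence[str],
    vcv: PhyloVCV,
    config: ModelConfig | None = None,
) -> tuple[PosteriorSamples, ResidualCorrelations]:
    """Trivariate intercept-only Student-t model; returns residual correlations.

    With no fixed-effect predictors, the residual correlation matrix captures
    the pairwise association among the three resilience components after
    accounting for phylogeny, species and state-variable random effects.
    """
    config = config or ModelConfig()
    Y, sp, st = _prepare_trivariate(responses, species_ids, state_labels, vcv)
    gibbs = _TrivariateGibbs(
        Y,
        np.ones((Y.shape[0], 1)),
        sp,
        st,
        vcv.matrix,
        student_t=True,
        coef_names=["beta0"],
        intercept_sd=10.0,
        scale_logp=_exponential_logp,
    )
    posterior = gibbs.run(config)
    rows = []
    for name in posterior.names:
        if not name.startswith("rho_"):
            continue
        flat = posterior.stacked(name)
        rows.append(
            {
                "pair": name[len("rho_") :],
                "mean": float(flat.mean()),
                "sd": float(flat.std(ddof=1)),
                "q2.5": float(np.quantile(flat, 0.025)),
                "q97.5": float(np.quantile(flat, 0.975)),
            }
        )
    table = pd.DataFrame(rows).set_index("pair")
    return posterior, ResidualCorrelations(table=table)


def fit_lifehistory_model(
    responses,
    generation_time: np.ndarray,
    reproductive_output: np.ndarray,
    matrix_dimension: np.ndarray,
    species_ids: Sequence[str],
    state_labels: Sequence[str],
    vcv: PhyloVCV,
    config: ModelConfig | None = None,
) -> PosteriorSamples:
    """Trivariate Gaussian regression of the resilience components on traits.

    Fixed effects per response: standardized generation time (betaG),
    standardized mean reproductive output (betaR), their interaction
    (betaGxR) and matrix dimension (betaD) as a covariate; random effects as
    in the other models.  Predictors are expected already standardized;
    complete cases only.
    """
    config = config or ModelConfig()
    Y, sp, st = _prepare_trivariate(responses, species_ids, state_labels, vcv)
    G = np.asarray(generation_time, dtype=float)
    R = np.asarray(reproductive_output, dtype=float)
    D = np.asarray(matrix_dimension, dtype=float)
    for name, v in (("generation_time", G), ("reproductive_output", R), ("matrix_dimension", D)):
        if v.shape != (Y.shape[0],) or not np.all(np.isfinite(v)):
            raise ModelError(f"predictor {name} must be finite and aligned")
    r_gr = np.corrcoef(G, R)[0, 1]
    if abs(r_gr) > 0.95:
        warnings.warn(
            f"generation time and reproductive output are nearly collinear (r = {r_gr:.3f})",
            stacklevel=2,
        )
    X = np.column_stack([np.ones_like(G), G, R, G * R, D])
    gibbs = _TrivariateGibbs(
        Y,
        X,
        sp,
        st,
        vcv.matrix,
        student_t=False,
        coef_names=["beta0", "betaG", "betaR", "betaGxR", "betaD"],
        intercept_sd=1.0,
        slope_sd=10.0,
        scale_logp=_halfnormal_logp,
    )
    return gibbs.run(config)


def check_convergence(
    posterior: PosteriorSamples, config: ModelConfig | None = None
) -> tuple[bool, pd.Series]:
    """Pass/fail convergence gate: every Rhat at or below the threshold."""
    config = config or posterior.config
    if posterior.n_chains < 2:
        raise ModelError("convergence check requires at least 2 chains")
    rh = posterior.rhat()
    return bool((rh <= config.rhat_threshold).all()), rh
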