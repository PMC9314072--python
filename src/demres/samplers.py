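"""MCMC building blocks used by the multilevel models.

Two samplers are provided:

* :class:`EnsembleStretch` — the affine-invariant ensemble sampler
  (Goodman & Weare stretch moves), run as several independent ensembles
  batched through one vectorized log-posterior, so that between-ensemble
  agreement can be diagnosed with Rhat.  Used on the low-dimensional
  marginal posterior of the variance-partitioning model, where the random
  effects have been integrated out analytically; affine invariance copes
  with that posterior's strong scale correlations without step-size tuning.
* :func:`slice_sample` — univariate stepping-out/shrinkage slice sampling
  (Neal 2003), used inside the Gibbs sweeps for scale, correlation and
  degrees-of-freedom parameters whose full conditionals are not standard.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["EnsembleStretch", "slice_sample"]


def slice_sample(
    x0: float,
    logdensity: Callable[[float], float],
    rng: np.random.Generator,
    width: float = 1.0,
    max_steps: int = 50,
) -> float:
    """One univariate slice-sampling update of ``x0`` under ``logdensity``.

    Stepping-out with interval ``width`` then shrinkage; ``logdensity`` may
    return ``-inf`` outside the support.
    """
    ly0 = logdensity(x0)
    if not np.isfinite(ly0):
        raise ValueError("slice_sample started from a zero-density point")
    ly = ly0 + np.log(rng.uniform())
    left = x0 - width * rng.uniform()
    right = left + width
    j = int(max_steps * rng.uniform())
    k = max_steps - 1 - j
    while j > 0 and logdensity(left) > ly:
        left -= width
        j -= 1
    while k > 0 and logdensity(right) > ly:
        right += width
        k -= 1
    while True:
        x1 = left + (right - left) * rng.uniform()
        if logdensity(x1) > ly:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


class EnsembleStretch:
    """Independent stretch-move ensembles sharing one vectorized log-posterior.

    ``logpost`` maps a ``(points, dim)`` block to ``(points,)`` log-posterior
    values.  Each of the ``ensembles`` ensembles evolves ``walkers`` walkers
    by the standard stretch move (scale parameter ``a``): a walker is pulled
    toward/past a complementary walker of its own ensemble by a factor
    ``z ~ g(z) prop. 1/sqrt(z)`` on ``[1/a, a]``, accepted with probability
    ``z^(dim-1) pi(prop)/pi(cur)``.  Ensembles never exchange information,
    so they serve as the "chains" of convergence diagnostics.
    """

    def __init__(
        self,
        logpost: Callable[[np.ndarray], np.ndarray],
        init: np.ndarray,
        seed: int,
        a: float = 2.0,
    ) -> None:
        init = np.asarray(init, dtype=float)
        if init.ndim != 3 or init.shape[1] < 4 or init.shape[1] % 2:
            raise ValueError("init must be (ensembles, walkers, dim) with an even walker count >= 4")
        self.walkers = init.copy()
        self.E, self.W, self.D = init.shape
        self.a = a
        self.rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.logpost = logpost
        self.lp = logpost(init.reshape(-1, self.D)).reshape(self.E, self.W)
        if not np.all(np.isfinite(self.lp)):
            raise ValueError("ensemble initialized at zero-density points")

    def _half_step(self, idx: np.ndarray, comp: np.ndarray) -> None:
        E, H, D, a = self.E, idx.size, self.D, self.a
        cur = self.walkers[:, idx, :]
        j = self.rng.integers(0, comp.size, size=(E, H))
        partners = self.walkers[np.arange(E)[:, None], comp[j], :]
        z = (1.0 + (a - 1.0) * self.rng.uniform(size=(E, H))) ** 2 / a
        prop = partners + z[:, :, None] * (cur - partners)
        lp_prop = self.logpost(prop.reshape(-1, D)).reshape(E, H)
        log_accept = (D - 1) * np.log(z) + lp_prop - self.lp[:, idx]
        accept = np.log(self.rng.uniform(size=(E, H))) < log_accept
        sel = self.walkers[:, idx, :]
        sel[accept] = prop[accept]
        self.walkers[:, idx, :] = sel
        lps = self.lp[:, idx]
        lps[accept] = lp_prop[accept]
        self.lp[:, idx] = lps

    def run(self, moves: int, warmup: int) -> np.ndarray:
        """Run and return post-warmup draws shaped (ensembles, draws, dim).

        Each kept move contributes every walker's position, so draws per
        ensemble equal ``(moves - warmup) * walkers``.
        """
        if not 0 < warmup < moves:
            raise ValueError("need 0 < warmup < moves")
        half = self.W // 2
        first, second = np.arange(half), np.arange(half, self.W)
        kept = np.empty((moves - warmup, self.E, self.W, self.D))
        for t in range(moves):
            self._half_step(first, second)
            self._half_step(second, first)
            if t >= warmup:
                kept[t - warmup] = self.walkers
        out = np.moveaxis(kept, 1, 0)  # (E, moves-warmup, W, D)
        return out.reshape(self.E, -1, self.D)
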