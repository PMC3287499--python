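"""Bayesian change-point analysis over an ordered real series.

Product-partition model in the Barry–Hartigan style: contiguous blocks with
independent means, a uniform prior U(0, p0) on the per-position change
probability and U(0, w0) on the variance-ratio parameter w.  `bh_gibbs` runs
the Gibbs sampler (each indicator updated from its conditional odds with the
block-mean and noise parameters integrated out); `bh_exact` enumerates all
2^(n-1) indicator vectors for small n and serves as the engine's oracle.

The model is location/scale free: the conditional odds depend on the data
only through the between-block share of the total sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from . import _bh_kernel as _k
from .errors import SeriesSizeError, ValidationError

__all__ = [
    "BHParams",
    "ChangePointPosterior",
    "bh_gibbs",
    "bh_exact",
    "boundary_posterior",
]

_EXACT_MAX_N = 12


@dataclass(frozen=True)
class BHParams:
    """Sampler configuration.

    p0, w0
        Upper bounds of the uniform priors on the change probability and the
        variance-ratio parameter.  0.2 each: the conventional defaults of the
        fast implementation this engine follows.
    burnin, sweeps
        Discarded and retained full Gibbs sweeps.
    seed
        Seed for the sampler's RNG stream.
    """

    p0: float = 0.2
    w0: float = 0.2
    burnin: int = 50
    sweeps: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p0 <= 1.0) or not (0.0 < self.w0 <= 1.0):
            raise ValidationError("p0 and w0 must lie in (0, 1]")
        if self.sweeps < 1 or self.burnin < 0:
            raise ValidationError("need sweeps >= 1 and burnin >= 0")


@dataclass
class ChangePointPosterior:
    """Per-position change probabilities and posterior means.

    ``change_prob[i]`` (0-based, length n-1) is the posterior probability of
    a change between positions i+1 and i+2 in 1-based series coordinates;
    ``posterior_mean`` has one entry per observation.
    """

    change_prob: np.ndarray
    posterior_mean: np.ndarray

    def __post_init__(self) -> None:
        self.change_prob = np.asarray(self.change_prob, dtype=np.float64)
        self.posterior_mean = np.asarray(self.posterior_mean, dtype=np.float64)
        n = self.posterior_mean.size
        if self.change_prob.size != n - 1:
            raise ValidationError("change_prob must have length n - 1")
        if np.any((self.change_prob < 0) | (self.change_prob > 1)):
            raise ValidationError("change probabilities must lie in [0, 1]")
        if not np.all(np.isfinite(self.posterior_mean)):
            raise ValidationError("posterior means must be finite")

    @property
    def n(self) -> int:
        return self.posterior_mean.size


def _check_series(x, min_n: int = 4) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64).ravel()
    if not np.all(np.isfinite(x)):
        raise ValidationError("series contains non-finite values")
    if x.size < min_n:
        raise SeriesSizeError(f"series too short: need n >= {min_n}, got {x.size}")
    return x


def bh_gibbs(series, params: BHParams = BHParams()) -> ChangePointPosterior:
    """Gibbs-sampled posterior for the product-partition change-point model."""
    x = _check_series(series)
    tab = _k.engine_tables(x.size, params.p0, params.w0)
    change_prob, posterior_mean = _k.gibbs_run(
        x, int(params.seed) % (2**31), tab, params.burnin, params.sweeps
    )
    return ChangePointPosterior(change_prob, posterior_mean)


def bh_exact(series, params: BHParams = BHParams()) -> ChangePointPosterior:
    """Exact posterior by enumerating every indicator vector (n <= 12).

    Weighs each partition by its marginal likelihood, evaluated with the
    non-interpolated closed form (adaptive quadrature where the closed form
    does not apply).  This is the reference the sampler is tested against.
    """
    x = _check_series(series)
    n = x.size
    if n > _EXACT_MAX_N:
        raise SeriesSizeError(
            f"exact enumeration limited to n <= {_EXACT_MAX_N}, got {n}"
        )
    tab = _k.engine_tables(n, params.p0, params.w0)
    mu = float(np.mean(x))
    xc = x - mu
    S = np.concatenate([[0.0], np.cumsum(xc)])
    T = float(np.dot(xc, xc))

    n_masks = 1 << (n - 1)
    logw = np.empty(n_masks)
    block_means = np.empty((n_masks, n))
    for mask in range(n_masks):
        bounds = [j for j in range(n - 1) if (mask >> j) & 1]
        edges = [0] + [j + 1 for j in bounds] + [n]
        b = len(edges) - 1
        Q = 0.0
        for lo, hi in zip(edges[:-1], edges[1:]):
            s = S[hi] - S[lo]
            Q += s * s / (hi - lo)
            block_means[mask, lo:hi] = s / (hi - lo)
        logw[mask] = tab.logprior[b] + _k.log_w_integral_exact(Q, T, b, n, params.w0)
    logz = logsumexp(logw)
    post = np.exp(logw - logz)

    change_prob = np.empty(n - 1)
    for j in range(n - 1):
        sel = (np.arange(n_masks) >> j) & 1 == 1
        change_prob[j] = post[sel].sum()
    posterior_mean = post @ block_means + mu
    return ChangePointPosterior(np.clip(change_prob, 0.0, 1.0), posterior_mean)


def boundary_posterior(post: ChangePointPosterior, boundary: int) -> float:
    """Change probability at a 1-based boundary (between positions
    ``boundary`` and ``boundary + 1``)."""
    n = post.n
    if not 1 <= boundary <= n - 1:
        raise IndexError(f"boundary must lie in [1, {n - 1}], got {boundary}")
    return float(post.change_prob[boundary - 1])
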