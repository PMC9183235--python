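"""Probability densities used by the colocalization image model.

All densities are parameterized the way they enter the model:

* ``gamma_meanvar_logpdf`` — Gamma distribution given its mean and variance
  (shape = mean^2/var, rate = mean/var).  The camera noise model uses
  variance = mean * gain; the background prior uses (mean, sd^2).
* ``affine_beta_logpdf`` — Beta distribution rescaled to an interval
  (lower, upper), given its mean and standard deviation.
* ``trunc_poisson_pmf`` — Poisson truncated at a maximum count K, with all
  residual mass placed on K.
* ``m_prior_prob`` — marginal prior probability that spot k is present,
  conditional on which spot (if any) is target-specific.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special, stats

__all__ = [
    "gamma_meanvar_logpdf",
    "gamma_meanvar_sample",
    "affine_beta_params",
    "affine_beta_logpdf",
    "affine_beta_sample",
    "trunc_poisson_pmf",
    "m_prior_prob",
    "halfnormal_logpdf",
    "exponential_logpdf",
    "beta_logpdf",
    "uniform_logpdf",
]


def gamma_meanvar_logpdf(value, mean, variance):
    """Log-density of a Gamma distribution with given mean and variance.

    Shape ``alpha = mean**2 / variance`` and rate ``beta = mean / variance``.
    ``value <= 0`` yields ``-inf`` (not an exception); nonpositive mean or
    variance is a domain error.
    """
    mean = np.asarray(mean, dtype=float)
    variance = np.asarray(variance, dtype=float)
    if np.any(mean <= 0) or np.any(variance <= 0):
        raise ValueError("gamma_meanvar_logpdf requires mean > 0 and variance > 0")
    value = np.asarray(value, dtype=float)
    alpha = mean**2 / variance
    beta = mean / variance
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            alpha * np.log(beta)
            - special.gammaln(alpha)
            + (alpha - 1.0) * np.log(value)
            - beta * value
        )
    return np.where(value > 0, out, -np.inf)[()]


def gamma_meanvar_sample(rng, mean, variance, size=None):
    """Draw Gamma variates with given mean and variance."""
    mean = np.asarray(mean, dtype=float)
    variance = np.asarray(variance, dtype=float)
    shape = mean**2 / variance
    scale = variance / mean
    return rng.gamma(shape, scale, size=size)


def affine_beta_params(mean, sd, lower, upper):
    """Solve (alpha, beta) of the rescaled Beta with given mean and sd.

    With concentration ``nu = (mean-lower)*(upper-mean)/sd**2 - 1``:
    ``alpha = nu*(mean-lower)/(upper-lower)``, ``beta = nu*(upper-mean)/(upper-lower)``.
    Requires ``sd**2 < (mean-lower)*(upper-mean)``.
    """
    mean, sd = float(mean), float(sd)
    if not (lower < mean < upper):
        raise ValueError("mean must lie strictly inside (lower, upper)")
    span = (mean - lower) * (upper - mean)
    if sd <= 0 or sd**2 >= span:
        raise ValueError(
            f"sd^2 must be in (0, {span}) for mean {mean} on ({lower}, {upper})"
        )
    nu = span / sd**2 - 1.0
    alpha = nu * (mean - lower) / (upper - lower)
    beta = nu * (upper - mean) / (upper - lower)
    return alpha, beta


def affine_beta_logpdf(value, mean, sd, lower, upper):
    """Log-density of a Beta rescaled to (lower, upper) with given mean/sd.

    Values outside the open interval get ``-inf``.
    """
    alpha, beta = affine_beta_params(mean, sd, lower, upper)
    value = np.asarray(value, dtype=float)
    y = (value - lower) / (upper - lower)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            (alpha - 1.0) * np.log(y)
            + (beta - 1.0) * np.log1p(-y)
            - special.betaln(alpha, beta)
            - math.log(upper - lower)
        )
    return np.where((y > 0) & (y < 1), out, -np.inf)[()]


def affine_beta_sample(rng, mean, sd, lower, upper, size=None):
    alpha, beta = affine_beta_params(mean, sd, lower, upper)
    return lower + (upper - lower) * rng.beta(alpha, beta, size=size)


def trunc_poisson_pmf(k, lam, K):
    """Poisson(lam) pmf truncated at K: residual mass P(X >= K) sits on k = K."""
    if lam <= 0:
        raise ValueError("lam must be > 0")
    k = np.asarray(k)
    if np.any(k < 0) or np.any(k > K):
        raise ValueError(f"k must lie in [0, {K}]")
    if K == 0:
        return np.ones_like(k, dtype=float)[()]
    pmf = stats.poisson.pmf(k, lam)
    tail = float(stats.poisson.sf(K - 1, lam))
    return np.where(k == K, tail, pmf)[()]


def m_prior_rate(theta_is_zero: bool, lam: float, K: int) -> float:
    """Bernoulli rate for spot presence when the spot is not target-specific.

    For theta = 0 the rate is ``sum_l l * TruncPoisson(l; lam, K) / K``; for
    theta = j != k one of the K slots is taken by the specific spot, so the
    remaining K-1 slots share ``sum_l l * TruncPoisson(l; lam, K-1) / (K-1)``.
    """
    Keff = K if theta_is_zero else K - 1
    if Keff == 0:
        return 0.0
    ls = np.arange(1, Keff + 1)
    return float(np.sum(ls * trunc_poisson_pmf(ls, lam, Keff)) / Keff)


def m_prior_prob(theta: int, k: int, lam: float, K: int) -> float:
    """Prior probability that spot ``k`` is present given the specific index.

    Returns 1 exactly when ``theta == k``; otherwise a Bernoulli rate driven
    by the nonspecific binding density ``lam``.
    """
    if not (0 <= theta <= K):
        raise ValueError("theta out of range")
    if not (1 <= k <= K):
        raise ValueError("spot index out of range")
    if theta == k:
        return 1.0
    return m_prior_rate(theta == 0, lam, K)


def m_prior_rate_dlam(theta_is_zero: bool, lam: float, K: int) -> float:
    """d(m_prior_rate)/d(lam), used by the inference engine."""
    Keff = K if theta_is_zero else K - 1
    if Keff == 0:
        return 0.0
    ls = np.arange(1, Keff + 1)
    # d pmf(l)/dlam = pmf(l) * (l/lam - 1) for l < Keff; d tail/dlam = pmf(Keff-1)
    grads = np.empty(Keff)
    for i, l in enumerate(ls):
        if l < Keff:
            grads[i] = stats.poisson.pmf(l, lam) * (l / lam - 1.0)
        else:
            grads[i] = stats.poisson.pmf(Keff - 1, lam)
    return float(np.sum(ls * grads) / Keff)


def halfnormal_logpdf(value, scale):
    value = np.asarray(value, dtype=float)
    out = (
        0.5 * math.log(2.0 / math.pi)
        - math.log(scale)
        - value**2 / (2.0 * scale**2)
    )
    return np.where(value > 0, out, -np.inf)[()]


def exponential_logpdf(value, rate):
    value = np.asarray(value, dtype=float)
    return np.where(value > 0, math.log(rate) - rate * value, -np.inf)[()]


def beta_logpdf(value, alpha, beta):
    value = np.asarray(value, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            (alpha - 1.0) * np.log(value)
            + (beta - 1.0) * np.log1p(-value)
            - special.betaln(alpha, beta)
        )
    return np.where((value > 0) & (value < 1), out, -np.inf)[()]


def uniform_logpdf(value, lower, upper):
    value = np.asarray(value, dtype=float)
    return np.where(
        (value >= lower) & (value <= upper), -math.log(upper - lower), -np.inf
    )[()]
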