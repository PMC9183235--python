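"""Hot numerical kernel: offset-marginalized Gamma image log-likelihood.

For every spot-presence mask the kernel evaluates, per pixel,

    log sum_bins w_bin * Gamma(D - delta_bin; mean=mu_I, var=mu_I * g)

together with its derivatives with respect to mu_I (per pixel) and the
gain g.  A Numba implementation is used when available; a vectorized
NumPy/SciPy implementation provides a reference path (and is exercised
against the Numba one in the tests).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special

try:  # pragma: no cover - exercised indirectly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

_NEG_BIG = -1e30  # finite stand-in for an impossible pixel


def mixture_loglik_grad_numpy(muI, g, v, logv, logw, need_grad=True):
    """Reference implementation.

    Parameters
    ----------
    muI : (M, T, P, P) noise-free image per spot mask, flattened AOI-frames T
    g : float camera gain
    v, logv : (B, T, P, P) data minus each offset bin value, and its log
    logw : (B,) log offset-bin weights

    Returns ``logL (M, T)``, ``dmu (M, T, P, P)``, ``dg (M, T)``.
    """
    g = float(g)
    alpha = muI / g
    lga = special.gammaln(alpha)
    logg = math.log(g)
    valid = v > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (
            logw[:, None, None, None, None]
            - alpha[None] * logg
            - lga[None]
            + (alpha[None] - 1.0) * np.where(valid, logv, 0.0)[:, None]
            - np.where(valid, v, 0.0)[:, None] / g
        )
    terms = np.where(valid[:, None], terms, -np.inf)
    tmax = terms.max(axis=0)
    impossible = ~np.isfinite(tmax)
    tmax_safe = np.where(impossible, 0.0, tmax)
    w = np.exp(terms - tmax_safe[None])
    ssum = w.sum(axis=0)
    logG = np.where(impossible, _NEG_BIG, tmax_safe + np.log(np.where(ssum > 0, ssum, 1.0)))
    logL = logG.sum(axis=(2, 3))
    if not need_grad:
        return logL, None, None
    rho = w / np.where(ssum > 0, ssum, 1.0)[None]
    psi = special.digamma(alpha)
    c = np.where(valid, logv, 0.0)[:, None] - logg - psi[None]
    dmu = np.sum(np.where(valid[:, None], rho * c, 0.0), axis=0) / g
    dg_px = np.sum(
        np.where(
            valid[:, None],
            rho * ((-muI[None] * c - muI[None] + np.where(valid, v, 0.0)[:, None]) / g**2),
            0.0,
        ),
        axis=0,
    )
    dmu = np.where(impossible, 0.0, dmu)
    dg_px = np.where(impossible, 0.0, dg_px)
    return logL, dmu, dg_px.sum(axis=(2, 3))


if HAVE_NUMBA:

    @njit(cache=True)
    def _digamma(x):
        r = 0.0
        while x < 6.0:
            r -= 1.0 / x
            x += 1.0
        f = 1.0 / (x * x)
        return (
            r
            + math.log(x)
            - 0.5 / x
            - f
            * (
                1.0 / 12.0
                - f * (1.0 / 120.0 - f * (1.0 / 252.0 - f * (1.0 / 240.0 - f / 132.0)))
            )
        )

    @njit(cache=True)
    def _mixture_kernel(muI, g, v, logv, logw, need_grad):
        M, T, P = muI.shape[0], muI.shape[1], muI.shape[2]
        B = v.shape[0]
        logL = np.zeros((M, T))
        if need_grad:
            dmu = np.zeros((M, T, P, P))
            dg = np.zeros((M, T))
        else:
            dmu = np.zeros((1, 1, 1, 1))
            dg = np.zeros((1, 1))
        logg = math.log(g)
        terms = np.empty(B)
        for m in range(M):
            for t in range(T):
                acc = 0.0
                dgacc = 0.0
                for i in range(P):
                    for j in range(P):
                        mu = muI[m, t, i, j]
                        alpha = mu / g
                        lga = math.lgamma(alpha)
                        tmax = -np.inf
                        for b in range(B):
                            vv = v[b, t, i, j]
                            if vv <= 0.0:
                                terms[b] = -np.inf
                            else:
                                terms[b] = (
                                    logw[b]
                                    - alpha * logg
                                    - lga
                                    + (alpha - 1.0) * logv[b, t, i, j]
                                    - vv / g
                                )
                            if terms[b] > tmax:
                                tmax = terms[b]
                        if tmax == -np.inf:
                            acc += _NEG_BIG
                            continue
                        ssum = 0.0
                        for b in range(B):
                            terms[b] = math.exp(terms[b] - tmax)
                            ssum += terms[b]
                        acc += tmax + math.log(ssum)
                        if need_grad:
                            psi = _digamma(alpha)
                            dmu_px = 0.0
                            dg_px = 0.0
                            for b in range(B):
                                vv = v[b, t, i, j]
                                if vv <= 0.0:
                                    continue
                                rho = terms[b] / ssum
                                c = logv[b, t, i, j] - logg - psi
                                dmu_px += rho * c / g
                                dg_px += rho * ((-mu * c - mu + vv) / (g * g))
                            dmu[m, t, i, j] = dmu_px
                            dgacc += dg_px
                logL[m, t] = acc
                if need_grad:
                    dg[m, t] = dgacc
        return logL, dmu, dg

    def mixture_loglik_grad(muI, g, v, logv, logw, need_grad=True):
        muI = np.ascontiguousarray(muI)
        v = np.ascontiguousarray(v)
        logv = np.ascontiguousarray(logv)
        logL, dmu, dg = _mixture_kernel(
            muI, float(g), v, logv, np.ascontiguousarray(logw), need_grad
        )
        if not need_grad:
            return logL, None, None
        return logL, dmu, dg

else:  # pragma: no cover
    mixture_loglik_grad = mixture_loglik_grad_numpy
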