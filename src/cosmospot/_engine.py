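"""Stochastic variational inference engine.

Mean-field variational inference in the style of automatic differentiation
variational inference (ADVI): every continuous latent is given an
independent Gaussian factor in an unconstrained space linked to its support
by a smooth bijection (log for positive latents, a scaled logit for
interval-bounded ones).  The discrete latents (z, theta, m) and the
empirical offset are never sampled: they are summed out exactly inside the
likelihood, so the evidence lower bound (ELBO) is estimated only over the
continuous latents, with reparameterized (pathwise) gradients assembled
from hand-derived derivatives of every model term.

The public fitting API wrapping this engine lives in :mod:`.inference`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from . import distributions as dist
from . import model as mdl
from ._kernels import mixture_loglik_grad

LOG_2PI_E = math.log(2.0 * math.pi * math.e)


# ----------------------------------------------------------------- transforms
@dataclass(frozen=True)
class Transform:
    """Bijection from the unconstrained real line to the latent support."""

    kind: str  # "log" or "interval"
    lo: float = 0.0
    hi: float = 1.0

    def forward(self, u):
        if self.kind == "log":
            return np.exp(u)
        s = special.expit(u)
        return self.lo + (self.hi - self.lo) * s

    def inverse(self, v):
        if self.kind == "log":
            return np.log(v)
        y = (np.asarray(v, dtype=float) - self.lo) / (self.hi - self.lo)
        y = np.clip(y, 1e-12, 1.0 - 1e-12)
        return special.logit(y)

    def dv_du(self, u, v):
        if self.kind == "log":
            return v
        s = special.expit(u)
        return (self.hi - self.lo) * s * (1.0 - s)

    def log_jac(self, u):
        if self.kind == "log":
            return u
        s = special.expit(u)
        with np.errstate(divide="ignore"):
            return math.log(self.hi - self.lo) + np.log(s) + np.log1p(-s)

    def dlog_jac_du(self, u):
        if self.kind == "log":
            return np.ones_like(u)
        s = special.expit(u)
        return 1.0 - 2.0 * s


# --------------------------------------------------------------- config table
@dataclass(frozen=True)
class ConfigTable:
    """Vectorized layout of the admissible (z, theta, m) combinations."""

    K: int
    z: np.ndarray  # (C,)
    theta: np.ndarray  # (C,)
    mask_index: np.ndarray  # (C,) index into the 2**K mu_I masks
    masks: np.ndarray  # (2**K, K) 0/1
    n_on: np.ndarray  # (C,) count of present nonspecific spots (k != theta)
    n_off: np.ndarray  # (C,) count of absent spots

    @classmethod
    def build(cls, K: int) -> "ConfigTable":
        configs = mdl.admissible_configs(K)
        masks = np.array(
            [[(bits >> k) & 1 for k in range(K)] for bits in range(2**K)], dtype=float
        )
        mask_lookup = {tuple(int(x) for x in row): i for i, row in enumerate(masks)}
        z = np.array([c.z for c in configs])
        theta = np.array([c.theta for c in configs])
        midx = np.array([mask_lookup[c.m] for c in configs])
        n_on = np.array(
            [sum(c.m[k] for k in range(K) if k + 1 != c.theta) for c in configs]
        )
        n_off = np.array(
            [sum(1 - c.m[k] for k in range(K) if k + 1 != c.theta) for c in configs]
        )
        return cls(K=K, z=z, theta=theta, mask_index=midx, masks=masks, n_on=n_on, n_off=n_off)

    @property
    def n_configs(self) -> int:
        return len(self.z)

    def log_prior(self, pi: float, lam: float):
        """(C,) log prior for on-target and control AOIs, plus the
        d/dlam coefficient per config (for on-target; control shares it)."""
        K = self.K
        r0 = dist.m_prior_rate(True, lam, K)
        r1 = dist.m_prior_rate(False, lam, K)
        dr0 = dist.m_prior_rate_dlam(True, lam, K)
        dr1 = dist.m_prior_rate_dlam(False, lam, K)
        r = np.where(self.theta == 0, r0, r1)
        dr = np.where(self.theta == 0, dr0, dr1)
        with np.errstate(divide="ignore"):
            lp_m = self.n_on * np.log(r) + self.n_off * np.log1p(-r)
        lp_m = np.where((self.n_on > 0) & (r == 0.0), -np.inf, lp_m)
        lp_on = (
            np.where(self.z == 1, math.log(pi) - math.log(K), math.log1p(-pi)) + lp_m
        )
        lp_ctrl = np.where(self.z == 0, lp_m, -np.inf)
        dlam_coef = np.where(
            r * (1.0 - r) > 0, (self.n_on / np.where(r > 0, r, 1.0) - self.n_off / np.where(r < 1, 1.0 - r, 1.0)) * dr, 0.0
        )
        return lp_on, lp_ctrl, dlam_coef


# ------------------------------------------------------- affine-beta helpers
def _ab_logpdf_and_grads(x, sigma, a):
    """Symmetric AffineBeta(0, sigma, -a, a): logpdf, d/dx, d/dsigma.

    alpha = beta = nu/2 with nu = a^2/sigma^2 - 1.
    """
    nu = a * a / (sigma * sigma) - 1.0
    al = nu / 2.0
    y = (x + a) / (2.0 * a)
    logy = np.log(y)
    log1my = np.log1p(-y)
    logpdf = (
        (al - 1.0) * (logy + log1my)
        - (2.0 * special.gammaln(al) - special.gammaln(nu))
        - math.log(2.0 * a)
    )
    dx = (al - 1.0) * (1.0 / y - 1.0 / (1.0 - y)) / (2.0 * a)
    dnu = 0.5 * (logy + log1my) - special.digamma(al) + special.digamma(nu)
    dsigma = dnu * (-2.0 * a * a / sigma**3)
    return logpdf, dx, dsigma


def _gamma_meansd_grads(b, mu, sd):
    """Gamma(mean mu, sd) logpdf of b plus d/db, d/dmu, d/dsd."""
    var = sd * sd
    alpha = mu * mu / var
    beta = mu / var
    logb = np.log(b)
    logpdf = alpha * np.log(beta) - special.gammaln(alpha) + (alpha - 1.0) * logb - beta * b
    dl_da = np.log(beta) - special.digamma(alpha) + logb
    dl_dbeta = alpha / beta - b
    db = (alpha - 1.0) / b - beta
    dmu = dl_da * (2.0 * mu / var) + dl_dbeta * (1.0 / var)
    dsd = dl_da * (-2.0 * mu * mu / sd**3) + dl_dbeta * (-2.0 * mu / sd**3)
    return logpdf, db, dmu, dsd


# ------------------------------------------------------------------- forward
@dataclass
class ForwardResult:
    logp_local: float  # sum over batch frames of local log density
    grads: dict | None
    r_config: np.ndarray | None  # (C, n, f) responsibilities
    log_marginal: np.ndarray | None  # (n, f)


def spot_surfaces(h, w, x, y, xt, yt, P):
    """Spot surfaces S (K, n, f, P, P) and the pixel-offset grids."""
    i = np.arange(P, dtype=float)
    di = i[None, None, None, :] - x[..., None] - xt[None, ..., None]  # (K,n,f,P)
    dj = i[None, None, None, :] - y[..., None] - yt[None, ..., None]
    d2 = di[..., :, None] ** 2 + dj[..., None, :] ** 2  # (K,n,f,P,P)
    S = h[..., None, None] / (2.0 * math.pi * w[..., None, None] ** 2) * np.exp(
        -d2 / (2.0 * w[..., None, None] ** 2)
    )
    return S, di, dj, d2


def forward_backward(
    values: dict,
    D: np.ndarray,
    xt: np.ndarray,
    yt: np.ndarray,
    is_control: np.ndarray,
    offset_samples: np.ndarray,
    offset_logw: np.ndarray,
    table: ConfigTable,
    P: int,
    need_grad: bool = True,
    v_cache=None,
):
    """Evaluate the marginalized local log density and its gradients.

    ``values`` holds constrained latent values for the mini-batch:
    scalars ``g, sigma_xy, pi, lam``; per-AOI ``mu_b, sigma_b`` (n,);
    ``b`` (n, f); per-spot ``h, w, x, y`` (K, n, f).
    Returns gradients with respect to the *constrained* values.
    """
    K = table.K
    n, f = D.shape[0], D.shape[1]
    T = n * f
    g = float(values["g"])
    sigma_xy = float(values["sigma_xy"])
    pi = float(values["pi"])
    lam = float(values["lam"])
    b = values["b"]
    h, w, x, y = values["h"], values["w"], values["x"], values["y"]
    a_bound = mdl.position_bound(P)

    S, di, dj, d2 = spot_surfaces(h, w, x, y, xt, yt, P)
    M = table.masks.shape[0]
    muI = b[None, :, :, None, None] + np.einsum("mk,knfij->mnfij", table.masks, S)

    if v_cache is None:
        v = D[None] - offset_samples[:, None, None, None, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            logv = np.where(v > 0, np.log(np.where(v > 0, v, 1.0)), 0.0)
    else:
        v, logv = v_cache
    B = len(offset_samples)
    logL, dmu, dg_px = mixture_loglik_grad(
        muI.reshape(M, T, P, P),
        g,
        v.reshape(B, T, P, P),
        logv.reshape(B, T, P, P),
        offset_logw,
        need_grad,
    )
    logL = logL.reshape(M, n, f)

    # position priors
    logU2 = -2.0 * math.log(2.0 * a_bound)
    ab_x, dab_x, dsig_x = _ab_logpdf_and_grads(x, sigma_xy, a_bound)
    ab_y, dab_y, dsig_y = _ab_logpdf_and_grads(y, sigma_xy, a_bound)
    logAB = ab_x + ab_y  # (K, n, f)

    lp_on, lp_ctrl, dlam_coef = table.log_prior(pi, lam)
    C = table.n_configs
    logP = np.where(is_control[None, :], lp_ctrl[:, None], lp_on[:, None])  # (C, n)

    T_c = logP[:, :, None] + K * logU2 + logL[table.mask_index]
    th = table.theta
    spec = th > 0
    T_c = T_c + np.where(
        spec[:, None, None], (logAB - logU2)[np.maximum(th - 1, 0)], 0.0
    )
    T_max = T_c.max(axis=0)
    with np.errstate(invalid="ignore"):
        expT = np.exp(T_c - T_max[None])
    expT = np.where(np.isfinite(T_c), expT, 0.0)
    Z = expT.sum(axis=0)
    log_marg = T_max + np.log(Z)
    r = expT / Z[None]  # (C, n, f)

    # m-independent local priors
    mu_b = values["mu_b"][:, None]
    sigma_b = values["sigma_b"][:, None]
    lp_b, db_prior, dmub, dsigb = _gamma_meansd_grads(b, mu_b, sigma_b)
    lp_h = dist.halfnormal_logpdf(h, mdl.H_PRIOR_SCALE)
    lp_w = -math.log(mdl.W_MAX - mdl.W_MIN) * np.ones_like(w)

    logp_local = float(log_marg.sum() + lp_b.sum() + lp_h.sum() + lp_w.sum())

    if not need_grad:
        return ForwardResult(logp_local, None, r, log_marg)

    dmu = dmu.reshape(M, n, f, P, P)
    dg_px = dg_px.reshape(M, n, f)
    omega = np.zeros((M, n, f))
    np.add.at(omega, table.mask_index, r)
    # rho_k: responsibility that spot k is the specific one
    rho = np.zeros((K, n, f))
    for k in range(1, K + 1):
        rho[k - 1] = r[th == k].sum(axis=0)

    dmu_sum = dmu.sum(axis=(3, 4))  # (M, n, f)
    grad_b = (omega * dmu_sum).sum(axis=0) + db_prior
    grad_g = float((omega * dg_px).sum())

    w2 = w[..., None, None] ** 2
    grads_h = np.empty_like(h)
    grads_w = np.empty_like(w)
    grads_x = np.empty_like(x)
    grads_y = np.empty_like(y)
    for k in range(K):
        rows = [i for i in range(M) if table.masks[i, k] > 0]
        Wk = np.einsum("mnf,mnfij->nfij", omega[rows], dmu[rows])
        WS = Wk * S[k]
        grads_h[k] = WS.sum(axis=(2, 3)) / h[k] - h[k] / mdl.H_PRIOR_SCALE**2
        grads_x[k] = (WS * di[k][:, :, :, None]).sum(axis=(2, 3)) / w[k] ** 2 + rho[k] * dab_x[k]
        grads_y[k] = (WS * dj[k][:, :, None, :]).sum(axis=(2, 3)) / w[k] ** 2 + rho[k] * dab_y[k]
        grads_w[k] = (WS * (d2[k] / w2[k] - 2.0) ).sum(axis=(2, 3)) / w[k]

    grad_sigma = float((rho * (dsig_x + dsig_y)).sum())
    on_t = ~is_control
    z_r = r[table.z == 1].sum(axis=0)  # (n, f) specific probability
    grad_pi = float(((z_r[on_t] - pi) / (pi * (1.0 - pi))).sum())
    grad_lam = float((r * dlam_coef[:, None, None]).sum())

    grads = {
        "b": grad_b,
        "h": grads_h,
        "w": grads_w,
        "x": grads_x,
        "y": grads_y,
        "g": grad_g,
        "sigma_xy": grad_sigma,
        "pi": grad_pi,
        "lam": grad_lam,
        "mu_b": dmub.sum(axis=1),
        "sigma_b": dsigb.sum(axis=1),
    }
    return ForwardResult(logp_local, grads, r, log_marg)


def global_prior_and_grads(values: dict):
    """Log priors of the dataset-level latents and their gradients."""
    g, sigma_xy, pi, lam = (
        float(values["g"]),
        float(values["sigma_xy"]),
        float(values["pi"]),
        float(values["lam"]),
    )
    mu_b, sigma_b = values["mu_b"], values["sigma_b"]
    lp = (
        float(dist.halfnormal_logpdf(g, mdl.G_PRIOR_SCALE))
        + float(dist.exponential_logpdf(sigma_xy, mdl.SIGMA_XY_PRIOR_RATE))
        + float(dist.beta_logpdf(pi, 0.5, 0.5))
        + float(dist.exponential_logpdf(lam, mdl.LAM_PRIOR_RATE))
        + float(np.sum(dist.halfnormal_logpdf(mu_b, mdl.MU_B_PRIOR_SCALE)))
        + float(np.sum(dist.halfnormal_logpdf(sigma_b, mdl.SIGMA_B_PRIOR_SCALE)))
    )
    grads = {
        "g": -g / mdl.G_PRIOR_SCALE**2,
        "sigma_xy": -mdl.SIGMA_XY_PRIOR_RATE,
        "pi": -0.5 / pi + 0.5 / (1.0 - pi),
        "lam": -mdl.LAM_PRIOR_RATE,
        "mu_b": -mu_b / mdl.MU_B_PRIOR_SCALE**2,
        "sigma_b": -sigma_b / mdl.SIGMA_B_PRIOR_SCALE**2,
    }
    return lp, grads


# ---------------------------------------------------------------------- Adam
@dataclass
class AdamState:
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    t: dict = field(default_factory=dict)

    @classmethod
    def for_params(cls, params: dict) -> "AdamState":
        st = cls()
        for name, arr in params.items():
            st.m[name] = np.zeros_like(arr)
            st.v[name] = np.zeros_like(arr)
            st.t[name] = np.zeros(np.shape(arr))
        return st


def adam_update(state: AdamState, name, param, grad, lr, idx=None, b1=0.9, b2=0.999, eps=1e-8):
    """One Adam ascent step; ``idx`` restricts the update to a mini-batch
    slice (per-element bias-correction counters keep the step unbiased)."""
    if idx is None:
        m = state.m[name] = b1 * state.m[name] + (1 - b1) * grad
        v = state.v[name] = b2 * state.v[name] + (1 - b2) * grad**2
        t = state.t[name] = state.t[name] + 1.0
        mhat = m / (1.0 - b1**t)
        vhat = v / (1.0 - b2**t)
        param += lr * mhat / (np.sqrt(vhat) + eps)
    else:
        m = state.m[name][idx] = b1 * state.m[name][idx] + (1 - b1) * grad
        v = state.v[name][idx] = b2 * state.v[name][idx] + (1 - b2) * grad**2
        t = state.t[name][idx] = state.t[name][idx] + 1.0
        mhat = m / (1.0 - b1**t)
        vhat = v / (1.0 - b2**t)
        param[idx] += lr * mhat / (np.sqrt(vhat) + eps)
    return param
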