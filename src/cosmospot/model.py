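"""The generative image model for CoSMoS colocalization data.

Each P x P AOI image D is modeled as an offset delta plus a photon-dependent
image I with Gamma noise whose variance equals the noise-free intensity
mu_I times the camera gain g.  mu_I is a background b plus up to K 2-D
Gaussian spots; a binary state z says whether one of the spots is
target-specific, theta indexes which one, and m marks which spots exist.
The offset is marginalized exactly over its empirical distribution, and the
discrete latents (z, theta, m) can be enumerated exactly: for K spots there
are 2**K + K * 2**(K-1) admissible combinations (8 for K = 2).

This module is the plain-NumPy reference implementation of all densities;
the optimized vectorized path used for fitting lives in ``_engine``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from . import distributions as dist
from .aoi_io import OffsetEmpirical

__all__ = [
    "GlobalParams",
    "AOIParams",
    "FrameLatents",
    "SpotLatents",
    "Config",
    "admissible_configs",
    "config_log_prior",
    "spot_surface",
    "ideal_image",
    "image_loglik",
    "local_prior_logpdf",
    "joint_logpdf",
    "marginal_logpdf",
    "sigma_xy_max",
    "position_bound",
]

# Prior hyperparameters (fixed; see docs/methods.md)
H_PRIOR_SCALE = 10000.0  # HalfNormal scale on integrated spot intensity
G_PRIOR_SCALE = 50.0  # HalfNormal scale on camera gain
MU_B_PRIOR_SCALE = 1000.0  # HalfNormal scale on mean background
SIGMA_B_PRIOR_SCALE = 100.0  # HalfNormal scale on background sd
W_MIN, W_MAX = 0.75, 2.25  # uniform prior bounds on spot width (pixels)
LAM_PRIOR_RATE = 1.0  # Exponential prior on nonspecific density
SIGMA_XY_PRIOR_RATE = 1.0  # Exponential prior on proximity


def position_bound(P: int) -> float:
    """Half-width of the spot-position support: centers may fall up to one
    pixel outside the AOI, so (x, y) live in (-(P+1)/2, (P+1)/2)."""
    return (P + 1) / 2.0


def sigma_xy_max(P: int) -> float:
    """Largest admissible proximity sd: the sd of a uniform on the position
    support, (P+1)/sqrt(12).  At this value the specific-position prior
    degenerates to the nonspecific (uniform) one."""
    return (P + 1) / math.sqrt(12.0)


@dataclass
class GlobalParams:
    """Dataset-level parameters: gain, proximity, specific-binding
    probability and nonspecific binding density."""

    g: float
    sigma_xy: float
    pi: float
    lam: float

    def validate(self, P: int) -> None:
        if self.g <= 0 or self.lam <= 0:
            raise ValueError("g and lam must be positive")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        if not 0.0 < self.sigma_xy < sigma_xy_max(P):
            raise ValueError(f"sigma_xy must lie in (0, {sigma_xy_max(P):.4g})")


@dataclass
class AOIParams:
    mu_b: np.ndarray  # (n_aoi,)
    sigma_b: np.ndarray


@dataclass
class FrameLatents:
    b: np.ndarray  # (n_aoi, F)
    z: np.ndarray  # (n_aoi, F) in {0, 1}
    theta: np.ndarray  # (n_aoi, F) in {0..K}


@dataclass
class SpotLatents:
    m: np.ndarray  # (K, n_aoi, F) in {0, 1}
    h: np.ndarray
    w: np.ndarray
    x: np.ndarray
    y: np.ndarray


@dataclass(frozen=True)
class Config:
    """One admissible assignment of the discrete latents (z, theta, m)."""

    z: int
    theta: int
    m: tuple  # length K


def admissible_configs(K: int) -> list[Config]:
    """All (z, theta, m) combinations with nonzero prior probability.

    z = 0 forces theta = 0 with free m; z = 1 allows theta = k only when
    m[k] = 1.  Counts 2**K + K * 2**(K-1) (= 8 for K = 2).
    """
    configs = []
    for bits in range(2**K):
        m = tuple((bits >> k) & 1 for k in range(K))
        configs.append(Config(z=0, theta=0, m=m))
    for theta in range(1, K + 1):
        for bits in range(2 ** (K - 1)):
            free = [(bits >> i) & 1 for i in range(K - 1)]
            m = []
            j = 0
            for k in range(1, K + 1):
                if k == theta:
                    m.append(1)
                else:
                    m.append(free[j])
                    j += 1
            configs.append(Config(z=1, theta=theta, m=tuple(m)))
    return configs


def config_log_prior(
    cfg: Config, pi: float, lam: float, K: int, is_control: bool
) -> float:
    """log p(z) + log p(theta | z) + sum_k log p(m_k | theta, lam)."""
    if is_control:
        if cfg.z != 0:
            return -np.inf
        lp = 0.0
    else:
        if cfg.z == 1 and pi == 0.0:
            return -np.inf
        if cfg.z == 0 and pi == 1.0:
            return -np.inf
        lp = math.log(pi) if cfg.z == 1 else math.log1p(-pi)
    if cfg.z == 1:
        lp += -math.log(K)  # theta uniform over {1..K}
    for k in range(1, K + 1):
        rate = dist.m_prior_prob(cfg.theta, k, lam, K)
        mk = cfg.m[k - 1]
        if cfg.theta == k:
            continue  # probability 1
        lp += math.log(rate) if mk else math.log1p(-rate)
    return lp


def spot_surface(m, h, w, x, y, x_target, y_target, P: int) -> np.ndarray:
    """Noise-free surface of one 2-D Gaussian spot on the P x P pixel grid.

    ``m = 0`` gives the zero surface.  The peak integrates to h over the
    plane; pixel (i, j) evaluates the density at the pixel center.
    """
    i = np.arange(P, dtype=float)[:, None]
    j = np.arange(P, dtype=float)[None, :]
    d2 = (i - x - x_target) ** 2 + (j - y - y_target) ** 2
    return m * h / (2.0 * math.pi * w**2) * np.exp(-d2 / (2.0 * w**2))


def ideal_image(b: float, surfaces) -> np.ndarray:
    """Pixelwise b + sum of spot surfaces."""
    if b <= 0:
        raise ValueError("background must be positive")
    out = None
    for s in surfaces:
        out = s.copy() if out is None else out + s
    if out is None:
        raise ValueError("provide at least one (possibly zero) surface")
    return b + out


def image_loglik(
    D_image: np.ndarray, mu_I: np.ndarray, g: float, offset: OffsetEmpirical
) -> float:
    """Log-likelihood of one AOI image with the offset marginalized exactly.

    Per pixel: log sum_bins weight_bin * Gamma(D - delta_bin; mu_I, mu_I*g),
    summed over pixels.  Bins with D - delta_bin <= 0 contribute no mass.
    If some pixel is <= min(offset.samples) the image has zero likelihood
    under the model; returns -inf with a warning.
    """
    D_image = np.asarray(D_image, dtype=float)
    mu_I = np.asarray(mu_I, dtype=float)
    if np.any(mu_I <= 0):
        raise ValueError("mu_I must be positive everywhere")
    if D_image.min() <= offset.samples[0]:
        warnings.warn(
            "image contains pixels not larger than the smallest offset value; "
            "log-likelihood is -inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return -np.inf
    v = D_image[None] - offset.samples[:, None, None]  # (B, P, P)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = dist.gamma_meanvar_logpdf(v, mu_I[None], (mu_I * g)[None])
        lp = np.where(v > 0, lp, -np.inf)
        terms = np.log(offset.weights)[:, None, None] + lp
    return float(np.sum(logsumexp(terms, axis=0)))


def _position_log_prior(cfg, spots, glob, P):
    bound = position_bound(P)
    lp = 0.0
    for k in range(1, K_of(spots) + 1):
        xk, yk = spots.x[k - 1], spots.y[k - 1]
        if cfg.theta == k:
            lp += dist.affine_beta_logpdf(xk, 0.0, glob.sigma_xy, -bound, bound)
            lp += dist.affine_beta_logpdf(yk, 0.0, glob.sigma_xy, -bound, bound)
        else:
            lp += dist.uniform_logpdf(xk, -bound, bound)
            lp += dist.uniform_logpdf(yk, -bound, bound)
    return lp


def K_of(spots: SpotLatents) -> int:
    return np.asarray(spots.m).shape[0]


def local_prior_logpdf(
    b: float,
    cfg: Config,
    spots: SpotLatents,
    aoi_mu_b: float,
    aoi_sigma_b: float,
    glob: GlobalParams,
    is_control: bool,
    P: int,
) -> float:
    """Log-prior of one frame's latents (continuous + discrete) for one AOI.

    Spot latents here are scalars per spot: ``spots.m/h/w/x/y`` of shape (K,).
    An impossible combination (theta = k but m[k] = 0) returns -inf.
    """
    K = K_of(spots)
    if cfg.theta > 0 and spots.m[cfg.theta - 1] == 0:
        return -np.inf
    if tuple(int(v) for v in spots.m) != tuple(cfg.m):
        raise ValueError("spots.m must agree with cfg.m")
    lp = dist.gamma_meanvar_logpdf(b, aoi_mu_b, aoi_sigma_b**2)
    lp += config_log_prior(cfg, glob.pi, glob.lam, K, is_control)
    for k in range(K):
        lp += dist.halfnormal_logpdf(spots.h[k], H_PRIOR_SCALE)
        lp += dist.uniform_logpdf(spots.w[k], W_MIN, W_MAX)
    lp += _position_log_prior(cfg, spots, glob, P)
    return float(lp)


def global_prior_logpdf(glob: GlobalParams, aoi: AOIParams) -> float:
    lp = dist.halfnormal_logpdf(glob.g, G_PRIOR_SCALE)
    lp += dist.exponential_logpdf(glob.sigma_xy, SIGMA_XY_PRIOR_RATE)
    lp += dist.beta_logpdf(glob.pi, 0.5, 0.5)
    lp += dist.exponential_logpdf(glob.lam, LAM_PRIOR_RATE)
    lp += np.sum(dist.halfnormal_logpdf(aoi.mu_b, MU_B_PRIOR_SCALE))
    lp += np.sum(dist.halfnormal_logpdf(aoi.sigma_b, SIGMA_B_PRIOR_SCALE))
    return float(lp)


def _frame_mu_I(b, spots, m, xt, yt, P):
    K = K_of(spots)
    surfaces = [
        spot_surface(m[k], spots.h[k], spots.w[k], spots.x[k], spots.y[k], xt, yt, P)
        for k in range(K)
    ]
    return ideal_image(b, surfaces)


def joint_logpdf(dataset, glob: GlobalParams, aoi: AOIParams, frames: FrameLatents, spots: SpotLatents) -> float:
    """Fully factorized joint log-density of data and all latents.

    Sums the global priors once, per-AOI background hyperpriors, per-frame
    priors of all latents (including the discrete z/theta/m), and the
    offset-marginalized image likelihood.
    """
    P = dataset.P
    glob.validate(P)
    n, F = dataset.n_aoi, dataset.F
    lp = global_prior_logpdf(glob, aoi)
    for a in range(n):
        for f in range(F):
            cfg = Config(
                z=int(frames.z[a, f]),
                theta=int(frames.theta[a, f]),
                m=tuple(int(v) for v in spots.m[:, a, f]),
            )
            sp = SpotLatents(
                m=spots.m[:, a, f],
                h=spots.h[:, a, f],
                w=spots.w[:, a, f],
                x=spots.x[:, a, f],
                y=spots.y[:, a, f],
            )
            lp_frame = local_prior_logpdf(
                frames.b[a, f],
                cfg,
                sp,
                aoi.mu_b[a],
                aoi.sigma_b[a],
                glob,
                bool(dataset.is_control[a]),
                P,
            )
            if not np.isfinite(lp_frame):
                return -np.inf
            mu_I = _frame_mu_I(
                frames.b[a, f], sp, cfg.m, dataset.x_target[a, f], dataset.y_target[a, f], P
            )
            lp += lp_frame + image_loglik(dataset.data[a, f], mu_I, glob.g, dataset.offset)
    return float(lp)


def marginal_logpdf(dataset, glob: GlobalParams, aoi: AOIParams, b: np.ndarray, spots: SpotLatents) -> float:
    """Joint log-density with z, theta and m summed out exactly.

    ``spots`` here carries only the continuous latents (h, w, x, y); its
    ``m`` field is ignored.  Everywhere finite for valid data.
    """
    P = dataset.P
    glob.validate(P)
    K = np.asarray(spots.h).shape[0]
    configs = admissible_configs(K)
    lp = global_prior_logpdf(glob, aoi)
    for a in range(dataset.n_aoi):
        is_ctrl = bool(dataset.is_control[a])
        for f in range(dataset.F):
            sp = SpotLatents(
                m=np.zeros(K, dtype=int),
                h=spots.h[:, a, f],
                w=spots.w[:, a, f],
                x=spots.x[:, a, f],
                y=spots.y[:, a, f],
            )
            base = dist.gamma_meanvar_logpdf(b[a, f], aoi.mu_b[a], aoi.sigma_b[a] ** 2)
            for k in range(K):
                base += dist.halfnormal_logpdf(sp.h[k], H_PRIOR_SCALE)
                base += dist.uniform_logpdf(sp.w[k], W_MIN, W_MAX)
            terms = []
            for cfg in configs:
                lw = config_log_prior(cfg, glob.pi, glob.lam, K, is_ctrl)
                if not np.isfinite(lw):
                    continue
                lw += _position_log_prior(cfg, sp, glob, P)
                mu_I = _frame_mu_I(
                    b[a, f], sp, cfg.m, dataset.x_target[a, f], dataset.y_target[a, f], P
                )
                lw += image_loglik(dataset.data[a, f], mu_I, glob.g, dataset.offset)
                terms.append(lw)
            lp += base + logsumexp(terms)
    return float(lp)
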