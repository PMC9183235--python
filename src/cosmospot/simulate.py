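"""Ground-truth simulation of CoSMoS AOI datasets.

Draws every latent of the generative model — specific-binding states
(Bernoulli or a two-state Markov chain at equilibrium), spot presence from
the truncated-Poisson prior, positions (tightly colocalized for specific
spots, uniform for nonspecific ones) — and renders noisy images with Gamma
camera noise (variance = mean x gain) plus an empirical integer offset.
The returned truth object makes every stage of the pipeline testable.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from . import distributions as dist
from . import model as mdl
from .aoi_io import AOIDataset, OffsetEmpirical

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_dataset",
    "simulate_kinetic_states",
    "snr_theoretical",
    "snr_empirical",
    "height_for_snr",
    "posterior_predictive",
    "default_offset",
]


def default_offset() -> OffsetEmpirical:
    """Three-point empirical offset; exercises the mixture marginalization."""
    return OffsetEmpirical(samples=[90.0, 100.0, 110.0], weights=[0.5, 0.3, 0.2])


@dataclass
class SimConfig:
    """Study conditions of one simulation (defaults in docs/methods.md)."""

    N: int = 10  # on-target AOIs
    Nc: int = 10  # off-target control AOIs
    F: int = 100  # frames
    P: int = 14  # AOI edge (pixels)
    K: int = 2  # max spots per AOI image
    pi: float = 0.15  # specific-binding probability
    lam: float = 0.15  # nonspecific spots per AOI image
    g: float = 7.0  # camera gain
    sigma_xy: float = 0.5  # proximity (pixels)
    b: float = 150.0  # background intensity
    mu_b: float | None = None  # if set with sigma_b: per AOI/frame Gamma background
    sigma_b: float | None = None
    h: float = 3000.0  # integrated spot intensity
    w: float = 1.4  # spot width (pixels)
    snr_target: float | None = None  # overrides h when set
    offset_samples: tuple = (90.0, 100.0, 110.0)
    offset_weights: tuple = (0.5, 0.3, 0.2)
    kon: float | None = None  # per-frame transition probabilities; both set
    koff: float | None = None  # -> z follows an equilibrium Markov chain
    frame_interval: float = 1.0  # seconds
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        if min(self.N + self.Nc, self.F, self.P) < 1 or self.P % 2 or self.P < 6:
            raise ValueError("invalid sizes (P must be even and >= 6)")
        if self.lam <= 0 or self.g <= 0 or self.b <= 0 or self.h <= 0:
            raise ValueError("lam, g, b, h must be positive")
        if not mdl.W_MIN <= self.w <= mdl.W_MAX:
            raise ValueError("w outside the admissible width range")
        if not 0 < self.sigma_xy < mdl.sigma_xy_max(self.P):
            raise ValueError(
                f"sigma_xy infeasible for the position prior (must be < "
                f"{mdl.sigma_xy_max(self.P):.4g})"
            )
        if (self.kon is None) != (self.koff is None):
            raise ValueError("set kon and koff together")
        if self.kon is not None and not (0 < self.kon < 1 and 0 < self.koff < 1):
            raise ValueError("kon, koff must lie in (0, 1)")

    @property
    def offset(self) -> OffsetEmpirical:
        return OffsetEmpirical(
            samples=np.asarray(self.offset_samples),
            weights=np.asarray(self.offset_weights),
        )

    @property
    def height(self) -> float:
        if self.snr_target is not None:
            return height_for_snr(
                self.snr_target, self.w, self.b, self.g, self.offset
            )
        return self.h


@dataclass
class SimTruth:
    """Ground-truth latents paired with the simulated dataset."""

    z: np.ndarray  # (n_aoi, F)
    theta: np.ndarray  # (n_aoi, F)
    m: np.ndarray  # (K, n_aoi, F)
    x: np.ndarray  # (K, n_aoi, F)
    y: np.ndarray
    h: np.ndarray
    w: np.ndarray
    b: np.ndarray  # (n_aoi, F)
    config: SimConfig = None

    def to_frame(self):
        """truth as a tidy DataFrame (one row per AOI/frame)."""
        import pandas as pd

        n, F = self.z.shape
        K = self.m.shape[0]
        rows = {
            "aoi": np.repeat(np.arange(n), F),
            "frame": np.tile(np.arange(F), n),
            "z": self.z.ravel(),
            "theta": self.theta.ravel(),
        }
        for k in range(K):
            rows[f"m{k+1}"] = self.m[k].ravel()
            rows[f"x{k+1}"] = self.x[k].ravel()
            rows[f"y{k+1}"] = self.y[k].ravel()
        return pd.DataFrame(rows)


def simulate_kinetic_states(kon: float, koff: float, N: int, F: int, rng) -> np.ndarray:
    """Equilibrium two-state Markov chains of specific binding.

    Initial state ~ Categorical([koff, kon] / (kon + koff)); transitions
    0->1 with probability kon and 1->0 with koff, independent across AOIs.
    """
    if not (0 < kon < 1 and 0 < koff < 1):
        raise ValueError("rates must lie in (0, 1)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    z = np.zeros((N, F), dtype=np.int8)
    z[:, 0] = rng.random(N) < kon / (kon + koff)
    u = rng.random((N, F))
    for f in range(1, F):
        p_next_bound = np.where(z[:, f - 1] == 1, 1.0 - koff, kon)
        z[:, f] = u[:, f] < p_next_bound
    return z


def simulate_dataset(config: SimConfig) -> tuple[AOIDataset, SimTruth]:
    """Sample a full synthetic dataset; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.N + config.Nc
    F, P, K = config.F, config.P, config.K
    is_control = np.concatenate(
        [np.zeros(config.N, dtype=bool), np.ones(config.Nc, dtype=bool)]
    )
    a = mdl.position_bound(P)
    offset = config.offset
    height = config.height

    # target positions jittered inside the central range, constant per AOI
    xt = rng.uniform(P / 2 - 1, P / 2, size=n)[:, None] * np.ones((1, F))
    yt = rng.uniform(P / 2 - 1, P / 2, size=n)[:, None] * np.ones((1, F))

    # specific-binding states
    z = np.zeros((n, F), dtype=np.int8)
    if config.kon is not None:
        z[~is_control] = simulate_kinetic_states(
            config.kon, config.koff, config.N, F, rng
        )
    else:
        z[~is_control] = rng.random((config.N, F)) < config.pi
    theta = np.where(z == 1, rng.integers(1, K + 1, size=(n, F)), 0)

    # spot presence via the truncated-Poisson prior
    r0 = dist.m_prior_rate(True, config.lam, K)
    r1 = dist.m_prior_rate(False, config.lam, K)
    m = np.zeros((K, n, F), dtype=np.int8)
    for k in range(1, K + 1):
        rate = np.where(theta == k, 1.0, np.where(theta == 0, r0, r1))
        m[k - 1] = rng.random((n, F)) < rate

    # positions: AffineBeta around the target for the specific spot, uniform else
    x = rng.uniform(-a, a, size=(K, n, F))
    y = rng.uniform(-a, a, size=(K, n, F))
    for k in range(1, K + 1):
        sel = theta == k
        nsel = int(sel.sum())
        if nsel:
            x[k - 1][sel] = dist.affine_beta_sample(
                rng, 0.0, config.sigma_xy, -a, a, size=nsel
            )
            y[k - 1][sel] = dist.affine_beta_sample(
                rng, 0.0, config.sigma_xy, -a, a, size=nsel
            )

    h = np.full((K, n, F), float(height))
    w = np.full((K, n, F), float(config.w))
    if config.mu_b is not None and config.sigma_b is not None:
        b = dist.gamma_meanvar_sample(
            rng, config.mu_b, config.sigma_b**2, size=(n, F)
        )
    else:
        b = np.full((n, F), float(config.b))

    from ._engine import spot_surfaces

    S, _, _, _ = spot_surfaces(h, w, x, y, xt, yt, P)
    mu_I = b[:, :, None, None] + np.einsum("knf,knfij->nfij", m.astype(float), S)
    I = dist.gamma_meanvar_sample(rng, mu_I, mu_I * config.g)
    delta = offset.sample(rng, size=(n, F, P, P))
    D = I + delta

    dataset = AOIDataset(
        data=D,
        x_target=xt,
        y_target=yt,
        is_control=is_control,
        offset=offset,
        frame_interval=config.frame_interval,
        meta={"sim_config": asdict(config)},
    )
    truth = SimTruth(z=z, theta=theta, m=m, x=x, y=y, h=h, w=w, b=b, config=config)
    return dataset, truth


# ------------------------------------------------------------------- SNR
def _weight_grid(w: float, x: float, y: float, xt: float, yt: float, P: int):
    i = np.arange(P, dtype=float)
    d2 = (i[:, None] - x - xt) ** 2 + (i[None, :] - y - yt) ** 2
    return np.exp(-d2 / (2.0 * w**2)) / (2.0 * math.pi * w**2)


def snr_theoretical(
    h: float, w: float, b: float, g: float, offset: OffsetEmpirical, P: int = 14
) -> float:
    """Theoretical signal-to-noise ratio of a centered specific spot.

    signal = sum_px h * weight^2; noise = sqrt(var_offset + b * g).
    """
    c = (P - 1) / 2.0
    weight = _weight_grid(w, 0.0, 0.0, c, c, P)
    signal = float(h * np.sum(weight**2))
    return signal / math.sqrt(offset.var + b * g)


def height_for_snr(
    snr: float, w: float, b: float, g: float, offset: OffsetEmpirical, P: int = 14
) -> float:
    """Spot intensity h that yields the requested theoretical SNR."""
    return snr / snr_theoretical(1.0, w, b, g, offset, P)


def snr_empirical(dataset: AOIDataset, truth: SimTruth) -> float:
    """Empirical SNR measured from the images at the true spot parameters.

    For every target-specific spot: signal = sum_px (D - mean b - mean
    offset) * weight; the ratio uses the same noise denominator as the
    theoretical form; returns the mean over specific spots.
    """
    which = truth.theta > 0
    if not which.any():
        raise ValueError("no target-specific spots in the truth")
    P = dataset.P
    off_mean = dataset.offset.mean
    noise = math.sqrt(dataset.offset.var + float(np.mean(truth.b)) * truth.config.g)
    vals = []
    for aoi, frame in zip(*np.nonzero(which)):
        k = truth.theta[aoi, frame] - 1
        weight = _weight_grid(
            truth.w[k, aoi, frame],
            truth.x[k, aoi, frame],
            truth.y[k, aoi, frame],
            dataset.x_target[aoi, frame],
            dataset.y_target[aoi, frame],
            P,
        )
        signal = np.sum(
            (dataset.data[aoi, frame] - truth.b[aoi, frame] - off_mean) * weight
        )
        vals.append(signal / noise)
    return float(np.mean(vals))


def posterior_predictive(state, dataset: AOIDataset, n_samples: int = 1, seed: int = 0):
    """Sample image stacks from the fitted posterior predictive distribution.

    Draws continuous latents from the guide, the discrete spot configuration
    from its exact conditional given those latents, and pushes everything
    through the generative model.  Output shape: (n_samples,) + data.shape.
    """
    from ._engine import spot_surfaces
    from .inference import _config_table

    if state.iteration == 0:
        raise ValueError("state is unfitted; run fit() first")
    rng = np.random.default_rng(seed)
    table = _config_table(state)
    out = np.empty((n_samples,) + dataset.data.shape)
    from ._engine import forward_backward

    offset_logw = np.log(dataset.offset.weights)
    for s in range(n_samples):
        vals = state.sample_values(rng)
        res = forward_backward(
            vals,
            dataset.data,
            dataset.x_target,
            dataset.y_target,
            dataset.is_control,
            dataset.offset.samples,
            offset_logw,
            table,
            dataset.P,
            need_grad=False,
        )
        r = res.r_config  # (C, n, F)
        cum = np.cumsum(r, axis=0)
        pick = (rng.random(cum.shape[1:])[None] > cum).sum(axis=0)
        masks = table.masks[table.mask_index[pick]]  # (n, F, K)
        S, _, _, _ = spot_surfaces(
            vals["h"], vals["w"], vals["x"], vals["y"],
            dataset.x_target, dataset.y_target, dataset.P,
        )
        mu_I = vals["b"][:, :, None, None] + np.einsum(
            "nfk,knfij->nfij", masks, S
        )
        I = dist.gamma_meanvar_sample(rng, mu_I, mu_I * float(vals["g"]))
        delta = dataset.offset.sample(rng, size=mu_I.shape)
        out[s] = I + delta
    return out
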