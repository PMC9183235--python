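"""Variational posterior approximation and spot probabilities.

`fit` optimizes a factorized variational distribution over all continuous
latents by mini-batch stochastic gradient ascent on the ELBO (the discrete
latents and the camera offset are enumerated exactly inside the objective).
`spot_probabilities` then draws Monte-Carlo samples of the continuous
latents from the fitted guide and, for each sample, computes the *exact*
conditional p(z, theta | phi', D) by enumeration, averaging the results
into p(specific), p(theta) and p(m) matrices.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import model as mdl
from ._engine import (
    AdamState,
    ConfigTable,
    Transform,
    adam_update,
    forward_backward,
    global_prior_and_grads,
    LOG_2PI_E,
)
from .aoi_io import AOIDataset

__all__ = [
    "FitConfig",
    "VariationalState",
    "PosteriorResult",
    "init_guide",
    "elbo_step",
    "fit",
    "spot_probabilities",
    "hdr_interval",
    "save_checkpoint",
    "load_checkpoint",
]

GLOBAL_NAMES = ("g", "sigma_xy", "pi", "lam")
AOI_NAMES = ("mu_b", "sigma_b")
LOCAL_NAMES = ("b", "h", "w", "x", "y")


@dataclass
class FitConfig:
    """Settings of the stochastic variational fit."""

    learning_rate: float = 5e-3
    final_learning_rate: float | None = None  # geometric decay when set
    local_lr_scale: float = 1.0  # multiplier for per-frame/per-spot factors
    batch_aoi: int | None = None  # default min(n_aoi, 10)
    batch_frame: int | None = None  # default min(F, 500)
    max_iterations: int = 20000
    convergence_window: int = 200
    elbo_tolerance: float = 1e-4
    param_tolerance: float = 1e-3
    mc_samples: int = 25  # S, for spot probabilities
    grad_samples: int = 1  # reparameterized samples per gradient step
    K: int = 2
    seed: int = 0
    checkpoint_path: str | None = None
    checkpoint_every: int = 1000

    def __post_init__(self):
        if self.learning_rate <= 0 or self.max_iterations < 1 or self.mc_samples < 1:
            raise ValueError("FitConfig values must be positive")


@dataclass
class VariationalState:
    """All variational parameters plus optimizer and RNG state."""

    loc: dict
    log_scale: dict
    transforms: dict
    adam: AdamState
    config: FitConfig
    iteration: int = 0
    elbo_trace: list = field(default_factory=list)
    globals_history: list = field(default_factory=list)
    rng: np.random.Generator = None
    n_aoi: int = 0
    F: int = 0

    def values_mean(self, names=None) -> dict:
        """Posterior-median point values (transform of the location)."""
        names = names or list(self.loc)
        return {n: self.transforms[n].forward(self.loc[n]) for n in names}

    def sample_values(self, rng, names=None) -> dict:
        names = names or list(self.loc)
        out = {}
        for n in names:
            u = self.loc[n] + np.exp(self.log_scale[n]) * rng.standard_normal(
                np.shape(self.loc[n])
            )
            out[n] = self.transforms[n].forward(u)
        return out


@dataclass
class PosteriorResult:
    """Fitted posterior summaries and spot-probability matrices."""

    p_specific: np.ndarray  # (n_aoi, F)
    p_theta: np.ndarray  # (n_aoi, F, K+1)
    p_m: np.ndarray  # (K, n_aoi, F)
    params_mean: dict
    params_hdr: dict  # name -> (low, high) arrays
    elbo_trace: list
    converged: bool
    iterations: int

    def summary_frame(self):
        """Global-parameter summary as a pandas DataFrame."""
        import pandas as pd

        rows = []
        for name in GLOBAL_NAMES:
            lo, hi = self.params_hdr[name]
            rows.append(
                {
                    "parameter": name,
                    "mean": float(self.params_mean[name]),
                    "hdr95_low": float(lo),
                    "hdr95_high": float(hi),
                }
            )
        return pd.DataFrame(rows)


def _latent_transforms(dataset: AOIDataset, K: int) -> dict:
    P = dataset.P
    a = mdl.position_bound(P)
    tr = {
        "g": Transform("log"),
        "sigma_xy": Transform("interval", 0.0, mdl.sigma_xy_max(P)),
        "pi": Transform("interval", 0.0, 1.0),
        "lam": Transform("log"),
        "mu_b": Transform("log"),
        "sigma_b": Transform("log"),
        "b": Transform("log"),
        "h": Transform("log"),
        "w": Transform("interval", mdl.W_MIN, mdl.W_MAX),
        "x": Transform("interval", -a, a),
        "y": Transform("interval", -a, a),
    }
    return tr


def _peak_positions(data, x_target, y_target, P, K, a, w0: float = 1.4):
    """Matching-pursuit initial spot positions and intensities.

    Per AOI/frame: locate the brightest residual pixel, estimate that
    spot's integrated intensity from the peak height, subtract its
    Gaussian surface, and repeat — so overlapping spots start from
    distinct locations instead of collapsing onto the same blob.
    """
    n, F = data.shape[:2]
    res = data - np.median(data, axis=(2, 3), keepdims=True)
    noise = 1.4826 * np.median(np.abs(res), axis=(2, 3))  # robust pixel sd
    grid = np.arange(P, dtype=float)
    xs = np.empty((K, n, F))
    ys = np.empty((K, n, F))
    hs = np.empty((K, n, F))
    strong = np.empty((K, n, F), dtype=bool)
    for k in range(K):
        flat = res.reshape(n, F, P * P)
        idx = flat.argmax(axis=2)
        peak = np.take_along_axis(flat, idx[..., None], axis=2)[..., 0]
        i_pk, j_pk = (idx // P).astype(float), (idx % P).astype(float)
        hs[k] = np.clip(peak, 10.0, None) * 2.0 * math.pi * w0**2
        strong[k] = peak > 4.0 * noise
        xs[k] = np.clip(i_pk - x_target, -a + 0.5, a - 0.5)
        ys[k] = np.clip(j_pk - y_target, -a + 0.5, a - 0.5)
        if k + 1 < K:
            d2 = (grid[None, None, :, None] - i_pk[..., None, None]) ** 2 + (
                grid[None, None, None, :] - j_pk[..., None, None]
            ) ** 2
            res = res - np.clip(peak, 0.0, None)[..., None, None] * np.exp(
                -d2 / (2.0 * w0**2)
            )
    return xs, ys, hs, strong


def init_guide(dataset: AOIDataset, config: FitConfig) -> VariationalState:
    """Deterministic, data-informed initialization of the guide.

    Background factors start at the per-frame median intensity minus the
    offset mean; spot intensity at (max - median) * 2 pi w^2 with w = 1.5;
    spot positions at the brightest residual pixels of each frame.
    """
    K, P = config.K, dataset.P
    n, F = dataset.n_aoi, dataset.F
    a = mdl.position_bound(P)
    tr = _latent_transforms(dataset, K)
    off_mean = dataset.offset.mean

    med = np.median(dataset.data, axis=(2, 3))
    b0 = np.clip(med - off_mean, 1.0, None)
    x0, y0, h0, _strong = _peak_positions(
        dataset.data, dataset.x_target, dataset.y_target, P, K, a
    )
    h0 = np.clip(h0, 50.0, None)

    loc = {
        "g": tr["g"].inverse(5.0),
        "sigma_xy": tr["sigma_xy"].inverse(0.5),
        "pi": tr["pi"].inverse(0.5),
        "lam": tr["lam"].inverse(0.5),
        "mu_b": tr["mu_b"].inverse(np.clip(b0.mean(axis=1), 1.0, None)),
        "sigma_b": tr["sigma_b"].inverse(np.clip(b0.std(axis=1), 1.0, None)),
        "b": tr["b"].inverse(b0),
        "h": tr["h"].inverse(h0),
        "w": tr["w"].inverse(np.full((K, n, F), 1.4)),
        "x": tr["x"].inverse(x0),
        "y": tr["y"].inverse(y0),
    }
    loc = {k: np.asarray(v, dtype=float) for k, v in loc.items()}
    scale0 = {
        "g": 0.1,
        "sigma_xy": 0.3,
        "pi": 0.3,
        "lam": 0.3,
        "mu_b": 0.1,
        "sigma_b": 0.2,
        "b": 0.1,
        "h": 0.3,
        "w": 0.3,
        "x": 0.3,
        "y": 0.3,
    }
    log_scale = {k: np.full(np.shape(loc[k]), math.log(scale0[k])) for k in loc}
    params = {}
    for name in loc:
        params[f"loc:{name}"] = loc[name]
        params[f"ls:{name}"] = log_scale[name]
    return VariationalState(
        loc=loc,
        log_scale=log_scale,
        transforms=tr,
        adam=AdamState.for_params(params),
        config=config,
        rng=np.random.default_rng(config.seed),
        n_aoi=n,
        F=F,
    )


def _index_for(name, idx_n, idx_f):
    """Mini-batch slice of a latent array, by latent kind."""
    if name in GLOBAL_NAMES:
        return None
    if name in AOI_NAMES:
        return (idx_n,)
    return (Ellipsis, idx_n[:, None], idx_f[None, :])


def elbo_step(state: VariationalState, dataset: AOIDataset, idx_n=None, idx_f=None):
    """One stochastic gradient update of all variational parameters.

    Returns ``(state, elbo_estimate)``.  z, theta (and the offset bins) are
    enumerated exactly inside the ELBO; gradients of the continuous latents
    are reparameterized.  Raises on a non-finite ELBO, naming the worst
    AOI/frame of the mini-batch.
    """
    cfg = state.config
    n, F = state.n_aoi, state.F
    rng = state.rng
    bn = cfg.batch_aoi or min(n, 10)
    bf = cfg.batch_frame or min(F, 500)
    if idx_n is None:
        idx_n = np.sort(rng.choice(n, size=bn, replace=False))
    else:
        idx_n = np.asarray(idx_n)
    if idx_f is None:
        idx_f = np.sort(rng.choice(F, size=bf, replace=False))
    else:
        idx_f = np.asarray(idx_f)
    bn, bf = len(idx_n), len(idx_f)
    scale_nf = (n * F) / (bn * bf)
    scale_f = F / bf
    scale_n = n / bn

    D = dataset.data[idx_n[:, None], idx_f[None, :]]
    xt = dataset.x_target[idx_n[:, None], idx_f[None, :]]
    yt = dataset.y_target[idx_n[:, None], idx_f[None, :]]
    is_ctrl = dataset.is_control[idx_n]
    table = _config_table(state)
    offset_logw = np.log(dataset.offset.weights)

    grad_loc = {k: 0.0 for k in state.loc}
    grad_ls = {k: 0.0 for k in state.loc}
    elbo_acc = 0.0
    Sg = cfg.grad_samples
    for _ in range(Sg):
        u, eps, vals, logJ, dlogJ, dvdu = {}, {}, {}, {}, {}, {}
        for name in state.loc:
            sl = _index_for(name, idx_n, idx_f)
            loc = state.loc[name] if sl is None else state.loc[name][sl]
            ls = state.log_scale[name] if sl is None else state.log_scale[name][sl]
            e = rng.standard_normal(np.shape(loc))
            uu = loc + np.exp(ls) * e
            t = state.transforms[name]
            u[name], eps[name] = uu, e
            vals[name] = t.forward(uu)
            logJ[name] = t.log_jac(uu)
            dlogJ[name] = t.dlog_jac_du(uu)
            dvdu[name] = t.dv_du(uu, vals[name])

        res = forward_backward(
            vals,
            D,
            xt,
            yt,
            is_ctrl,
            dataset.offset.samples,
            offset_logw,
            table,
            dataset.P,
            need_grad=True,
        )
        lp_glob, g_glob = global_prior_and_grads(vals)
        if not np.isfinite(res.logp_local):
            worst = np.unravel_index(np.argmin(res.log_marginal), res.log_marginal.shape)
            raise FloatingPointError(
                f"non-finite ELBO at iteration {state.iteration}; worst AOI "
                f"{idx_n[worst[0]]}, frame {idx_f[worst[1]]}"
            )

        # ELBO estimate (for the trace): global + scaled per-AOI + scaled frame terms
        ent = lambda name: float(
            np.sum(
                (state.log_scale[name] if _index_for(name, idx_n, idx_f) is None
                 else state.log_scale[name][_index_for(name, idx_n, idx_f)])
                + 0.5 * LOG_2PI_E
            )
        )
        elbo = 0.0
        for name in GLOBAL_NAMES:
            elbo += float(np.sum(logJ[name])) + ent(name)
        for name in AOI_NAMES:
            elbo += scale_n * (float(np.sum(logJ[name])) + ent(name))
        for name in LOCAL_NAMES:
            elbo += scale_nf * (float(np.sum(logJ[name])) + ent(name))
        elbo += lp_glob + scale_nf * res.logp_local
        # mu_b/sigma_b hyperpriors are inside lp_glob (unscaled batch sum): rescale
        elbo_acc += elbo

        for name in state.loc:
            if name in GLOBAL_NAMES:
                gv = g_glob[name] + scale_nf * res.grads[name]
            elif name in AOI_NAMES:
                gv = g_glob[name] + scale_f * res.grads[name]
            else:
                gv = res.grads[name]
            gu = gv * dvdu[name] + dlogJ[name]
            grad_loc[name] = grad_loc[name] + gu
            grad_ls[name] = grad_ls[name] + gu * np.exp(
                state.log_scale[name] if _index_for(name, idx_n, idx_f) is None
                else state.log_scale[name][_index_for(name, idx_n, idx_f)]
            ) * eps[name] + 1.0

    lr = cfg.learning_rate
    if cfg.final_learning_rate is not None:
        frac = min(state.iteration / max(cfg.max_iterations - 1, 1), 1.0)
        lr = lr * (cfg.final_learning_rate / lr) ** frac
    for name in state.loc:
        sl = _index_for(name, idx_n, idx_f)
        lr_name = lr * cfg.local_lr_scale if name in LOCAL_NAMES else lr
        gl = np.clip(grad_loc[name] / Sg, -1e6, 1e6)
        gs = np.clip(grad_ls[name] / Sg, -1e6, 1e6)
        adam_update(state.adam, f"loc:{name}", state.loc[name], gl, lr_name, idx=sl)
        adam_update(state.adam, f"ls:{name}", state.log_scale[name], gs, lr_name, idx=sl)

    state.iteration += 1
    elbo_val = elbo_acc / Sg
    state.elbo_trace.append(elbo_val)
    state.globals_history.append(
        [float(state.transforms[k].forward(state.loc[k])) for k in GLOBAL_NAMES]
    )
    return state, elbo_val


_TABLE_CACHE: dict = {}


def _config_table(state: VariationalState) -> ConfigTable:
    K = state.config.K
    if K not in _TABLE_CACHE:
        _TABLE_CACHE[K] = ConfigTable.build(K)
    return _TABLE_CACHE[K]


def _converged(state: VariationalState) -> bool:
    W = state.config.convergence_window
    tr = state.elbo_trace
    if len(tr) < 2 * W:
        return False
    recent = float(np.mean(tr[-W:]))
    prev = float(np.mean(tr[-2 * W : -W]))
    if abs(recent - prev) / (abs(prev) + 1.0) >= state.config.elbo_tolerance:
        return False
    gh = np.asarray(state.globals_history[-2 * W :])
    now, before = gh[-1], gh[0]
    rel = np.abs(now - before) / (np.abs(before) + 1e-8)
    return bool(np.all(rel < state.config.param_tolerance))


def fit(
    dataset: AOIDataset,
    config: FitConfig | None = None,
    resume_from=None,
    progress: bool = False,
):
    """Fit the variational posterior; returns (state, PosteriorResult).

    Iterates :func:`elbo_step` until the smoothed ELBO and the global
    posterior means are stable over the convergence window, or the
    iteration budget is exhausted.  Periodically checkpoints (resumable via
    ``resume_from``) when ``config.checkpoint_path`` is set.
    """
    config = config or FitConfig()
    dataset.validate_offset()
    if resume_from is not None:
        state = load_checkpoint(resume_from)
    else:
        state = init_guide(dataset, config)
    while state.iteration < config.max_iterations:
        state, elbo = elbo_step(state, dataset)
        if progress and state.iteration % 100 == 0:
            print(f"iter {state.iteration}: elbo {elbo:.4g}")
        if config.checkpoint_path and state.iteration % config.checkpoint_every == 0:
            save_checkpoint(state, config.checkpoint_path)
        if state.iteration % config.convergence_window == 0 and _converged(state):
            break
    converged = _converged(state)
    if config.checkpoint_path:
        save_checkpoint(state, config.checkpoint_path)
    result = spot_probabilities(state, dataset, S=config.mc_samples)
    result.converged = converged
    result.iterations = state.iteration
    return state, result


def spot_probabilities(
    state: VariationalState, dataset: AOIDataset, S: int = 25
) -> PosteriorResult:
    """Monte-Carlo marginal posterior probabilities of the discrete latents.

    Draws ``S`` joint samples of the continuous latents from the guide and
    averages the exact enumerated conditionals p(z, theta | phi', D);
    p(specific) = p(z=1 | D).  Control AOIs have p(specific) = 0 by
    construction.  Uses a dedicated random stream so results do not depend
    on where the optimizer stopped.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    cfg = state.config
    K = cfg.K
    n, F = state.n_aoi, state.F
    table = _config_table(state)
    rng = np.random.default_rng((cfg.seed + 1_000_003) % (2**31))
    offset_logw = np.log(dataset.offset.weights)

    p_zt = np.zeros((table.n_configs, n, F))
    chunk = max(1, int(5e6 // (F * dataset.P**2 * 4)))
    for _ in range(S):
        vals_full = state.sample_values(rng)
        for a0 in range(0, n, chunk):
            sl = slice(a0, min(n, a0 + chunk))
            vals = {}
            for name in state.loc:
                if name in GLOBAL_NAMES:
                    vals[name] = vals_full[name]
                elif name in AOI_NAMES:
                    vals[name] = vals_full[name][sl]
                else:
                    vals[name] = vals_full[name][..., sl, :]
            res = forward_backward(
                vals,
                dataset.data[sl],
                dataset.x_target[sl],
                dataset.y_target[sl],
                dataset.is_control[sl],
                dataset.offset.samples,
                offset_logw,
                table,
                dataset.P,
                need_grad=False,
            )
            p_zt[:, sl] += res.r_config
    p_zt /= S

    p_theta = np.zeros((n, F, K + 1))
    for t in range(K + 1):
        p_theta[:, :, t] = p_zt[table.theta == t].sum(axis=0)
    p_specific = p_theta[:, :, 1:].sum(axis=2)
    p_m = np.zeros((K, n, F))
    for k in range(K):
        on = table.masks[table.mask_index, k] > 0
        p_m[k] = p_zt[on].sum(axis=0)

    params_mean, params_hdr = _posterior_summaries(state, rng)
    return PosteriorResult(
        p_specific=p_specific,
        p_theta=p_theta,
        p_m=p_m,
        params_mean=params_mean,
        params_hdr=params_hdr,
        elbo_trace=list(state.elbo_trace),
        converged=False,
        iterations=state.iteration,
    )


def _posterior_summaries(state: VariationalState, rng, n_draws: int = 500):
    """Posterior mean and 95% HDR per latent via guide sampling."""
    params_mean, params_hdr = {}, {}
    for name in state.loc:
        nd = n_draws if name in GLOBAL_NAMES + AOI_NAMES else 100
        shape = np.shape(state.loc[name])
        draws = state.loc[name][None] + np.exp(state.log_scale[name])[None] * (
            rng.standard_normal((nd,) + shape)
        )
        v = state.transforms[name].forward(draws)
        params_mean[name] = v.mean(axis=0)[()]
        params_hdr[name] = hdr_interval_nd(v, 0.95, axis=0)
    return params_mean, params_hdr


def hdr_interval(samples, mass: float = 0.95):
    """Narrowest contiguous interval holding ``ceil(mass * n)`` samples.

    Ties break to the leftmost minimal window.  Requires >= 20 samples.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    nsmp = x.size
    if nsmp < 20:
        raise ValueError("hdr_interval requires at least 20 samples")
    m = int(math.ceil(mass * nsmp))
    widths = x[m - 1 :] - x[: nsmp - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def hdr_interval_nd(samples, mass: float = 0.95, axis: int = 0):
    """Vectorized HDR along one axis; returns (low, high) arrays."""
    x = np.sort(np.moveaxis(np.asarray(samples, dtype=float), axis, 0), axis=0)
    nsmp = x.shape[0]
    m = int(math.ceil(mass * nsmp))
    widths = x[m - 1 :] - x[: nsmp - m + 1]
    i = np.argmin(widths, axis=0)
    low = np.take_along_axis(x, i[None], axis=0)[0]
    high = np.take_along_axis(x, (i + m - 1)[None], axis=0)[0]
    return low[()], high[()]


# ----------------------------------------------------------- checkpointing
def save_checkpoint(state: VariationalState, path) -> None:
    """Persist the full state (resume gives bit-identical continuation)."""
    path = Path(path)
    arrays = {}
    for name in state.loc:
        arrays[f"loc__{name}"] = state.loc[name]
        arrays[f"ls__{name}"] = state.log_scale[name]
    for key in state.adam.m:
        safe = key.replace(":", "_")
        arrays[f"adam_m__{safe}"] = state.adam.m[key]
        arrays[f"adam_v__{safe}"] = state.adam.v[key]
        arrays[f"adam_t__{safe}"] = state.adam.t[key]
    meta = {
        "config": asdict(state.config),
        "iteration": state.iteration,
        "elbo_trace": state.elbo_trace,
        "globals_history": state.globals_history,
        "rng_state": state.rng.bit_generator.state,
        "n_aoi": state.n_aoi,
        "F": state.F,
        "transforms": {
            k: [t.kind, t.lo, t.hi] for k, t in state.transforms.items()
        },
    }
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path) -> VariationalState:
    path = Path(path)
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        loc, log_scale = {}, {}
        adam = AdamState()
        for key in data.files:
            if key.startswith("loc__"):
                loc[key[5:]] = data[key]
            elif key.startswith("ls__"):
                log_scale[key[4:]] = data[key]
            elif key.startswith("adam_m__"):
                adam.m[key[8:].replace("_", ":", 1)] = data[key]
            elif key.startswith("adam_v__"):
                adam.v[key[8:].replace("_", ":", 1)] = data[key]
            elif key.startswith("adam_t__"):
                adam.t[key[8:].replace("_", ":", 1)] = data[key]
    config = FitConfig(**meta["config"])
    transforms = {
        k: Transform(kind, lo, hi) for k, (kind, lo, hi) in meta["transforms"].items()
    }
    rng = np.random.default_rng(config.seed)
    rng.bit_generator.state = meta["rng_state"]
    state = VariationalState(
        loc=loc,
        log_scale=log_scale,
        transforms=transforms,
        adam=adam,
        config=config,
        iteration=meta["iteration"],
        elbo_trace=list(meta["elbo_trace"]),
        globals_history=[list(v) for v in meta["globals_history"]],
        rng=rng,
        n_aoi=meta["n_aoi"],
        F=meta["F"],
    )
    return state
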