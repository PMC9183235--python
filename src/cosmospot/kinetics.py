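"""Kinetic and thermodynamic constants from p(specific) time records.

Instead of thresholding, binary time records are resampled from the
per-frame posterior probabilities; each replicate is fit by a two-state
Markov-chain maximum likelihood (including the equilibrium initial-state
term), and the replicate distribution yields means and 95% highest-density
credible intervals.  The same resampling drives time-to-first-binding
analysis with a two-population model (an active fraction Af binding at
rate ka + kns, the rest at the nonspecific rate kns) fit with censoring.
Keq = pi / (1 - pi) maps posterior samples of the specific-binding
probability to the equilibrium constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

__all__ = [
    "BinaryTraceSet",
    "KineticEstimate",
    "sample_traces",
    "hmm_mle",
    "estimate_rates",
    "keq_from_pi",
    "time_to_first_binding",
    "dwell_intervals",
]


@dataclass
class BinaryTraceSet:
    """Bernoulli resamples of p(specific): (n_samples, n_aoi, F) in {0,1}."""

    traces: np.ndarray
    seed: int
    frame_interval: float = 1.0

    @property
    def n_samples(self) -> int:
        return self.traces.shape[0]


@dataclass
class Estimate:
    mean: float
    ci_low: float
    ci_high: float
    flag: str | None = None

    def as_tuple(self):
        return self.mean, self.ci_low, self.ci_high


@dataclass
class KineticEstimate:
    """Rate/equilibrium constants with 95% credible intervals."""

    kon: Estimate | None = None
    koff: Estimate | None = None
    keq: Estimate | None = None
    ka: Estimate | None = None
    kns: Estimate | None = None
    af: Estimate | None = None
    dt_on: list = field(default_factory=list)  # pooled bound-interval lengths
    dt_off: list = field(default_factory=list)


def sample_traces(p_specific, n_samples: int = 2000, seed: int = 0,
                  frame_interval: float = 1.0) -> BinaryTraceSet:
    """Independent Bernoulli draws per AOI/frame cell, per replicate."""
    p = np.asarray(p_specific, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p(specific) must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    traces = (rng.random((n_samples,) + p.shape) < p[None]).astype(np.int8)
    return BinaryTraceSet(traces=traces, seed=seed, frame_interval=frame_interval)


def _chain_counts(traces: np.ndarray):
    """Sufficient statistics of 2-state chains: initial and transition counts."""
    t0 = traces[..., 0]
    prev, nxt = traces[..., :-1], traces[..., 1:]
    n01 = int(np.sum((prev == 0) & (nxt == 1)))
    n00 = int(np.sum((prev == 0) & (nxt == 0)))
    n10 = int(np.sum((prev == 1) & (nxt == 0)))
    n11 = int(np.sum((prev == 1) & (nxt == 1)))
    c1 = int(np.sum(t0 == 1))
    c0 = int(t0.size - c1)
    return c0, c1, n00, n01, n10, n11


def _chain_negloglik(params, counts):
    """Negative log-likelihood of (kon, koff) in log-odds space."""
    c0, c1, n00, n01, n10, n11 = counts
    kon = float(np.clip(special.expit(params[0]), 1e-12, 1 - 1e-12))
    koff = float(np.clip(special.expit(params[1]), 1e-12, 1 - 1e-12))
    s = kon + koff
    ll = (
        c1 * math.log(kon / s)
        + c0 * math.log(koff / s)
        + n01 * math.log(kon)
        + n00 * math.log1p(-kon)
        + n10 * math.log(koff)
        + n11 * math.log1p(-koff)
    )
    return -ll


def hmm_mle(traces) -> tuple[float, float, str | None]:
    """Maximum-likelihood (kon, koff) of observed two-state binary chains.

    Maximizes the product over AOIs of the chain likelihood including the
    equilibrium initial-state term; the transition-count estimator
    (n01/n0., n10/n1.) seeds the search.  Degenerate data (a state never
    visited, or no transitions out of a visited state) yields a boundary
    estimate with a flag.
    """
    traces = np.atleast_2d(np.asarray(traces))
    if traces.size == 0:
        raise ValueError("no traces given")
    counts = _chain_counts(traces)
    c0, c1, n00, n01, n10, n11 = counts
    flag = None
    if n01 + n00 == 0 or (n01 == 0 and c1 == 0):
        # never in state 0 with a continuation, or no binding events at all
        flag = "kon-unidentifiable"
    if n10 + n11 == 0 or (n10 == 0 and c1 == 0 and n11 == 0):
        flag = (flag + ";" if flag else "") + "koff-unidentifiable"
    kon0 = (n01 + 0.5) / (n01 + n00 + 1.0)
    koff0 = (n10 + 0.5) / (n10 + n11 + 1.0)
    if flag is not None:
        kon_b = n01 / (n01 + n00) if (n01 + n00) else 0.0
        koff_b = n10 / (n10 + n11) if (n10 + n11) else float("nan")
        return float(kon_b), float(koff_b), flag
    x0 = special.logit(np.clip([kon0, koff0], 1e-6, 1 - 1e-6))
    res = optimize.minimize(_chain_negloglik, x0, args=(counts,), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10})
    kon, koff = special.expit(res.x)
    return float(kon), float(koff), None


def estimate_rates(trace_set: BinaryTraceSet) -> KineticEstimate:
    """Per-replicate chain MLEs aggregated into means and 95% HDR intervals."""
    kons, koffs = [], []
    flags = 0
    for s in range(trace_set.n_samples):
        kon, koff, flag = hmm_mle(trace_set.traces[s])
        if flag is not None:
            flags += 1
            continue
        kons.append(kon)
        koffs.append(koff)
    if not kons:
        raise ValueError("all replicates degenerate; no transitions observed")
    dt = trace_set.frame_interval
    kons = np.asarray(kons) / dt
    koffs = np.asarray(koffs) / dt
    est = KineticEstimate(
        kon=_estimate(kons, flag=f"{flags} degenerate replicates" if flags else None),
        koff=_estimate(koffs),
    )
    don, doff = dwell_intervals(trace_set.traces[0])
    est.dt_on = [d * dt for d in don]
    est.dt_off = [d * dt for d in doff]
    return est


def _estimate(samples: np.ndarray, flag=None) -> Estimate:
    if samples.size >= 20:
        lo, hi = _hdr(samples)
    else:
        lo = hi = float(np.mean(samples))
    return Estimate(mean=float(np.mean(samples)), ci_low=lo, ci_high=hi, flag=flag)


def _hdr(samples, mass=0.95):
    from .inference import hdr_interval

    if np.ptp(samples) == 0:
        return float(samples[0]), float(samples[0])
    return hdr_interval(samples, mass)


def dwell_intervals(traces) -> tuple[list, list]:
    """Complete bound (dt_on) and unbound (dt_off) interval lengths, pooled
    over AOIs; intervals touching the record ends are discarded."""
    traces = np.atleast_2d(np.asarray(traces))
    don, doff = [], []
    for row in traces:
        edges = np.flatnonzero(np.diff(row)) + 1
        if edges.size < 2:
            continue
        for a, b in zip(edges[:-1], edges[1:]):
            (don if row[a] == 1 else doff).append(int(b - a))
    return don, doff


def keq_from_pi(pi_samples) -> Estimate:
    """Equilibrium constant Keq = pi / (1 - pi) from posterior pi samples."""
    pi = np.asarray(pi_samples, dtype=float)
    if np.any(pi < 0) or np.any(pi >= 1):
        raise ValueError("pi samples must lie in [0, 1)")
    keq = pi / (1.0 - pi)
    return _estimate(keq)


# ------------------------------------------------- time-to-first-binding
def _first_event_frames(traces: np.ndarray):
    """Per AOI: frame index of the first bound frame, or F if censored."""
    n, F = traces.shape
    has = traces.any(axis=1)
    first = np.where(has, traces.argmax(axis=1), F)
    return first, F


def _ttfb_negloglik(params, first, F, dt, first_off=None, F_off=None):
    """Interval-censored two-population first-binding likelihood.

    Survival S(t) = Af * exp(-(ka+kns) t) + (1-Af) * exp(-kns t); an event
    at frame k has probability S(k dt) - S((k+1) dt); AOIs with no event
    contribute S(F dt).  Optional off-target AOIs bind only nonspecifically
    (Af = 0).
    """
    af = float(np.clip(special.expit(params[0]), 1e-9, 1 - 1e-9))
    ka = float(np.exp(np.clip(params[1], -40.0, 10.0)))
    kns = float(np.exp(np.clip(params[2], -40.0, 10.0)))

    def surv(t):
        return af * np.exp(-(ka + kns) * t) + (1.0 - af) * np.exp(-kns * t)

    ll = 0.0
    event = first < F
    t = first[event] * dt
    pk = surv(t) - surv(t + dt)
    ll += float(np.sum(np.log(np.clip(pk, 1e-300, None))))
    ncens = int(np.sum(~event))
    if ncens:
        ll += ncens * math.log(max(surv(F * dt), 1e-300))
    if first_off is not None and first_off.size:
        ev = first_off < F_off
        toff = first_off[ev] * dt
        pko = np.exp(-kns * toff) - np.exp(-kns * (toff + dt))
        ll += float(np.sum(np.log(np.clip(pko, 1e-300, None))))
        nco = int(np.sum(~ev))
        if nco:
            ll += nco * (-kns * F_off * dt)
    return -ll


def time_to_first_binding(
    trace_set: BinaryTraceSet,
    frame_interval: float | None = None,
    off_target_traces: np.ndarray | None = None,
    max_replicates: int | None = None,
) -> tuple[KineticEstimate, dict]:
    """Fit the first-binding model to initial absent intervals.

    For each trace replicate the initial binder-absent interval per AOI is
    measured (AOIs with no event censored at F) and the two-population
    model — fraction bound by time t equal to Af(1 - e^-(ka+kns) t) +
    (1 - Af)(1 - e^-kns t) — is fit by censored maximum likelihood.
    Returns the aggregated estimates and the mean empirical survival data.
    """
    dt = frame_interval or trace_set.frame_interval
    S = trace_set.n_samples if max_replicates is None else min(
        trace_set.n_samples, max_replicates
    )
    afs, kas, knss = [], [], []
    F = trace_set.traces.shape[2]
    cum_bound = np.zeros(F + 1)
    total_events = 0
    for s in range(S):
        first, _ = _first_event_frames(trace_set.traces[s])
        total_events += int(np.sum(first < F))
        first_off = None
        F_off = None
        if off_target_traces is not None:
            off = np.atleast_2d(off_target_traces if off_target_traces.ndim <= 2
                                else off_target_traces[s])
            first_off, F_off = _first_event_frames(off)
        # start from the physically expected regime: most targets active,
        # nonspecific association much slower than specific
        x0 = np.array([2.0, math.log(0.05), math.log(0.001)])
        res = optimize.minimize(
            _ttfb_negloglik, x0, args=(first, F, dt, first_off, F_off),
            method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
        )
        afs.append(float(special.expit(res.x[0])))
        kas.append(float(np.exp(np.clip(res.x[1], -40.0, 10.0))))
        knss.append(float(np.exp(np.clip(res.x[2], -40.0, 10.0))))
        cum_bound += np.concatenate([[0.0], np.cumsum(np.bincount(first, minlength=F + 1)[:F])]) / first.size
    cum_bound /= S

    est = KineticEstimate(
        ka=_estimate(np.asarray(kas)),
        kns=_estimate(np.asarray(knss)),
        af=_estimate(np.asarray(afs), flag="no-events" if total_events == 0 else None),
    )
    if total_events == 0:
        est.af = Estimate(0.0, 0.0, 0.0, flag="no-events")
    curve = {
        "time": np.arange(F + 1) * dt,
        "fraction_bound": cum_bound,
    }
    return est, curve
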