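"""Binary classification accuracy against ground truth, and rastergrams.

Predictions are obtained by thresholding p(specific) (strictly greater
than the threshold, default 0.5).  Accuracy is summarized by recall,
precision and the Matthews correlation coefficient; metrics with a zero
denominator are reported as NaN ("undefined"), never as 0.  By default the
confusion counts cover on-target AOI x frame cells only — control AOIs
have p(specific) clamped to 0 and truth identically 0, so including them
would only inflate the true-negative count (switchable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "classify",
    "confusion",
    "metrics",
    "first_binding_frame",
    "rastergram",
]


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricReport:
    recall: float
    precision: float
    mcc: float
    threshold: float = 0.5


def classify(p_specific, threshold: float = 0.5) -> np.ndarray:
    """Binary prediction: 1 where p > threshold (strict; p == threshold -> 0)."""
    p = np.asarray(p_specific, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p(specific) values must lie in [0, 1]")
    return (p > threshold).astype(np.int8)


def confusion(pred, truth) -> ConfusionCounts:
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes differ")
    return ConfusionCounts(
        TP=int(np.sum(pred & truth)),
        TN=int(np.sum(~pred & ~truth)),
        FP=int(np.sum(pred & ~truth)),
        FN=int(np.sum(~pred & truth)),
    )


def metrics(pred, truth, threshold: float = 0.5) -> MetricReport:
    """Recall, precision and MCC of a binary prediction.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    c = confusion(pred, truth)
    recall = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else float("nan")
    precision = c.TP / (c.TP + c.FP) if (c.TP + c.FP) else float("nan")
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    mcc = (
        (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom) if denom else float("nan")
    )
    return MetricReport(recall=recall, precision=precision, mcc=mcc, threshold=threshold)


def first_binding_frame(p_specific, threshold: float = 0.5) -> np.ndarray:
    """Index of the first frame with p > threshold per AOI (F if none)."""
    pred = classify(p_specific, threshold)
    n, F = pred.shape
    has = pred.any(axis=1)
    first = np.where(has, pred.argmax(axis=1), F)
    return first


def rastergram(
    p_specific,
    ordering: str = "time-to-first-binding",
    frame_step: int = 1,
    ax=None,
):
    """Probabilistic rastergram: one row per AOI, color = p(specific).

    AOIs are ordered by decreasing time-to-first-binding (the frame where
    p(specific) first exceeds 0.5).  Returns ``(fig, order)``.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    p = np.asarray(p_specific, dtype=float)
    if ordering == "time-to-first-binding":
        order = np.argsort(-first_binding_frame(p), kind="stable")
    elif ordering == "none":
        order = np.arange(p.shape[0])
    else:
        raise ValueError(f"unknown ordering {ordering!r}")
    img = p[order, ::frame_step]
    if ax is None:
        fig, ax = plt.subplots(figsize=(8, 4))
    else:
        fig = ax.figure
    im = ax.imshow(img, aspect="auto", vmin=0.0, vmax=1.0, cmap="viridis",
                   interpolation="nearest")
    ax.set_xlabel("frame" + (f" (step {frame_step})" if frame_step > 1 else ""))
    ax.set_ylabel("AOI (ordered by time to first binding)")
    fig.colorbar(im, ax=ax, label="p(specific)")
    return fig, order
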