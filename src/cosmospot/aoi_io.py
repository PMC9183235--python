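"""Reading raw image stacks and building the canonical AOI dataset.

A CoSMoS analysis starts from a multi-frame grayscale image stack and lists
of drift-corrected target (and off-target control) coordinates.  This module
crops a P x P area of interest (AOI) around every coordinate, builds the
empirical camera-offset distribution from a dark-pixel sample, and persists
the resulting :class:`AOIDataset` to a single HDF5 container.

Pixel convention: integer index (i, j) denotes the pixel *center*; arrays
are 0-based and AOI windows are half-open integer ranges.  The crop window
for a fractional coordinate is chosen so that the adjusted target coordinate
always lands in the central range [P/2 - 1, P/2].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RawStack",
    "TargetList",
    "OffsetEmpirical",
    "AOIDataset",
    "extract_aois",
    "build_offset",
    "save_dataset",
    "load_dataset",
    "read_target_csv",
]

_FORMAT_VERSION = 1


@dataclass
class RawStack:
    """A raw multi-frame image stack in camera intensity units."""

    frames: np.ndarray  # (F, H, W)
    frame_times: np.ndarray | None = None  # seconds, optional

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D array (frame, pixelX, pixelY)")
        if not np.all(np.isfinite(self.frames)) or np.any(self.frames < 0):
            raise ValueError("intensities must be finite and nonnegative")

    @classmethod
    def from_tiff(cls, path) -> "RawStack":
        import tifffile

        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        return cls(frames=np.asarray(arr, dtype=float))


@dataclass
class TargetList:
    """Per-AOI (optionally per-frame) drift-corrected raw coordinates."""

    x_raw: np.ndarray  # (n_aoi,) or (n_aoi, F)
    y_raw: np.ndarray
    is_control: np.ndarray  # (n_aoi,) bool

    def __post_init__(self):
        self.x_raw = np.atleast_1d(np.asarray(self.x_raw, dtype=float))
        self.y_raw = np.atleast_1d(np.asarray(self.y_raw, dtype=float))
        self.is_control = np.atleast_1d(np.asarray(self.is_control, dtype=bool))
        if self.x_raw.shape != self.y_raw.shape:
            raise ValueError("x_raw and y_raw must have the same shape")
        if self.is_control.shape[0] != self.x_raw.shape[0]:
            raise ValueError("is_control must have one flag per AOI")


@dataclass
class OffsetEmpirical:
    """Empirical camera-offset distribution (sorted values and weights)."""

    samples: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.samples.ndim != 1 or self.samples.shape != self.weights.shape:
            raise ValueError("samples and weights must be matching 1-D arrays")
        if np.any(np.diff(self.samples) <= 0):
            raise ValueError("samples must be strictly increasing")
        if np.any(self.weights <= 0):
            raise ValueError("weights must all be positive")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1 within 1e-9")

    @property
    def mean(self) -> float:
        return float(np.sum(self.samples * self.weights))

    @property
    def var(self) -> float:
        return float(np.sum(self.weights * (self.samples - self.mean) ** 2))

    def sample(self, rng, size=None):
        idx = rng.choice(len(self.samples), p=self.weights, size=size)
        return self.samples[idx]


@dataclass
class AOIDataset:
    """Extracted P x P AOI image stacks with metadata.

    ``data`` has shape (N + Nc, F, P, P) in camera units; ``x_target`` and
    ``y_target`` are AOI-local coordinates in [P/2 - 1, P/2].
    """

    data: np.ndarray
    x_target: np.ndarray  # (n_aoi, F)
    y_target: np.ndarray
    is_control: np.ndarray  # (n_aoi,) bool
    offset: OffsetEmpirical
    frame_interval: float = 1.0  # seconds per frame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[2] != self.data.shape[3]:
            raise ValueError("data must have shape (AOI, frame, P, P)")
        n, f = self.data.shape[:2]
        self.x_target = np.broadcast_to(
            np.asarray(self.x_target, dtype=float).reshape(n, -1), (n, f)
        ).copy()
        self.y_target = np.broadcast_to(
            np.asarray(self.y_target, dtype=float).reshape(n, -1), (n, f)
        ).copy()
        self.is_control = np.asarray(self.is_control, dtype=bool)
        p = self.P
        if p % 2 or p < 6:
            raise ValueError("P must be even and >= 6")
        lo, hi = p / 2 - 1, p / 2
        for name, arr in (("x_target", self.x_target), ("y_target", self.y_target)):
            if np.any(arr < lo - 1e-9) or np.any(arr > hi + 1e-9):
                raise ValueError(f"{name} must lie in [{lo}, {hi}]")

    @property
    def P(self) -> int:
        return self.data.shape[-1]

    @property
    def F(self) -> int:
        return self.data.shape[1]

    @property
    def n_aoi(self) -> int:
        return self.data.shape[0]

    @property
    def N(self) -> int:
        return int(np.sum(~self.is_control))

    @property
    def Nc(self) -> int:
        return int(np.sum(self.is_control))

    @property
    def ontarget(self) -> np.ndarray:
        return ~self.is_control

    def validate_offset(self) -> None:
        """Every observed intensity must exceed the smallest offset value."""
        if self.data.min() <= self.offset.samples[0]:
            raise ValueError(
                "data contains values not larger than the smallest offset value; "
                "rebuild the offset with data_min=data.min()"
            )


def extract_aois(stack: RawStack, targets: TargetList, P: int) -> AOIDataset:
    """Crop P x P AOI windows around each target for every frame.

    The window origin is ``floor(coord - P/2 + 1)`` so that the adjusted
    coordinate ``coord - origin`` falls in [P/2 - 1, P/2].  Crops are
    axis-aligned integer-pixel windows; no interpolation is performed.
    """
    if not isinstance(P, (int, np.integer)) or P % 2 or P < 6:
        raise ValueError("P must be an even integer >= 6")
    F, H, W = stack.frames.shape
    n_aoi = targets.x_raw.shape[0]
    x_raw = np.broadcast_to(targets.x_raw.reshape(n_aoi, -1), (n_aoi, F))
    y_raw = np.broadcast_to(targets.y_raw.reshape(n_aoi, -1), (n_aoi, F))

    x0 = np.floor(x_raw - P / 2 + 1).astype(int)
    y0 = np.floor(y_raw - P / 2 + 1).astype(int)
    bad = (x0 < 0) | (x0 + P > H) | (y0 < 0) | (y0 + P > W)
    if np.any(bad):
        idx = int(np.argwhere(bad.any(axis=1))[0, 0])
        raise ValueError(
            f"AOI {idx}: target too close to the raw image border for P={P}"
        )

    data = np.empty((n_aoi, F, P, P))
    for a in range(n_aoi):
        for f in range(F):
            data[a, f] = stack.frames[f, x0[a, f] : x0[a, f] + P, y0[a, f] : y0[a, f] + P]
    x_adj = x_raw - x0
    y_adj = y_raw - y0
    assert np.all((x_adj >= P / 2 - 1) & (x_adj <= P / 2))
    assert np.all((y_adj >= P / 2 - 1) & (y_adj <= P / 2))

    offset = OffsetEmpirical(samples=[stack.frames.min() - 1.0], weights=[1.0])
    return AOIDataset(
        data=data,
        x_target=x_adj,
        y_target=y_adj,
        is_control=targets.is_control,
        offset=offset,
    )


def build_offset(
    dark_pixels, trim_quantile: float = 0.005, data_min: float | None = None
) -> OffsetEmpirical:
    """Build the empirical offset distribution from a dark-pixel sample.

    The sample is histogrammed at unit intensity steps; values above the
    (1 - trim_quantile) quantile are merged into a single bin (the long
    right-hand tail carries negligible density).  If ``data_min`` is given
    and does not exceed the smallest bin, the value ``data_min - 1`` is
    appended with negligible weight so that every observed datum is larger
    than the smallest offset value.
    """
    dark = np.asarray(dark_pixels, dtype=float).ravel()
    if dark.size == 0:
        raise ValueError("dark-pixel sample is empty")
    if not np.all(np.isfinite(dark)):
        raise ValueError("dark-pixel sample contains non-finite values")
    dark = np.round(dark)
    cut = np.quantile(dark, 1.0 - trim_quantile)
    head = dark[dark <= cut]
    tail = dark[dark > cut]
    samples, counts = np.unique(head, return_counts=True)
    weights = counts.astype(float)
    if tail.size:
        tail_pos = np.round(tail.mean())
        if tail_pos <= samples[-1]:
            weights[-1] += tail.size
        else:
            samples = np.append(samples, tail_pos)
            weights = np.append(weights, float(tail.size))
    weights /= weights.sum()

    if data_min is not None and data_min <= samples[0]:
        eps = 1e-6
        samples = np.concatenate([[np.floor(data_min) - 1.0], samples])
        weights = np.concatenate([[eps], weights * (1.0 - eps)])
    return OffsetEmpirical(samples=samples, weights=weights)


def save_dataset(dataset: AOIDataset, path) -> None:
    """Write the dataset to a single HDF5 container (bit-exact round trip)."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["frame_interval"] = dataset.frame_interval
        f.attrs["meta"] = json.dumps(dataset.meta)
        f.attrs["no_control_aois"] = bool(dataset.Nc == 0)
        f.create_dataset("data", data=dataset.data)
        f.create_dataset("x_target", data=dataset.x_target)
        f.create_dataset("y_target", data=dataset.y_target)
        f.create_dataset("is_control", data=dataset.is_control)
        f.create_dataset("offset_samples", data=dataset.offset.samples)
        f.create_dataset("offset_weights", data=dataset.offset.weights)


def load_dataset(path) -> AOIDataset:
    import h5py

    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            version = f.attrs.get("format_version")
            if version != _FORMAT_VERSION:
                raise ValueError(
                    f"unsupported dataset format version {version!r} in {path}"
                )
            return AOIDataset(
                data=f["data"][()],
                x_target=f["x_target"][()],
                y_target=f["y_target"][()],
                is_control=f["is_control"][()].astype(bool),
                offset=OffsetEmpirical(
                    samples=f["offset_samples"][()], weights=f["offset_weights"][()]
                ),
                frame_interval=float(f.attrs.get("frame_interval", 1.0)),
                meta=json.loads(f.attrs.get("meta", "{}")),
            )
    except OSError as exc:
        raise ValueError(f"could not read dataset container {path}: {exc}") from exc


def read_target_csv(path) -> TargetList:
    """Read a target/control coordinate CSV.

    Required columns: ``aoi_id, frame, x, y, is_control`` (0-based raw-pixel
    coordinates).  A single row per AOI (frame = -1 or one frame) yields
    constant-per-AOI coordinates.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"aoi_id", "frame", "x", "y", "is_control"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"target CSV is missing columns: {sorted(missing)}")
    aois = sorted(df["aoi_id"].unique())
    per_frame = df.groupby("aoi_id").size().max() > 1
    if per_frame:
        frames = sorted(df["frame"].unique())
        x = np.full((len(aois), len(frames)), np.nan)
        y = np.full_like(x, np.nan)
        ctrl = np.zeros(len(aois), dtype=bool)
        fidx = {f: i for i, f in enumerate(frames)}
        aidx = {a: i for i, a in enumerate(aois)}
        for row in df.itertuples():
            x[aidx[row.aoi_id], fidx[row.frame]] = row.x
            y[aidx[row.aoi_id], fidx[row.frame]] = row.y
            ctrl[aidx[row.aoi_id]] = bool(row.is_control)
        if np.any(np.isnan(x)) or np.any(np.isnan(y)):
            raise ValueError("per-frame target CSV has missing (aoi, frame) entries")
    else:
        g = df.sort_values("aoi_id")
        x = g["x"].to_numpy()
        y = g["y"].to_numpy()
        ctrl = g["is_control"].to_numpy().astype(bool)
    return TargetList(x_raw=x, y_raw=y, is_control=ctrl)
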