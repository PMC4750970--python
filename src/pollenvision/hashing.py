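"""Hashed-histogram pixel classifier.

Every pixel is described by a *grid example*: a square lattice of neighbouring
pixel intensities (``grid_size`` per side, ``grid_spacing`` pixels apart,
centred on the pixel), quantized by integer division with a quantization
factor ``q``.  The example is mapped to one of ``B`` counting bins by summing
seeded random 64-bit numbers — one per (lattice slot, channel, quantized
level) — modulo 2**64 and then modulo ``B``.  Training increments the
positive or negative count of the bin; prediction classifies a pixel positive
when its bin's positive count exceeds its negative count.

The scheme is a histogram density estimator over a locality-sensitive hash of
texture neighbourhoods: identical neighbourhoods always collide, unrelated
ones collide with probability ~1/B.  Complexity is linear in the number of
pixels and memory is O(B), independent of the training-set size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .exceptions import FormatError, InputError, ParameterError, StateError

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class GridSpec:
    """Feature-representation parameters of the pixel classifier.

    Defaults are the segmentation-pass optimum (8x8 grid, spacing 8,
    quantization 10, about 2 million bins).
    """

    grid_size: int = 8
    grid_spacing: int = 8
    quantization: float = 10.0
    bins: int = 2_048_000
    channels: tuple = (0,)
    max_intensity: int = 255

    def __post_init__(self) -> None:
        if self.grid_size < 1:
            raise ParameterError(f"grid_size must be >= 1, got {self.grid_size}")
        if self.grid_spacing < 1:
            raise ParameterError(f"grid_spacing must be >= 1, got {self.grid_spacing}")
        if self.quantization < 1:
            raise ParameterError(f"quantization must be >= 1, got {self.quantization}")
        if self.bins < 1:
            raise ParameterError(f"bins must be >= 1, got {self.bins}")
        if len(self.channels) < 1:
            raise ParameterError("at least one channel required")

    @property
    def n_levels(self) -> int:
        """Q — number of quantized intensity levels per channel."""
        return int(self.max_intensity // self.quantization) + 1

    @property
    def n_slots(self) -> int:
        """Number of lattice cells (grid_size**2)."""
        return self.grid_size * self.grid_size

    def to_dict(self) -> dict:
        return {
            "grid_size": self.grid_size,
            "grid_spacing": self.grid_spacing,
            "quantization": self.quantization,
            "bins": self.bins,
            "channels": list(self.channels),
            "max_intensity": self.max_intensity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(
            grid_size=int(d["grid_size"]),
            grid_spacing=int(d["grid_spacing"]),
            quantization=float(d["quantization"]),
            bins=int(d["bins"]),
            channels=tuple(d["channels"]),
            max_intensity=int(d["max_intensity"]),
        )


@dataclass
class GridExample:
    """Quantized neighbourhood of one pixel: ``levels[slot, channel]``."""

    levels: np.ndarray
    center: tuple = (0, 0)
    label: int | None = None


def quantize(value, q: float, max_intensity: int = 255):
    """Coarsen intensities: ``level = floor(value / q)``.

    ``q=1`` is the identity; ``q=max_intensity/2 + eps`` leaves only levels
    {0, 1}.  ``q`` may be fractional.
    """
    if q < 1:
        raise ParameterError(f"quantization factor must be >= 1, got {q}")
    lev = np.floor(np.asarray(value, dtype=np.float64) / q).astype(np.int64)
    if lev.ndim == 0:
        return int(lev)
    return lev


def grid_offsets(spec: GridSpec) -> np.ndarray:
    """Row-major (drow, dcol) lattice offsets relative to the centre pixel.

    For even grid sizes the centre is top-left-biased: offsets run from
    ``-floor((g-1)/2)*s`` to ``+ceil((g-1)/2)*s``.
    """
    g, s = spec.grid_size, spec.grid_spacing
    lo = -((g - 1) // 2) * s
    steps = lo + s * np.arange(g)
    return np.stack(np.meshgrid(steps, steps, indexing="ij"), axis=-1).reshape(-1, 2)


def grid_coordinates(center, spec: GridSpec, plane_shape) -> np.ndarray:
    """Absolute (row, col) sample coordinates for one centre, clamped to the
    plane bounds (edge replication), in row-major order."""
    H, W = plane_shape[:2]
    r, c = center
    if not (0 <= r < H and 0 <= c < W):
        raise InputError(f"center {center} outside plane {H}x{W}")
    coords = np.asarray(center) + grid_offsets(spec)
    coords[:, 0] = np.clip(coords[:, 0], 0, H - 1)
    coords[:, 1] = np.clip(coords[:, 1], 0, W - 1)
    return coords


def make_grid_example(plane: np.ndarray, center, spec: GridSpec) -> GridExample:
    """Build the quantized grid example for one pixel of an (H, W, C) plane."""
    plane = np.asarray(plane)
    if plane.ndim == 2:
        plane = plane[:, :, None]
    coords = grid_coordinates(center, spec, plane.shape)
    vals = plane[coords[:, 0], coords[:, 1]][:, list(spec.channels)]
    return GridExample(levels=quantize(vals, spec.quantization, spec.max_intensity),
                       center=tuple(center))


def _random_table(spec: GridSpec, seed: int) -> np.ndarray:
    """Fixed matrix of random 64-bit numbers: one row per lattice slot, one
    column per (channel, level) pair; fully determined by (spec, seed)."""
    rng = np.random.default_rng(seed)
    n_cols = len(spec.channels) * spec.n_levels
    return rng.integers(
        0, np.iinfo(np.uint64).max, size=(spec.n_slots, n_cols),
        dtype=np.uint64, endpoint=True,
    )


@dataclass
class HashModel:
    """Seeded random table plus positive/negative bin counts."""

    spec: GridSpec
    seed: int
    random_table: np.ndarray
    pos_counts: np.ndarray
    neg_counts: np.ndarray
    n_pos: int = 0
    n_neg: int = 0

    @classmethod
    def empty(cls, spec: GridSpec, seed: int) -> "HashModel":
        return cls(
            spec=spec,
            seed=seed,
            random_table=_random_table(spec, seed),
            pos_counts=np.zeros(spec.bins, dtype=np.int64),
            neg_counts=np.zeros(spec.bins, dtype=np.int64),
        )

    @property
    def trained(self) -> bool:
        return self.n_pos + self.n_neg > 0


def compute_hash(example: GridExample, model: HashModel) -> int:
    """Bin index of one grid example: sum the slot random numbers modulo 2**64,
    then modulo B."""
    spec = model.spec
    levels = np.asarray(example.levels, dtype=np.int64).reshape(spec.n_slots, -1)
    if levels.shape[1] != len(spec.channels):
        raise InputError(
            f"example has {levels.shape[1]} channels, spec expects {len(spec.channels)}"
        )
    if (levels < 0).any() or (levels >= spec.n_levels).any():
        raise InputError("quantized level outside random-table range")
    cols = levels + spec.n_levels * np.arange(len(spec.channels), dtype=np.int64)
    rows = np.arange(spec.n_slots, dtype=np.int64)[:, None]
    total = np.sum(model.random_table[rows, cols], dtype=np.uint64)
    return int(total % np.uint64(spec.bins))


def hash_plane(plane: np.ndarray, model: HashModel) -> np.ndarray:
    """Bin index of every pixel of an (H, W[, C]) plane, vectorised.

    Equivalent to calling :func:`compute_hash` on
    :func:`make_grid_example` at every pixel; border neighbourhoods are edge
    replicated, matching the per-pixel clamping rule.
    """
    spec = model.spec
    plane = np.asarray(plane)
    if plane.ndim == 2:
        plane = plane[:, :, None]
    H, W, _ = plane.shape
    q = quantize(plane[:, :, list(spec.channels)], spec.quantization, spec.max_intensity)
    acc = np.zeros((H, W), dtype=np.uint64)
    rows = np.arange(H)
    cols = np.arange(W)
    for slot, (dr, dc) in enumerate(grid_offsets(spec)):
        rr = np.clip(rows + dr, 0, H - 1)
        cc = np.clip(cols + dc, 0, W - 1)
        shifted = q[rr[:, None], cc[None, :]]  # (H, W, C')
        for ci in range(shifted.shape[2]):
            acc += model.random_table[slot, ci * spec.n_levels + shifted[:, :, ci]]
    return (acc % np.uint64(spec.bins)).astype(np.int64)


def train(
    examples: Iterable[tuple[GridExample, int] | GridExample],
    spec: GridSpec,
    seed: int,
) -> HashModel:
    """Single-pass training from a stream of labelled grid examples.

    Accepts ``(example, label)`` pairs or examples with ``label`` set;
    labels are binary (1 = positive).  Memory is O(B + random table).
    """
    model = HashModel.empty(spec, seed)
    n = 0
    for item in examples:
        ex, label = item if isinstance(item, tuple) else (item, item.label)
        if label not in (0, 1):
            raise InputError(f"label must be 0/1, got {label!r}")
        b = compute_hash(ex, model)
        if label:
            model.pos_counts[b] += 1
            model.n_pos += 1
        else:
            model.neg_counts[b] += 1
            model.n_neg += 1
        n += 1
    if n == 0:
        raise InputError("empty training stream")
    return model


def accumulate_plane(
    model: HashModel, plane: np.ndarray, labels: np.ndarray,
    select: np.ndarray | None = None,
) -> None:
    """Vectorised training update: add every pixel of ``plane`` (optionally
    restricted to ``select``) with its binary label to the model counts."""
    bins = hash_plane(plane, model)
    labels = np.asarray(labels)
    if labels.shape != bins.shape:
        raise InputError(f"labels shape {labels.shape} != plane shape {bins.shape}")
    if select is not None:
        keep = np.asarray(select).astype(bool)
        bins, labels = bins[keep], labels[keep]
    else:
        bins, labels = bins.ravel(), labels.ravel()
    pos = labels.astype(bool)
    model.pos_counts += np.bincount(bins[pos], minlength=model.spec.bins)
    model.neg_counts += np.bincount(bins[~pos], minlength=model.spec.bins)
    model.n_pos += int(pos.sum())
    model.n_neg += int((~pos).sum())


def predict_pixel(model: HashModel, plane: np.ndarray, center) -> tuple[int, int, int]:
    """Classify one pixel: positive iff its bin's positive count strictly
    exceeds the negative count (ties, including unseen 0/0 bins, go negative).
    Returns ``(label, pos_count, neg_count)``."""
    if not model.trained:
        raise StateError("model has no training counts")
    b = compute_hash(make_grid_example(plane, center, model.spec), model)
    p, n = int(model.pos_counts[b]), int(model.neg_counts[b])
    return (1 if p > n else 0), p, n


def predict_plane(model: HashModel, plane: np.ndarray):
    """Classify every pixel of a plane.  Returns ``(labels, pos, neg)`` arrays
    of shape (H, W)."""
    if not model.trained:
        raise StateError("model has no training counts")
    bins = hash_plane(plane, model)
    p = model.pos_counts[bins]
    n = model.neg_counts[bins]
    return (p > n).astype(np.uint8), p, n


def grid_configuration_count(grid_size: int, n_levels: int, n_channels: int = 1) -> int:
    """Exact number of distinct grid examples: K**N with N = grid_size**2
    lattice cells and K = n_levels**n_channels colours per cell.

    Motivates hashing: an 8x8 grid at Q=4 over 3 channels already exceeds
    10**115 configurations.
    """
    if grid_size < 1 or n_levels < 1 or n_channels < 1:
        raise ParameterError("counts must be >= 1")
    return (n_levels**n_channels) ** (grid_size**2)


def save_model(model: HashModel, path: str | Path) -> None:
    """Serialise a model (spec, seed, counts) to a single .npz archive."""
    import json

    np.savez(
        Path(path),
        format_version=np.int64(MODEL_FORMAT_VERSION),
        spec_json=np.frombuffer(json.dumps(model.spec.to_dict()).encode(), dtype=np.uint8),
        seed=np.int64(model.seed),
        pos_counts=model.pos_counts,
        neg_counts=model.neg_counts,
        n_pos=np.int64(model.n_pos),
        n_neg=np.int64(model.n_neg),
    )


def load_model(path: str | Path) -> HashModel:
    """Load a model saved by :func:`save_model`; the random table is
    regenerated from the stored seed, so predictions round-trip bit-exactly."""
    import json
    import zipfile

    try:
        with np.load(Path(path)) as z:
            if int(z["format_version"]) != MODEL_FORMAT_VERSION:
                raise FormatError(
                    f"model format version {int(z['format_version'])} unsupported"
                )
            spec = GridSpec.from_dict(json.loads(bytes(z["spec_json"]).decode()))
            model = HashModel.empty(spec, int(z["seed"]))
            model.pos_counts = z["pos_counts"].astype(np.int64)
            model.neg_counts = z["neg_counts"].astype(np.int64)
            model.n_pos = int(z["n_pos"])
            model.n_neg = int(z["n_neg"])
            return model
    except (OSError, KeyError, ValueError, zipfile.BadZipFile) as e:
        if isinstance(e, FormatError):
            raise
        raise FormatError(f"cannot load model from {path}: {e}") from e
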