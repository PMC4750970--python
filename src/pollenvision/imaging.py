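"""Image-stack data model, window extraction and raster file I/O.

A *slide* is represented as an :class:`ImageStack`: an ordered set of z-planes
of equal size, each an 8-bit raster with 1 or 3 channels, acquired by optical
sectioning of a microscope slide.  Coordinates are 0-based ``(z, row, col)``
and rectangles are half-open: ``[row0, row0 + height) x [col0, col0 + width)``.

On disk a stack is a directory of one PNG/TIFF file per z-plane plus a JSON
manifest listing the plane files in z-order with the slide metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .exceptions import BoundsError, FormatError, InputError, ParameterError

MANIFEST_NAME = "manifest.json"


def _as_plane(arr: np.ndarray) -> np.ndarray:
    """Normalise a raster to shape (H, W, C)."""
    a = np.asarray(arr)
    if a.ndim == 2:
        a = a[:, :, None]
    if a.ndim != 3:
        raise InputError(f"plane must be 2-D or 3-D, got shape {a.shape}")
    return a


@dataclass
class ImageStack:
    """Ordered z-planes of a slide scan.

    Parameters
    ----------
    planes
        Array of shape ``(Z, H, W, C)``; 2-D/3-D inputs are promoted.
    bit_depth, max_intensity
        Intensity representation; 8-bit 0-255 by default.
    pixel_pitch_um
        Physical pixel pitch, informational only (0.23 um at 400x).
    slide_id, slide_label
        Identifier and optional class label or mixture ratio of the slide.
    """

    planes: np.ndarray
    bit_depth: int = 8
    max_intensity: int = 255
    pixel_pitch_um: float = 0.23
    slide_id: str = ""
    slide_label: object = None

    def __post_init__(self) -> None:
        p = np.asarray(self.planes)
        if p.ndim == 2:
            p = p[None, :, :, None]
        elif p.ndim == 3:
            # (H, W, C) single plane when the last axis looks like channels,
            # else (Z, H, W) grayscale stack
            p = p[None] if p.shape[-1] in (1, 3) else p[:, :, :, None]
        if p.ndim != 4:
            raise InputError(f"planes must have shape (Z, H, W, C), got {p.shape}")
        if p.size and (p.min() < 0 or p.max() > self.max_intensity):
            raise InputError("intensities outside [0, max_intensity]")
        self.planes = p

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]

    @property
    def shape(self) -> tuple:
        """(Z, H, W, C)."""
        return self.planes.shape

    @property
    def n_channels(self) -> int:
        return self.planes.shape[3]

    def plane(self, z: int) -> np.ndarray:
        """Return plane ``z`` as an (H, W, C) view."""
        if not 0 <= z < self.n_planes:
            raise BoundsError(f"z={z} outside [0, {self.n_planes})")
        return self.planes[z]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ImageStack):
            return NotImplemented
        return (
            self.planes.shape == other.planes.shape
            and bool(np.array_equal(self.planes, other.planes))
            and self.slide_id == other.slide_id
        )


@dataclass
class Window:
    """A rectangular crop of a single z-plane, optionally with a label mask."""

    pixels: np.ndarray
    origin: tuple = (0, 0, 0)  # (z, row, col) in the parent stack
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = _as_plane(self.pixels)
        if self.mask is not None:
            m = np.asarray(self.mask)
            if m.shape != self.pixels.shape[:2]:
                raise InputError(
                    f"mask shape {m.shape} != window shape {self.pixels.shape[:2]}"
                )
            if not np.isin(m, (0, 1)).all():
                raise InputError("mask must be binary (0/1)")
            self.mask = m.astype(np.uint8)

    @property
    def size(self) -> tuple:
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]


def extract_window(
    stack: ImageStack, z: int, row0: int, col0: int, height: int, width: int
) -> Window:
    """Copy the half-open rectangle ``[row0, row0+height) x [col0, col0+width)``
    of plane ``z`` into a :class:`Window` (no mask attached)."""
    if not 0 <= z < stack.n_planes:
        raise BoundsError(f"z={z} outside [0, {stack.n_planes})")
    _, H, W, _ = stack.shape
    if row0 < 0 or col0 < 0 or height < 1 or width < 1:
        raise BoundsError(f"bad rectangle origin/size ({row0}, {col0}, {height}, {width})")
    if row0 + height > H:
        raise BoundsError(f"rows [{row0}, {row0 + height}) exceed plane height {H}")
    if col0 + width > W:
        raise BoundsError(f"cols [{col0}, {col0 + width}) exceed plane width {W}")
    return Window(
        pixels=stack.planes[z, row0 : row0 + height, col0 : col0 + width].copy(),
        origin=(z, row0, col0),
    )


def select_planes(stack: ImageStack, step: int) -> ImageStack:
    """Keep every ``step``-th z-plane (indices 0, step, 2*step, ...).

    ``step=5`` reproduces the usual decimated-z training regime.
    """
    if step < 1:
        raise ParameterError(f"step must be >= 1, got {step}")
    return replace(stack, planes=stack.planes[::step].copy())


def select_channel(window: Window, channel: int) -> Window:
    """Restrict a window to a single colour band (0 = red for RGB input)."""
    if not 0 <= channel < window.n_channels:
        raise ParameterError(
            f"channel {channel} invalid for {window.n_channels}-channel window"
        )
    return Window(
        pixels=window.pixels[:, :, channel : channel + 1].copy(),
        origin=window.origin,
        mask=None if window.mask is None else window.mask.copy(),
    )


def write_stack(stack: ImageStack, directory: str | Path) -> Path:
    """Write one image file per z-plane plus a JSON manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for z in range(stack.n_planes):
        name = f"plane_{z:03d}.png"
        plane = stack.planes[z]
        iio.imwrite(directory / name, plane[:, :, 0] if plane.shape[2] == 1 else plane)
        names.append(name)
    manifest = {
        "planes": names,
        "slide_id": stack.slide_id,
        "slide_label": stack.slide_label,
        "pixel_pitch_um": stack.pixel_pitch_um,
        "bit_depth": stack.bit_depth,
        "max_intensity": stack.max_intensity,
    }
    path = directory / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_stack(source: str | Path | Sequence[str | Path]) -> ImageStack:
    """Read a stack from a manifest path, a stack directory, or an ordered
    list of plane files."""
    meta: dict = {}
    if isinstance(source, (str, Path)):
        p = Path(source)
        manifest = p / MANIFEST_NAME if p.is_dir() else p
        try:
            meta = json.loads(Path(manifest).read_text())
        except OSError as e:
            raise FormatError(f"cannot read manifest {manifest}: {e}") from e
        paths = [Path(manifest).parent / n for n in meta["planes"]]
    else:
        paths = [Path(s) for s in source]
    if not paths:
        raise InputError("no plane files given")
    planes = []
    for path in paths:
        try:
            planes.append(_as_plane(iio.imread(path)))
        except OSError as e:
            raise FormatError(f"cannot read plane {path}: {e}") from e
    shapes = {a.shape for a in planes}
    if len(shapes) > 1:
        raise FormatError(f"planes have mixed dimensions: {sorted(shapes)}")
    return ImageStack(
        planes=np.stack(planes),
        bit_depth=int(meta.get("bit_depth", 8)),
        max_intensity=int(meta.get("max_intensity", 255)),
        pixel_pitch_um=float(meta.get("pixel_pitch_um", 0.23)),
        slide_id=str(meta.get("slide_id", "")),
        slide_label=meta.get("slide_label"),
    )
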