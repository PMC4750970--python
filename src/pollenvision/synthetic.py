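"""Synthetic slide simulator with ground truth.

Generates brightfield-like z-stacks of circular textured grains from two
classes placed on a noisy bright background, together with per-pixel pollen
masks, per-pixel class maps and per-grain labels.  The two classes share
geometry and mean intensity and differ only in texture parameters (speckle
spatial frequency, orientation anisotropy, contrast), mimicking exine
ornamentation differences, which are the discriminative signal of interest.
One z-plane is rendered sharp and the others are defocus-blurred in
proportion to their offset from the focal plane; grain geometry (and hence
the ground-truth masks) is identical across planes.

Experimental designs mirror a physical two-species study: pure *reference*
slides from a few "individuals" per class (three replicate slides per
individual, with individual-level texture jitter so held-out individuals
differ systematically), and a *ratio series* of mixed slides at 0-100% in
10% steps, two duplicates each.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .exceptions import InputError, ParameterError
from .imaging import ImageStack


@dataclass(frozen=True)
class TextureParams:
    """Per-class grain texture: band-pass filtered noise.

    ``freq_sigma`` is the Gaussian smoothing scale of the speckle (larger =
    coarser ornamentation); ``anisotropy`` stretches the speckle vertically
    (sigma_row = anisotropy * sigma_col); ``contrast`` is the speckle
    amplitude in intensity units (std of the texture field).
    """

    freq_sigma: float = 1.0
    anisotropy: float = 1.0
    contrast: float = 45.0


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Study conditions for one synthetic slide."""

    height: int = 1024
    width: int = 1024
    n_grains: int = 100
    ratio_class_a: float = 0.5
    radius_range: tuple = (18, 30)
    texture_a: TextureParams = field(default_factory=lambda: TextureParams(freq_sigma=1.0, contrast=55.0))
    texture_b: TextureParams = field(default_factory=lambda: TextureParams(freq_sigma=2.0, contrast=22.0))
    grain_mean: float = 120.0
    background_mean: float = 225.0
    background_noise: float = 6.0
    n_z_planes: int = 5
    defocus_blur_per_plane: float = 1.5
    n_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ratio_class_a <= 1:
            raise ParameterError("ratio_class_a must be in [0, 1]")
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ParameterError("invalid radius range")
        if self.n_grains < 1 or self.n_z_planes < 1:
            raise ParameterError("n_grains and n_z_planes must be >= 1")
        if self.n_channels not in (1, 3):
            raise ParameterError("n_channels must be 1 or 3")

    @property
    def focus_plane(self) -> int:
        return self.n_z_planes // 2


@dataclass
class SyntheticSlide:
    """A generated slide with full ground truth."""

    stack: ImageStack
    mask: np.ndarray        # (H, W) uint8, 1 = pollen (any grain)
    class_map: np.ndarray   # (H, W) int8, -1 background, 0 class A, 1 class B
    grains: list            # dicts: center, radius, label
    spec: SyntheticSlideSpec

    @property
    def label(self):
        """Class of a pure slide: 0 (all class A), 1 (all class B), else None."""
        if self.spec.ratio_class_a == 1.0:
            return 0
        if self.spec.ratio_class_a == 0.0:
            return 1
        return None


def _place_grains(spec: SyntheticSlideSpec, rng: np.random.Generator):
    """Non-overlapping grain placement fully inside the image, bounded retries."""
    n_a = int(round(spec.ratio_class_a * spec.n_grains))
    labels = [0] * n_a + [1] * (spec.n_grains - n_a)
    grains = []
    max_tries = 2000 * spec.n_grains
    tries = 0
    for label in labels:
        while True:
            tries += 1
            if tries > max_tries:
                raise InputError(
                    f"could not place {spec.n_grains} non-overlapping grains "
                    f"of radius {spec.radius_range} in {spec.height}x{spec.width}"
                )
            r = float(rng.uniform(*spec.radius_range))
            cy = float(rng.uniform(r, spec.height - r))
            cx = float(rng.uniform(r, spec.width - r))
            if all(
                (cy - g["center"][0]) ** 2 + (cx - g["center"][1]) ** 2
                > (r + g["radius"] + 1) ** 2
                for g in grains
            ):
                grains.append({"center": (cy, cx), "radius": r, "label": label})
                break
    return grains


def _texture_field(shape, tp: TextureParams, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-pass noise with the class's scale and anisotropy."""
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(
        noise, sigma=(tp.freq_sigma * tp.anisotropy, tp.freq_sigma)
    )
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_slide(spec: SyntheticSlideSpec) -> SyntheticSlide:
    """Render one slide: exactly ``n_grains`` grains with class counts
    ``round(ratio * n)`` vs the remainder; bit-exact reproducible from the
    spec's seed."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    grains = _place_grains(spec, rng)
    yy, xx = np.mgrid[0:H, 0:W]
    sharp = spec.background_mean + spec.background_noise * rng.standard_normal((H, W))
    mask = np.zeros((H, W), dtype=np.uint8)
    class_map = np.full((H, W), -1, dtype=np.int8)
    for g in grains:
        (cy, cx), r = g["center"], g["radius"]
        tp = spec.texture_a if g["label"] == 0 else spec.texture_b
        y0, y1 = max(0, int(np.floor(cy - r))), min(H, int(np.ceil(cy + r)) + 1)
        x0, x1 = max(0, int(np.floor(cx - r))), min(W, int(np.ceil(cx + r)) + 1)
        disk = (yy[y0:y1, x0:x1] - cy) ** 2 + (xx[y0:y1, x0:x1] - cx) ** 2 <= r**2
        tex = _texture_field((y1 - y0, x1 - x0), tp, rng)
        patch = spec.grain_mean + tp.contrast * tex
        region = sharp[y0:y1, x0:x1]
        region[disk] = patch[disk]
        mask[y0:y1, x0:x1][disk] = 1
        class_map[y0:y1, x0:x1][disk] = g["label"]
    planes = []
    for z in range(spec.n_z_planes):
        off = abs(z - spec.focus_plane)
        img = sharp if off == 0 else ndimage.gaussian_filter(
            sharp, sigma=spec.defocus_blur_per_plane * off
        )
        planes.append(np.clip(img, 0, 255))
    arr = np.stack(planes).astype(np.uint8)[:, :, :, None]
    if spec.n_channels == 3:
        arr = np.repeat(arr, 3, axis=3)
    stack = ImageStack(
        planes=arr,
        slide_id=f"synthetic-{spec.seed}",
        slide_label=spec.ratio_class_a,
    )
    return SyntheticSlide(stack=stack, mask=mask, class_map=class_map,
                          grains=grains, spec=spec)


def write_slide(slide: SyntheticSlide, directory) -> None:
    """Write a slide and its ground truth to a directory: plane PNGs plus a
    manifest (via :func:`pollenvision.imaging.write_stack`), ``mask.png``
    (0/255) and ``class_map.png`` (0 background, 1 class A, 2 class B)."""
    from pathlib import Path

    import imageio.v3 as iio

    from .imaging import write_stack

    directory = Path(directory)
    write_stack(slide.stack, directory)
    iio.imwrite(directory / "mask.png", (slide.mask * 255).astype(np.uint8))
    iio.imwrite(directory / "class_map.png", (slide.class_map + 1).astype(np.uint8))


def read_slide(directory):
    """Read back what :func:`write_slide` wrote.

    Returns ``(stack, mask, class_map)``; mask is 0/1, class_map uses -1 for
    background.  ``class_map`` is ``None`` when absent.
    """
    from pathlib import Path

    import imageio.v3 as iio

    from .imaging import read_stack

    directory = Path(directory)
    stack = read_stack(directory)
    mask = (np.asarray(iio.imread(directory / "mask.png")) > 127).astype(np.uint8)
    cpath = directory / "class_map.png"
    class_map = None
    if cpath.exists():
        class_map = np.asarray(iio.imread(cpath)).astype(np.int8) - 1
    return stack, mask, class_map


def generate_ratio_series(
    base: SyntheticSlideSpec,
    ratios=None,
    duplicates: int = 2,
) -> list[SyntheticSlide]:
    """The mixed-ratio test design: slides at each ratio with ``duplicates``
    replicates and distinct seeds.  Defaults (0.0-1.0 in 0.1 steps, two
    duplicates) give the canonical 22-slide series."""
    if ratios is None:
        ratios = [round(0.1 * i, 1) for i in range(11)]
    if any(not 0 <= r <= 1 for r in ratios):
        raise ParameterError("ratios must be in [0, 1]")
    out = []
    i = 0
    for ratio in ratios:
        for _ in range(duplicates):
            out.append(
                generate_slide(replace(base, ratio_class_a=ratio, seed=base.seed + 1000 + i))
            )
            i += 1
    return out


def generate_reference_set(
    base: SyntheticSlideSpec,
    slides_per_class: int = 6,
    individuals_per_class: int = 2,
    jitter: float = 0.15,
) -> list[SyntheticSlide]:
    """Pure training slides with individual-level texture variation.

    Each class contributes ``individuals_per_class`` simulated individuals
    whose texture parameters are jittered multiplicatively (by up to
    ``jitter``); an individual's replicate slides share its parameters, so
    slides of held-out individuals differ systematically from training
    slides.  Default 6 + 6 = 12 pure slides (2 individuals x 3 replicates per
    class).  Each slide's ``stack.slide_label`` is its class (0/1) and the
    individual id is recorded in ``slide_id``.
    """
    if slides_per_class < 1 or individuals_per_class < 1:
        raise ParameterError("counts must be >= 1")
    rng = np.random.default_rng(base.seed)
    out = []
    seed_i = 0
    for label, tp in ((0, base.texture_a), (1, base.texture_b)):
        # replicate slides round-robin over individuals
        indiv_params = []
        for _ in range(individuals_per_class):
            indiv_params.append(
                TextureParams(
                    freq_sigma=tp.freq_sigma * float(rng.uniform(1 - jitter, 1 + jitter)),
                    anisotropy=tp.anisotropy * float(rng.uniform(1 - jitter, 1 + jitter)),
                    contrast=tp.contrast * float(rng.uniform(1 - jitter, 1 + jitter)),
                )
            )
        for s in range(slides_per_class):
            indiv = s % individuals_per_class
            tp_i = indiv_params[indiv]
            spec = replace(
                base,
                ratio_class_a=1.0 if label == 0 else 0.0,
                texture_a=tp_i if label == 0 else base.texture_a,
                texture_b=tp_i if label == 1 else base.texture_b,
                seed=base.seed + 5000 + seed_i,
            )
            slide = generate_slide(spec)
            slide.stack.slide_id = f"ref-class{label}-indiv{indiv}-rep{s // individuals_per_class}"
            out.append(slide)
            seed_i += 1
    return out
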