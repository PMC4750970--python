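"""Canonical desk-scale study conditions and pipeline drivers.

This module fixes one set of synthetic study conditions — slide geometry,
class textures, experimental designs (12 pure reference slides, the 22-slide
mixed-ratio series) and the classifier operating points — and provides the
end-to-end drivers that the examples, the test suite and the reproduction
script all share.  The sizes are deliberately small (416-px slides, 20
grains, 3 z-planes) so every pipeline runs in seconds while preserving the
structure of a full-scale study.

The analysis operating points below were selected with the package's own
search harnesses (cross-validated objectives) under these conditions, the
same way the full-scale parameters were chosen in the original studies.
Profile extraction and window sampling for the species passes use the focal
plane: the simulator renders a single in-focus depth per slide, and defocus
genuinely destroys the texture signal that separates the classes.
"""

from __future__ import annotations

import numpy as np

from .hashing import GridSpec
from .profiles import (
    RuleEnsemble,
    build_ensemble,
    extract_profiles,
    predict_slide_ratio,
    r_squared,
    train_rules,
)
from .spotting import LabeledWindowSet, train_spotter
from .synthetic import (
    SyntheticSlide,
    SyntheticSlideSpec,
    TextureParams,
    generate_ratio_series,
    generate_reference_set,
)
from .imaging import Window
from .windows import WindowClassifierConfig, cross_validate_slides

#: Desk-scale slide: 416 px square, 20 grains of radius 22-30 px, 3 z-planes.
DESK_SLIDE_SPEC = SyntheticSlideSpec(
    height=416,
    width=416,
    n_grains=20,
    radius_range=(22, 30),
    texture_a=TextureParams(freq_sigma=1.0, contrast=55.0),
    texture_b=TextureParams(freq_sigma=2.0, contrast=22.0),
    n_z_planes=3,
)

#: Pollen-spotting feature spec at desk scale (coarse quantization: synthetic
#: background noise is pixel-independent, so small fine-grained grids do not
#: repeat across slides).
DESK_SPOT_SPEC = GridSpec(grid_size=2, grid_spacing=2, quantization=32, bins=100_003)

#: Species pixel-model feature spec at desk scale.
DESK_SPECIES_SPEC = GridSpec(grid_size=2, grid_spacing=1, quantization=64, bins=100_003)

#: Window classifier operating point at desk scale; confidence floor and
#: minimum classifications per slide keep their full-scale values.
DESK_WINDOW_CFG = WindowClassifierConfig(
    window_size=24,
    windows_per_slide=300,
    min_pollen_fraction=0.5,
    confidence_min=43.61,
    min_classifications_per_slide=1,
    spec=DESK_SPECIES_SPEC,
)

#: Profile length (px) and information-content floor at desk scale.  The
#: length is bounded by the grain chord (2 * min radius); the IC floor keeps
#: its full-scale value of 5.0 intensity units per pixel.
DESK_PROFILE_LENGTH = 32
DESK_IC_MIN = 5.0


def make_reference_slides(seed: int, slides_per_class: int = 6) -> list[SyntheticSlide]:
    """The pure-slide reference design: 2 individuals x 3 replicates per class."""
    from dataclasses import replace

    return generate_reference_set(
        replace(DESK_SLIDE_SPEC, seed=seed), slides_per_class=slides_per_class
    )


def make_ratio_slides(seed: int, duplicates: int = 2) -> list[SyntheticSlide]:
    """The 22-slide mixed-ratio series: 0-100% class A in 10% steps, twice."""
    from dataclasses import replace

    return generate_ratio_series(replace(DESK_SLIDE_SPEC, seed=seed), duplicates=duplicates)


def focus_profiles(slide: SyntheticSlide, stride: int = 3, labeled: bool = False):
    """Focal-plane profiles of one slide as an (n, L) matrix.

    With ``labeled`` also returns the per-profile class labels (profiles
    crossing grain boundaries or background are dropped).
    """
    zf = slide.spec.focus_plane
    profs = extract_profiles(
        slide.stack.planes[zf],
        slide.mask,
        length=DESK_PROFILE_LENGTH,
        ic_min=DESK_IC_MIN,
        stride=stride,
        class_map=slide.class_map if labeled else None,
        source=(slide.stack.slide_id, zf),
    )
    if not labeled:
        return np.array([p.values for p in profs])
    keep = [p for p in profs if p.label is not None]
    X = np.array([p.values for p in keep])
    y = np.array([p.label for p in keep])
    return X, y


def balanced_profile_sample(slides, per_class: int, seed: int):
    """Pool labelled focal-plane profiles over slides and subsample a
    class-balanced training set (the pure reference slides contribute one
    class each; balancing stops the commoner class from dominating rules)."""
    by_class: dict = {0: [], 1: []}
    for s in slides:
        X, y = focus_profiles(s, labeled=True)
        for cls in (0, 1):
            by_class[cls].extend(X[y == cls])
    rng = np.random.default_rng(seed)
    n = min(per_class, len(by_class[0]), len(by_class[1]))
    out_X, out_y = [], []
    for cls in (0, 1):
        idx = rng.choice(len(by_class[cls]), size=n, replace=False)
        out_X.extend(np.asarray(by_class[cls], dtype=np.int64)[idx])
        out_y.extend([cls] * n)
    return np.asarray(out_X), np.asarray(out_y)


def natural_profile_sample(slides, n: int, seed: int):
    """Pool labelled focal-plane profiles at their natural class mix (the
    finer-textured class passes the information-content filter more often,
    so it dominates) and subsample ``n`` of them."""
    Xs, ys = [], []
    for s in slides:
        X, y = focus_profiles(s, labeled=True)
        Xs.append(X)
        ys.append(y)
    X = np.concatenate(Xs)
    y = np.concatenate(ys)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(X), size=min(n, len(X)), replace=False)
    return X[idx], y[idx]


def train_ratio_ensemble(
    reference_slides, seed: int, n_candidates: int = 256, k: int = 16,
    per_class: int = 500,
) -> RuleEnsemble:
    """Full ratio-classifier training: balanced profiles -> candidate rules ->
    top-k ensemble."""
    X, y = balanced_profile_sample(reference_slides, per_class=per_class, seed=seed)
    rules = train_rules(X, y, n_candidates=n_candidates, seed=seed + 1)
    return build_ensemble(rules, min(k, len(rules)))


def evaluate_ratio_series(ensemble: RuleEnsemble, ratio_slides, stride: int = 4):
    """Predict every slide's class-A fraction and regress against truth.

    Returns ``(r2, predicted, actual)``.
    """
    pred, true = [], []
    for s in ratio_slides:
        X = focus_profiles(s, stride=stride)
        pred.append(predict_slide_ratio(ensemble, X))
        true.append(s.spec.ratio_class_a)
    return r_squared(pred, true), np.asarray(pred), np.asarray(true)


def spotting_training_set(slides, planes: str = "all") -> LabeledWindowSet:
    """Ground-truth labelled windows (whole planes) from synthetic slides."""
    lws = LabeledWindowSet()
    for s in slides:
        zs = range(s.stack.n_planes) if planes == "all" else [s.spec.focus_plane]
        for z in zs:
            lws.add(
                Window(pixels=s.stack.planes[z], origin=(z, 0, 0), mask=s.mask),
                annotator_id="ground-truth",
            )
    return lws


def train_desk_spotter(slides, seed: int):
    """Train the pollen/background model on synthetic slides (all planes)."""
    return train_spotter(spotting_training_set(slides), DESK_SPOT_SPEC, seed)


def species_cv(slides, n_repeats: int, seed: int, cfg: WindowClassifierConfig | None = None):
    """Leave-2-slides-out species CV on the focal plane of each slide.

    ``slides`` are :class:`SyntheticSlide` objects with pure labels.
    """
    cfg = cfg or DESK_WINDOW_CFG
    triples = [(s.stack, s.mask, s.label) for s in slides]
    zf = [slides[0].spec.focus_plane]
    return cross_validate_slides(triples, cfg, n_repeats=n_repeats, seed=seed, z_planes=zf)
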