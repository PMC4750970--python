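"""Pass 2, grain-level species classification with confidence gating.

Random windows are sampled from a slide, kept only when more than a minimum
fraction of their pixels were spotted as pollen, and classified by a species
pixel model (the hashed classifier retrained with class-A/class-B labels on
pollen pixels of pure reference slides).  A window's *confidence* is the
absolute difference between its two class pixel fractions, in percent; the
classifier abstains below a confidence floor, and a minimum number of
classifications per slide is enforced by force-classifying the most confident
abstained windows.  Slide calls are majority votes over classified windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError, ParameterError
from .hashing import GridSpec, HashModel, accumulate_plane, predict_plane
from .imaging import ImageStack, Window, extract_window

#: Species-pass pixel-model optimum: 3x3 grid, spacing 10, quantization 14.24.
SPECIES_GRID_SPEC = GridSpec(grid_size=3, grid_spacing=10, quantization=14.24)


@dataclass
class WindowClassifierConfig:
    """Parameters of the window species classifier.

    Defaults reflect the reference operating point: 256-px windows, 1,232
    sampled per slide, >50% pollen content, 43.61% minimum confidence, at
    least 1 classification per slide.
    """

    window_size: int = 256
    windows_per_slide: int = 1232
    min_pollen_fraction: float = 0.5
    confidence_min: float = 43.61
    min_classifications_per_slide: int = 1
    spec: GridSpec = field(default_factory=lambda: SPECIES_GRID_SPEC)

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.windows_per_slide < 1:
            raise ParameterError("window_size and windows_per_slide must be >= 1")
        if not 0 <= self.min_pollen_fraction <= 1:
            raise ParameterError("min_pollen_fraction must be in [0, 1]")
        if not 0 <= self.confidence_min <= 100:
            raise ParameterError("confidence_min must be in [0, 100]")
        if self.min_classifications_per_slide < 1:
            raise ParameterError("min_classifications_per_slide must be >= 1")


def sample_windows(
    stack: ImageStack,
    mask_stack: np.ndarray,
    cfg: WindowClassifierConfig,
    seed: int,
    z_planes=None,
) -> list[Window]:
    """Sample ``cfg.windows_per_slide`` uniformly random window origins
    (seeded) and keep those whose spotted-pollen fraction exceeds
    ``cfg.min_pollen_fraction``.  Each kept window carries its pollen mask."""
    masks = np.asarray(mask_stack)
    if masks.ndim == 2:
        masks = masks[None]
    Z, H, W, _ = stack.shape
    s = cfg.window_size
    if s > H or s > W:
        raise InputError(f"window size {s} exceeds plane {H}x{W}")
    zs = list(range(Z)) if z_planes is None else list(z_planes)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(cfg.windows_per_slide):
        z = zs[rng.integers(len(zs))]
        r0 = int(rng.integers(H - s + 1))
        c0 = int(rng.integers(W - s + 1))
        m = masks[z if masks.shape[0] > 1 else 0, r0 : r0 + s, c0 : c0 + s]
        if float(m.mean()) > cfg.min_pollen_fraction:
            w = extract_window(stack, z, r0, c0, s, s)
            w.mask = m.astype(np.uint8)
            out.append(w)
    if not out:
        warnings.warn("no windows passed the pollen-content filter", stacklevel=2)
    return out


def window_confidence(frac_a: float, frac_b: float) -> float:
    """Confidence in percent: ``|frac_a - frac_b| * 100``.

    100 for a window classified entirely one class, 0 for an even split.
    """
    return abs(frac_a - frac_b) * 100.0


def train_species_model(
    windows: list[Window], labels, spec: GridSpec, seed: int
) -> HashModel:
    """Train the species pixel model on the pollen pixels of labelled windows.

    ``labels`` gives each window's slide class (0 = A, 1 = B); grid examples
    are created only for mask-positive (pollen) pixels.  Class A maps to the
    model's positive counts.
    """
    if len(windows) != len(labels) or not windows:
        raise InputError("need equally many windows and labels, at least one")
    model = HashModel.empty(spec, seed)
    for w, lab in zip(windows, labels):
        if w.mask is None:
            raise InputError("species training window lacks a pollen mask")
        pix_labels = np.full(w.mask.shape, 1 - int(lab))  # class A -> positive
        accumulate_plane(model, w.pixels, pix_labels, select=w.mask)
    return model


def classify_window(
    model: HashModel, window: Window, mask: np.ndarray | None = None,
    confidence_min: float = 0.0,
):
    """Classify one window's pollen pixels and gate on confidence.

    Returns ``(cls, confidence)`` where ``cls`` is 0 (class A), 1 (class B) or
    ``None`` for abstention (confidence below the floor, or no pollen pixels).
    """
    m = window.mask if mask is None else np.asarray(mask)
    if m is None:
        raise InputError("window has no pollen mask")
    sel = m.astype(bool)
    if not sel.any():
        return None, None
    labels, _, _ = predict_plane(model, window.pixels)
    frac_a = float(np.mean(labels[sel] == 1))  # positive counts = class A
    conf = window_confidence(frac_a, 1.0 - frac_a)
    cls = 0 if frac_a >= 0.5 else 1
    if conf < confidence_min:
        return None, conf
    return cls, conf


def classify_slide(model: HashModel, windows: list[Window], cfg: WindowClassifierConfig):
    """Slide-level call: majority vote over confidently classified windows.

    If fewer than ``cfg.min_classifications_per_slide`` windows pass the
    confidence gate, the most confident abstained windows are force-classified
    (descending confidence) until the minimum is met.  Vote ties go to the
    class with the larger summed confidence.

    Returns ``(slide_class, per_window)`` where ``per_window`` is a list of
    ``(cls_or_None, confidence, forced)`` records in input order.
    """
    if not windows:
        raise InputError("at least one window required")
    records = []
    for w in windows:
        cls, conf = classify_window(model, w, confidence_min=cfg.confidence_min)
        records.append([cls, conf, False])
    n_classified = sum(r[0] is not None for r in records)
    if n_classified < cfg.min_classifications_per_slide:
        candidates = [r for r in records if r[0] is None and r[1] is not None]
        candidates.sort(key=lambda r: -r[1])
        for r in candidates[: cfg.min_classifications_per_slide - n_classified]:
            r[2] = True
    return _finish_slide(model, windows, cfg, records)


def _finish_slide(model, windows, cfg, records):
    # fill in forced classifications (ungated) for flagged records
    for w, r in zip(windows, records):
        if r[2] and r[0] is None:
            cls, conf = classify_window(model, w, confidence_min=0.0)
            r[0] = cls
    votes = {0: 0, 1: 0}
    confs = {0: 0.0, 1: 0.0}
    for cls, conf, _ in records:
        if cls is not None:
            votes[cls] += 1
            confs[cls] += conf or 0.0
    if votes[0] == votes[1] == 0:
        return None, [tuple(r) for r in records]
    if votes[0] != votes[1]:
        slide_cls = 0 if votes[0] > votes[1] else 1
    else:
        slide_cls = 0 if confs[0] >= confs[1] else 1
    return slide_cls, [tuple(r) for r in records]


def cross_validate_slides(
    slides, cfg: WindowClassifierConfig, n_repeats: int, seed: int,
    n_test: int = 2, z_planes=None, stratified_test: bool = False,
):
    """Leave-``n_test``-slides-out cross-validation of slide classification.

    ``slides`` is a list of ``(stack, mask_stack, label)`` with binary class
    labels.  Each repeat holds out ``n_test`` random slides, trains the
    species pixel model on windows sampled from the rest, and scores the
    fraction of held-out slides called correctly.  Splits missing a class on
    the training side are resampled.  Returns ``(mean, std, per_repeat)``.
    """
    if len(slides) < 2 * n_test:
        raise InputError("need at least 2 * n_test slides")
    labels = np.asarray([s[2] for s in slides])
    if set(labels.tolist()) != {0, 1}:
        raise InputError("both classes must be present")
    rng = np.random.default_rng(seed)
    accs = []
    for rep in range(n_repeats):
        for _ in range(100):
            if stratified_test:
                # equal test labels keep the training set label-balanced,
                # removing the majority-class bias of leave-out splits
                per = n_test // 2
                idx0 = rng.choice(np.nonzero(labels == 0)[0], size=per, replace=False)
                idx1 = rng.choice(np.nonzero(labels == 1)[0], size=n_test - per, replace=False)
                test_idx = np.concatenate([idx0, idx1])
            else:
                test_idx = rng.choice(len(slides), size=n_test, replace=False)
            train_idx = np.setdiff1d(np.arange(len(slides)), test_idx)
            if len(set(labels[train_idx].tolist())) == 2:
                break
        else:
            raise InputError("could not draw a split with both classes")
        train_windows, train_labels = [], []
        for i in train_idx:
            stack, masks, lab = slides[i]
            ws = sample_windows(stack, masks, cfg, seed=int(rng.integers(2**31)),
                                z_planes=z_planes)
            train_windows.extend(ws)
            train_labels.extend([lab] * len(ws))
        model = train_species_model(
            train_windows, train_labels, cfg.spec, seed=int(rng.integers(2**31))
        )
        correct = 0
        for i in test_idx:
            stack, masks, lab = slides[i]
            ws = sample_windows(stack, masks, cfg, seed=int(rng.integers(2**31)),
                                z_planes=z_planes)
            if not ws:
                continue
            call, _ = classify_slide(model, ws, cfg)
            correct += int(call == lab)
        accs.append(correct / n_test)
    accs = np.asarray(accs)
    return float(accs.mean()), float(accs.std()), accs
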