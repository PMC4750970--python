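"""Pass 1 — pollen spotting.

Trains the hashed pixel classifier on expert-style labelled windows
(binary masks: 1 = pollen, 0 = background), predicts per-pixel pollen masks
for new imagery, and evaluates agreement by plain pixel accuracy over all
pixels, the same metric used for window-level leave-one-out cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError
from .hashing import GridSpec, HashModel, accumulate_plane, hash_plane, predict_plane
from .imaging import Window


@dataclass
class LabeledWindowSet:
    """Windows with binary pollen masks, one entry per (window, annotator).

    The same window labelled by several annotators appears once per
    annotator: annotator disagreement is kept as separate training examples
    rather than merged by vote.
    """

    windows: list = field(default_factory=list)
    annotator_ids: list = field(default_factory=list)

    def add(self, window: Window, annotator_id: str = "expert-0") -> None:
        if window.mask is None:
            raise InputError("labelled window requires a mask")
        self.windows.append(window)
        self.annotator_ids.append(annotator_id)

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def n_examples(self) -> int:
        """Total pixel-level training examples (pixels x annotations)."""
        return sum(w.pixels.shape[0] * w.pixels.shape[1] for w in self.windows)


def training_example_count(
    n_windows: int, window_shape: tuple, n_annotators: int
) -> int:
    """Bookkeeping helper: labelled pixel examples produced by a campaign of
    ``n_windows`` windows of ``window_shape`` each labelled by
    ``n_annotators`` annotators."""
    h, w = window_shape
    return n_windows * h * w * n_annotators


def train_spotter(labels: LabeledWindowSet, spec: GridSpec, seed: int) -> HashModel:
    """Train a pollen/background pixel model: one grid example per pixel per
    annotated mask."""
    if len(labels) < 1:
        raise InputError("at least one labelled window required")
    model = HashModel.empty(spec, seed)
    for w in labels.windows:
        if w.mask is None:
            raise InputError("window without mask in training set")
        accumulate_plane(model, w.pixels, w.mask)
    return model


def predict_mask(model: HashModel, window: Window) -> np.ndarray:
    """Per-pixel pollen mask (uint8 0/1) for a window; pixels are classified
    independently."""
    labels, _, _ = predict_plane(model, window.pixels)
    return labels


def pixel_agreement(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of pixels on which two masks agree (1 - normalised Hamming)."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise InputError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return float(np.mean(a == b))


def _window_bins_and_counts(labels: LabeledWindowSet, model: HashModel):
    """Per-window (bins, mask) plus per-window bin count contributions."""
    per_window = []
    for w in labels.windows:
        bins = hash_plane(w.pixels, model)
        per_window.append((bins, w.mask))
    return per_window


def loo_cross_validate(
    labels: LabeledWindowSet, spec: GridSpec, seed: int,
    per_fold: bool = False,
):
    """Leave-one-window-out cross-validation of the spotter.

    n windows give n folds; each fold trains on n-1 windows and scores pixel
    agreement on the held-out window.  Count arrays are additive, so each
    fold's model is the all-window model minus the held-out window's
    contribution — identical results to retraining per fold at a fraction of
    the cost.

    Returns the mean pixel agreement across folds (and the per-fold list when
    ``per_fold`` is set).
    """
    n = len(labels)
    if n < 2:
        raise InputError("need at least 2 windows for cross-validation")
    full = train_spotter(labels, spec, seed)
    per = _window_bins_and_counts(labels, full)
    scores = []
    for bins, mask in per:
        pos_sub = np.bincount(bins[mask.astype(bool)], minlength=spec.bins)
        neg_sub = np.bincount(bins[~mask.astype(bool)], minlength=spec.bins)
        pos = full.pos_counts - pos_sub
        neg = full.neg_counts - neg_sub
        pred = (pos[bins] > neg[bins]).astype(np.uint8)
        scores.append(pixel_agreement(pred, mask))
    mean = float(np.mean(scores))
    return (mean, scores) if per_fold else mean
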