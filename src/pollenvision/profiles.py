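"""Pass 2, mixture-ratio reconstruction from pixel-line profiles.

A *profile* is a vertical line of L contiguous pixels (single channel) lying
entirely inside spotted pollen, retained only when its *information content*

    IC = (1/n) * sum_i |x_i - x_{i+1}|,   n = L - 1

is at least a threshold (default 5.0 intensity units per pixel) — a cheap
focus/contrast score that keeps the machine's attention on in-focus exine
texture.

Classification uses distance *rules*: a rule is a reference profile plus a
Manhattan-distance "near/far" threshold; each side of the threshold predicts
the class with the larger joint count of training profiles falling there.
Rules are ranked by training error and the top k vote with equal weight; the
fraction of a slide's profiles voted class A is the slide's predicted mixture
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import InputError, ParameterError

#: Default profile length (pixels).
DEFAULT_PROFILE_LENGTH = 128
#: Default information-content threshold (intensity units per pixel).
DEFAULT_IC_MIN = 5.0


@dataclass
class Profile:
    """A vertical pixel line with provenance and optional class label."""

    values: np.ndarray
    source: tuple = ("", 0, 0, 0)  # (slide_id, z, row, col) of the top pixel
    label: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int64)
        if v.ndim != 1 or v.size < 2:
            raise InputError("profile needs >= 2 values in a 1-D line")
        self.values = v


def info_content(values) -> float:
    """Mean absolute difference of adjacent intensities (units: intensity per
    pixel).  Zero for a constant line; invariant to reversal and offsets."""
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1 or v.size < 2:
        raise InputError("information content needs >= 2 values")
    return float(np.mean(np.abs(np.diff(v))))


def manhattan(p, r) -> int:
    """Manhattan (L1) distance between two equal-length profiles."""
    p = np.asarray(p, dtype=np.int64)
    r = np.asarray(r, dtype=np.int64)
    if p.shape != r.shape:
        raise InputError(f"profile lengths differ: {p.shape} vs {r.shape}")
    return int(np.abs(p - r).sum())


def extract_profiles(
    plane: np.ndarray,
    mask: np.ndarray,
    length: int = DEFAULT_PROFILE_LENGTH,
    ic_min: float = DEFAULT_IC_MIN,
    stride: int = 1,
    channel: int = 0,
    class_map: np.ndarray | None = None,
    source: tuple = ("", 0),
) -> list[Profile]:
    """All vertical length-``length`` lines whose pixels are entirely
    mask-positive and whose information content is >= ``ic_min``.

    Scan order is column-major (left-to-right columns, top-to-bottom starts),
    deterministic.  ``stride`` subsamples both start rows and columns.  When a
    ``class_map`` is given (per-pixel class index, negative = background), a
    profile inherits a label if all its pixels share one class.
    """
    plane = np.asarray(plane)
    if plane.ndim == 3:
        plane = plane[:, :, channel]
    mask = np.asarray(mask).astype(bool)
    if mask.shape != plane.shape:
        raise InputError(f"mask shape {mask.shape} != plane shape {plane.shape}")
    H, W = plane.shape
    if length > H:
        raise InputError(f"profile length {length} exceeds plane height {H}")
    from numpy.lib.stride_tricks import sliding_window_view

    # windows[r, c, :] = column c rows [r, r+length)
    win = sliding_window_view(plane, length, axis=0)
    mwin = sliding_window_view(mask, length, axis=0)
    all_pollen = mwin.all(axis=-1)
    diffs = np.abs(np.diff(win.astype(np.int16), axis=-1))
    ic = diffs.mean(axis=-1)
    ok = all_pollen & (ic >= ic_min)
    if stride > 1:
        keep = np.zeros_like(ok)
        keep[::stride, ::stride] = True
        ok &= keep
    slide_id, z = source
    out: list[Profile] = []
    rs, cs = np.nonzero(ok)
    order = np.lexsort((rs, cs))  # column-major
    if class_map is not None:
        cwin = sliding_window_view(np.asarray(class_map), length, axis=0)
    for i in order:
        r, c = int(rs[i]), int(cs[i])
        label = None
        if class_map is not None:
            cls = cwin[r, c]
            if (cls == cls[0]).all() and cls[0] >= 0:
                label = int(cls[0])
        out.append(Profile(win[r, c].copy(), source=(slide_id, z, r, c), label=label))
    return out


def slide_profiles(
    stack,
    mask,
    length: int = DEFAULT_PROFILE_LENGTH,
    ic_min: float = DEFAULT_IC_MIN,
    z_step: int = 5,
    stride: int = 1,
    channel: int = 0,
    class_map: np.ndarray | None = None,
) -> list[Profile]:
    """Pool profiles from every ``z_step``-th plane of a slide stack.

    ``mask`` may be a single (H, W) mask shared by all planes (fixed grain
    geometry) or an (Z, H, W) stack of per-plane masks.
    """
    mask = np.asarray(mask)
    out: list[Profile] = []
    for z in range(0, stack.n_planes, z_step):
        m = mask if mask.ndim == 2 else mask[z]
        out.extend(
            extract_profiles(
                stack.planes[z], m, length=length, ic_min=ic_min, stride=stride,
                channel=channel, class_map=class_map,
                source=(stack.slide_id, z),
            )
        )
    return out


@dataclass
class ProfileRule:
    """A reference profile with an optimised near/far distance threshold.

    ``near_counts``/``far_counts`` are per-class training counts on each side
    of the threshold; ``near_class``/``far_class`` the majority predictions.
    """

    reference: np.ndarray
    threshold: int
    near_counts: np.ndarray  # shape (2,): class 0, class 1
    far_counts: np.ndarray
    near_class: int
    far_class: int
    error_rate: float

    def predict(self, profiles: np.ndarray) -> np.ndarray:
        """Class of each row of an (n, L) profile matrix."""
        d = np.abs(np.asarray(profiles, dtype=np.int64) - self.reference).sum(axis=1)
        return np.where(d <= self.threshold, self.near_class, self.far_class)


def evaluate_rule(candidate, train_profiles, train_labels) -> ProfileRule:
    """Turn one candidate profile into a rule.

    Scans every distinct Manhattan distance from the candidate to the training
    profiles as a near/far threshold ("near" = distance <= threshold); each
    bin predicts the class with the larger joint training count; picks the
    threshold with the lowest training error (smallest threshold on ties).
    """
    cand = np.asarray(candidate, dtype=np.int64)
    X = np.asarray(train_profiles, dtype=np.int64)
    y = np.asarray(train_labels)
    if X.ndim != 2 or X.shape[0] < 1:
        raise InputError("non-empty (n, L) training matrix required")
    if X.shape[1] != cand.size:
        raise InputError("candidate/training profile lengths differ")
    d = np.abs(X - cand).sum(axis=1)
    n = d.size
    order = np.argsort(d, kind="stable")
    ds, ys = d[order], y[order]
    # cumulative class counts at each candidate threshold position
    is1 = (ys == 1).astype(np.int64)
    cum1 = np.cumsum(is1)
    cum0 = np.cumsum(1 - is1)
    tot1, tot0 = int(cum1[-1]), int(cum0[-1])
    if tot0 == 0 or tot1 == 0:
        # degenerate: single-class training set; any threshold is perfect
        only = 1 if tot0 == 0 else 0
        return ProfileRule(
            reference=cand, threshold=int(ds[-1]),
            near_counts=np.array([tot0, tot1]), far_counts=np.array([0, 0]),
            near_class=only, far_class=only, error_rate=0.0,
        )
    # last index of each distinct distance = inclusive "near" cut
    last = np.nonzero(np.r_[ds[1:] != ds[:-1], True])[0]
    near0, near1 = cum0[last], cum1[last]
    far0, far1 = tot0 - near0, tot1 - near1
    correct = np.maximum(near0, near1) + np.maximum(far0, far1)
    best = int(np.argmax(correct))  # argmax takes the first (smallest thr) tie
    i = last[best]
    thr = int(ds[i])
    n0, n1 = int(near0[best]), int(near1[best])
    f0, f1 = int(far0[best]), int(far1[best])
    near_class = 1 if n1 > n0 else 0
    far_class = 1 if f1 > f0 else 0
    err = 1.0 - float(correct[best]) / n
    return ProfileRule(
        reference=cand, threshold=thr,
        near_counts=np.array([n0, n1]), far_counts=np.array([f0, f1]),
        near_class=near_class, far_class=far_class, error_rate=err,
    )


def train_rules(
    train_profiles, train_labels, n_candidates: int = 1024, seed: int = 0
) -> list[ProfileRule]:
    """Evaluate ``n_candidates`` candidate rules whose references are drawn
    uniformly at random (seeded, with replacement) from the training
    profiles; returns the rules in evaluation order."""
    X = np.asarray(train_profiles, dtype=np.int64)
    y = np.asarray(train_labels)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InputError("need an (n>=2, L) training matrix")
    if n_candidates < 1:
        raise ParameterError("n_candidates must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(X.shape[0], size=min(n_candidates, 10**7))
    return [evaluate_rule(X[i], X, y) for i in idx]


@dataclass
class RuleEnsemble:
    """Top-k rules by ascending training error, equal vote weight.

    ``prior_class`` breaks even-vote ties (class with the larger training
    prior; class 0 when equal)."""

    rules: list
    k: int
    prior_class: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError(f"k must be >= 1, got {self.k}")


def build_ensemble(rules: Sequence[ProfileRule], k: int, prior_class: int = 0) -> RuleEnsemble:
    """Rank rules by training error (stable: first-evaluated wins ties) and
    keep the top k."""
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if k > len(rules):
        raise ParameterError(f"k={k} exceeds number of rules {len(rules)}")
    order = np.argsort([r.error_rate for r in rules], kind="stable")
    return RuleEnsemble(rules=[rules[i] for i in order[:k]], k=k, prior_class=prior_class)


def save_rules(ensemble: RuleEnsemble, path) -> None:
    """Serialise a rule ensemble to JSON (reference values, threshold,
    class distributions, error rate)."""
    import json
    from pathlib import Path

    doc = {
        "format_version": 1,
        "k": ensemble.k,
        "prior_class": ensemble.prior_class,
        "rules": [
            {
                "reference": np.asarray(r.reference).tolist(),
                "threshold": r.threshold,
                "near_counts": np.asarray(r.near_counts).tolist(),
                "far_counts": np.asarray(r.far_counts).tolist(),
                "near_class": r.near_class,
                "far_class": r.far_class,
                "error_rate": r.error_rate,
            }
            for r in ensemble.rules
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_rules(path) -> RuleEnsemble:
    import json
    from pathlib import Path

    doc = json.loads(Path(path).read_text())
    rules = [
        ProfileRule(
            reference=np.asarray(r["reference"], dtype=np.int64),
            threshold=int(r["threshold"]),
            near_counts=np.asarray(r["near_counts"]),
            far_counts=np.asarray(r["far_counts"]),
            near_class=int(r["near_class"]),
            far_class=int(r["far_class"]),
            error_rate=float(r["error_rate"]),
        )
        for r in doc["rules"]
    ]
    return RuleEnsemble(rules=rules, k=int(doc["k"]), prior_class=int(doc["prior_class"]))


def classify_profiles(ensemble: RuleEnsemble, profiles) -> np.ndarray:
    """Equal-weight majority vote over the ensemble for each profile row."""
    X = np.atleast_2d(np.asarray(profiles, dtype=np.int64))
    votes1 = np.zeros(X.shape[0], dtype=np.int64)
    for rule in ensemble.rules[: ensemble.k]:
        votes1 += rule.predict(X)
    k = ensemble.k
    pred = np.where(votes1 * 2 > k, 1, np.where(votes1 * 2 < k, 0, ensemble.prior_class))
    return pred.astype(np.int64)


def classify_profile(ensemble: RuleEnsemble, profile) -> int:
    """Single-profile convenience wrapper around :func:`classify_profiles`."""
    return int(classify_profiles(ensemble, np.atleast_2d(profile))[0])


def predict_slide_ratio(ensemble: RuleEnsemble, slide_profiles) -> float | None:
    """Fraction of a slide's profiles voted class A (class 0).

    Returns ``None`` (abstention) when the slide produced no profiles.
    """
    X = np.asarray(slide_profiles)
    if X.size == 0:
        return None
    pred = classify_profiles(ensemble, X)
    return float(np.mean(pred == 0))


def r_squared(predicted, actual) -> float:
    """Coefficient of determination of the least-squares regression of
    predicted on actual mixture fractions."""
    p = np.asarray(predicted, dtype=np.float64)
    a = np.asarray(actual, dtype=np.float64)
    if p.shape != a.shape or p.size < 3:
        raise InputError("need >= 3 paired values")
    if np.ptp(a) == 0:
        raise InputError("actual ratios are constant; r^2 undefined")
    if np.ptp(p) == 0:
        return 0.0  # a constant prediction explains none of the variance
    return float(stats.linregress(a, p).rvalue ** 2)
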