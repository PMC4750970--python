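"""Hyperparameter search harnesses and learning curves.

Two strategies mirror the two passes of the pipeline: greedy
one-dimension-at-a-time coordinate descent over discrete, ordered value lists
(the parameters are discrete, so gradient methods do not apply), and seeded
uniform random search over a mixed discrete/continuous space.  Objectives are
arbitrary callables (typically cross-validated accuracies); evaluations are
cached per parameter point because CV objectives are expensive and
deterministic given their seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError, ParameterError

log = logging.getLogger(__name__)


@dataclass
class ParamSpace:
    """Named search dimensions.

    Each dimension is either a finite ordered list of values (discrete) or a
    ``("uniform", lo, hi)`` tuple (continuous, random search only).
    """

    dims: dict

    def __post_init__(self) -> None:
        if not self.dims:
            raise ParameterError("empty parameter space")
        for name, vals in self.dims.items():
            if isinstance(vals, tuple) and len(vals) == 3 and vals[0] == "uniform":
                continue
            if len(list(vals)) == 0:
                raise ParameterError(f"dimension {name!r} is empty")

    def is_continuous(self, name: str) -> bool:
        v = self.dims[name]
        return isinstance(v, tuple) and len(v) == 3 and v[0] == "uniform"


@dataclass
class SearchTrace:
    """Evaluated points with objective values; ``best`` maximises the trace."""

    points: list = field(default_factory=list)  # (params dict, score)

    def record(self, params: dict, score: float) -> None:
        self.points.append((dict(params), float(score)))

    @property
    def best(self):
        if not self.points:
            raise InputError("empty trace")
        i = int(np.argmax([s for _, s in self.points]))
        return self.points[i]

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(p, score=s) for p, s in self.points]
        return pd.DataFrame(rows)


class _CachedObjective:
    def __init__(self, objective):
        self.objective = objective
        self.cache: dict = {}

    def __call__(self, params: dict):
        key = tuple(sorted(params.items()))
        if key not in self.cache:
            try:
                self.cache[key] = float(self.objective(params))
            except Exception as e:  # point skipped, search continues
                log.warning("objective failed at %s: %s", params, e)
                self.cache[key] = None
        return self.cache[key]


def coordinate_descent(space: ParamSpace, objective, start: dict) -> SearchTrace:
    """Greedy one-dimension-at-a-time search.

    Dimensions are swept in declaration order with the others held at the
    current best.  Along a dimension the search advances from the current
    value towards larger list positions while the objective strictly
    improves, stopping at the first non-improvement (the value lists encode
    the step schedule, e.g. powers of two).  One full cycle; the result is
    never worse than the start.
    """
    for name in space.dims:
        if space.is_continuous(name):
            raise ParameterError(f"coordinate descent needs a discrete dim: {name}")
        if start[name] not in list(space.dims[name]):
            raise ParameterError(f"start value for {name!r} not in its value list")
    f = _CachedObjective(objective)
    trace = SearchTrace()
    current = dict(start)
    best_score = f(current)
    if best_score is None:
        raise InputError("objective failed at the start point")
    trace.record(current, best_score)
    for name in space.dims:
        values = list(space.dims[name])
        i = values.index(current[name])
        while i + 1 < len(values):
            trial = dict(current, **{name: values[i + 1]})
            s = f(trial)
            if s is not None:
                trace.record(trial, s)
            if s is None or s <= best_score:
                break
            current, best_score = trial, s
            i += 1
    return trace


def random_search(space: ParamSpace, objective, n_points: int, seed: int) -> SearchTrace:
    """Seeded uniform sampling of the space: discrete dims uniform over their
    value list, continuous dims uniform on their interval."""
    if n_points < 1:
        raise ParameterError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    trace = SearchTrace()
    for _ in range(n_points):
        params = {}
        for name, vals in space.dims.items():
            if space.is_continuous(name):
                _, lo, hi = vals
                params[name] = float(rng.uniform(lo, hi))
            else:
                vals = list(vals)
                params[name] = vals[int(rng.integers(len(vals)))]
        try:
            score = float(objective(params))
        except Exception as e:
            log.warning("objective failed at %s: %s", params, e)
            continue
        trace.record(params, score)
    if not trace.points:
        raise InputError("every sampled point failed")
    return trace


def learning_curve(
    train_pool: list, sizes, reps: int, evaluator, seed: int
) -> pd.DataFrame:
    """Accuracy as a function of training-set size.

    For each size in ``sizes``, draws ``reps`` seeded subsamples (without
    replacement) of the pool and calls ``evaluator(subset, seed)``.  Returns a
    tidy frame with columns ``size``, ``rep``, ``accuracy``.
    """
    sizes = list(sizes)
    if any(s > len(train_pool) or s < 1 for s in sizes):
        raise InputError("sizes must be within [1, len(train_pool)]")
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        for rep in range(reps):
            idx = rng.choice(len(train_pool), size=size, replace=False)
            sub = [train_pool[i] for i in idx]
            acc = float(evaluator(sub, int(rng.integers(2**31))))
            rows.append({"size": size, "rep": rep, "accuracy": acc})
    return pd.DataFrame(rows)
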