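"""Hyperparameter search over the spotting feature parameters.

Runs the two search strategies against a leave-one-window-out CV objective on
a small labelled set: greedy one-dimension-at-a-time coordinate descent over
powers-of-two value lists (the pass-1 strategy) and seeded uniform random
search (the pass-2 strategy).
"""

from pollenvision import (
    GridSpec,
    ParamSpace,
    coordinate_descent,
    loo_cross_validate,
    random_search,
)
from pollenvision.study import make_reference_slides, spotting_training_set

labelled = spotting_training_set(make_reference_slides(seed=42)[:4], planes="focus")

space = ParamSpace({
    "grid_size": [1, 2, 4, 8],
    "grid_spacing": [1, 2, 4, 8],
    "quantization": [1, 2, 4, 8, 16, 32, 64, 128],
})


def objective(p):
    spec = GridSpec(grid_size=p["grid_size"], grid_spacing=p["grid_spacing"],
                    quantization=p["quantization"], bins=50_021)
    return loo_cross_validate(labelled, spec, seed=0)


trace = coordinate_descent(space, objective,
                           start={"grid_size": 1, "grid_spacing": 1, "quantization": 1})
best, score = trace.best
print(f"coordinate descent: {best} -> CV agreement {score:.4f} "
      f"({len(trace.points)} evaluations)")

trace = random_search(space, objective, n_points=12, seed=3)
best, score = trace.best
print(f"random search:      {best} -> CV agreement {score:.4f} "
      f"({len(trace.points)} evaluations)")
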