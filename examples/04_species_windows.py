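"""Pass 2, experiment 2: confidence-gated window species calls.

Trains the species pixel model on pollen pixels of pure slides, classifies
random high-pollen-content windows of held-out slides, abstains below the
43.61% confidence floor, and aggregates window votes into slide calls.
Finishes with leave-2-slides-out cross-validation.
"""

import numpy as np

from pollenvision import classify_slide, sample_windows, train_species_model
from pollenvision.study import DESK_WINDOW_CFG, make_reference_slides, species_cv

slides = make_reference_slides(seed=42)
cfg = DESK_WINDOW_CFG
focus = [slides[0].spec.focus_plane]

train = [s for s in slides if "indiv0" in s.stack.slide_id]
test = [s for s in slides if "indiv1" in s.stack.slide_id]

rng = np.random.default_rng(17)
windows, labels = [], []
for s in train:
    ws = sample_windows(s.stack, s.mask, cfg, seed=int(rng.integers(2**31)), z_planes=focus)
    windows += ws
    labels += [s.label] * len(ws)
model = train_species_model(windows, labels, cfg.spec, seed=int(rng.integers(2**31)))
print(f"trained on {len(windows)} windows (> {cfg.min_pollen_fraction:.0%} pollen each)")

for s in test:
    ws = sample_windows(s.stack, s.mask, cfg, seed=int(rng.integers(2**31)), z_planes=focus)
    call, records = classify_slide(model, ws, cfg)
    confident = sum(r[0] is not None and not r[2] for r in records)
    print(f"{s.stack.slide_id}: true class {s.label}, called {call} "
          f"({confident}/{len(ws)} windows above the {cfg.confidence_min}% gate)")

mean, std, _ = species_cv(slides, n_repeats=10, seed=5)
print(f"\nleave-2-slides-out CV accuracy: {mean:.3f} +/- {std:.3f}")
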