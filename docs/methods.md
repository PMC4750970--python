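# Methods

## The hashed-histogram pixel classifier

A pixel's feature vector is a square lattice of `grid_size**2` neighbouring
intensities, sampled `grid_spacing` pixels apart and centred on the pixel
(top-left-biased for even sizes: offsets run from `-floor((g-1)/2)*s` to
`+ceil((g-1)/2)*s`). Off-plane samples are clamped to the border (edge
replication), so every pixel of a plane is classifiable. Intensities are
quantized to `floor(v / q)`; `q` may be fractional (searched operating points
land on values like 14.24), giving `Q = floor(max_intensity / q) + 1` levels.
The default intensity bound is 255 (8-bit); it is configurable because
acquisition pipelines differ in how they scale luminance.

Hashing sums one random 64-bit number per (lattice slot, channel, level) —
drawn once from a seeded PCG64 generator and regenerated from the stored seed
on model load — with wraparound modulo 2^64, then reduces modulo `B` counting
bins (default 2,048,000; two int64 count arrays at that size serialize to
~32 MB). Identical neighbourhoods always collide; unrelated ones collide with
probability ~1/B (the test suite checks bin occupancy against a chi-square
bound). Training is a single pass that increments per-bin class counts, so
models are additive: leave-one-window-out cross-validation subtracts the
held-out window's counts instead of retraining, which the tests verify
against explicit per-fold retraining.

Ties (`pos == neg`, including unseen 0/0 bins) classify as the negative
class. For segmentation the negative class is background — by far the
majority phenomenon on a slide — so unseen texture defaults to background;
the species model inherits the same primitive with class B as the negative
side.

## Profiles and distance rules

Profiles are vertical single-channel pixel lines (column-major scan, stride
configurable) that lie entirely inside spotted pollen and pass the
information-content floor `IC >= 5.0` intensity units/pixel. IC is the mean
absolute difference of adjacent intensities: a cheap focus/contrast score
(defocused texture has small adjacent differences). Horizontal/diagonal
orientations are out of scope.

A candidate rule is a training profile; its near/far threshold is chosen by
exhaustive scan over the distinct Manhattan distances from the candidate to
the training set ("near" means `d <= t`), minimising training error with the
smallest threshold winning ties. Each side predicts the class with the larger
joint training count. The stated alternative objective for this search
("information content of the image") is not operational; error minimisation
is consistent with ranking rules by their discriminative power and is what
the implementation uses. Ensembles keep the top-k rules by training error
(stable sort: first-evaluated wins ties) with equal vote weight; even-vote
ties break toward the class with the larger training prior, class A when
equal. A slide's predicted mixture is the raw voted class-A fraction,
uncalibrated, since the evaluation regresses predictions against truth rather
than calibrating them.

## Window species classification

Windows are sampled at seeded uniform origins and kept when their spotted
pollen fraction strictly exceeds `min_pollen_fraction` (0.5). Confidence is
`|frac_A - frac_B| * 100` over the window's classified pollen pixels; windows
below `confidence_min` abstain. If fewer than
`min_classifications_per_slide` windows pass, the most confident abstentions
are force-classified in descending confidence order. Slide calls are majority
votes over classified windows, ties broken by summed confidence. Slide-level
cross-validation holds out 2 of 12 slides per repeat; an optional stratified
mode draws one test slide per class so the training set stays label-balanced
(see "Permutation null" below).

## Parameter search

Coordinate descent sweeps dimensions in declaration order, advancing along
each ordered value list (typically powers of two) while the objective
strictly improves and stopping at the first non-improvement; one cycle by
default, never worse than its start. Random search samples discrete
dimensions uniformly from their lists and continuous dimensions uniformly on
their intervals, all from one seeded generator. Objective evaluations are
cached per parameter point (CV objectives are deterministic given their
seeds); failed evaluations are logged and skipped.

## The synthetic slide simulator

Slides are bright noisy backgrounds (mean 225, sd 6) carrying non-overlapping
circular grains (default 100 per slide; exact class counts
`round(ratio * n)`), all sharing a mean grain intensity of 120. The two
classes differ only in texture: unit-variance Gaussian-band-pass speckle with
class-specific smoothing scale, vertical anisotropy and contrast (class A:
scale 1 px, contrast 55; class B: scale 2 px, contrast 22). These defaults
are chosen so the classes satisfy the designed invariant that mean
within-class profile Manhattan distance is smaller than between-class
distance — with equal contrasts that invariant fails, because L1 distance
between zero-mean textures is driven by summed variances. One z-plane is
rendered sharp; the others are Gaussian-blurred in proportion to their focal
offset (1.5 px/plane). Grain geometry is fixed across z, so ground-truth
masks are plane-independent. "Individuals" are modelled as multiplicative
texture-parameter jitter (±15%) shared across an individual's replicate
slides, so held-out individuals differ systematically from training ones.

What the simulator does *not* emulate: real exine ornamentation (rendered
speckle is statistically, not morphologically, realistic), grain overlap and
clumping, scanner artifacts (stitching, illumination falloff), chromatic
information (single channel by default), and within-slide focus variation
(one shared focal depth instead of per-grain focus). Passing tests therefore
demonstrate that the algorithms recover known structure of this model family,
not field-ready accuracy on real slides.

## Desk-scale study conditions

The canonical conditions in `pollenvision.study` use 416-px slides, 20 grains
of radius 22–30 px, 3 z-planes, profile length 32 and 100,003 bins, chosen so
every pipeline (12 reference slides + 22 ratio slides end to end) runs in
seconds. Classifier operating points at this scale (spotting grid 2×2,
spacing 2, q=32; species grid 2×2, spacing 1, q=64) were selected with the
package's own cross-validated searches, exactly as the full-scale operating
points (spotting 8×8/8/10; species 3×3/10/14.24, confidence 43.61%, minimum
1 call/slide) were obtained in the original workflow; the full-scale values
remain the documented defaults of the config types. Synthetic background
noise is pixel-independent — unlike the spatially correlated sensor noise of
real scans — which is why desk-scale optima favour coarser quantization and
smaller grids than the full-scale ones.

Species-pass analyses (window sampling, profile extraction) read the focal
plane. The simulator renders a single in-focus depth per slide, and defocus
blur genuinely converts the fine-textured class into coarse-looking texture,
so off-focus windows are confidently wrong rather than unconfident; on real
stacks each grain is sharp at some depth, making plane selection the
per-tile focus choice any whole-slide pipeline performs. Pass-1 spotting
trains and evaluates on all planes.

Ratio-classifier training balances the pooled profiles per class before rule
evaluation: the finer-textured class passes the IC filter far more often, and
rules trained at the natural mix collapse toward majority-class predictors.
The ensemble-size experiment deliberately uses the natural (unbalanced) mix,
which reproduces the characteristic rise-then-fall of accuracy with ensemble
size: once the ranking exhausts genuinely discriminative rules it admits
majority-biased ones, and large ensembles degrade.

The permutation null uses stratified test draws. With unstratified leave-2-out
splits and uninformative labels, removing two same-label slides biases the
training majority toward the opposite label, producing the well-known
below-chance pathology of leave-out estimates under permutation; stratifying
the test pair keeps training label-balanced and the estimate at chance.

## Numerical and degenerate-input conventions

64-bit sums wrap modulo 2^64 (unsigned numpy arithmetic) before the modulo-B
reduction. Single-class rule training yields a degenerate constant rule with
error 0 by convention. Empty profile sets abstain (`None`) rather than
returning a ratio; r² on a constant prediction is 0, and a constant truth
vector is rejected as undefined. All randomness flows through explicit
integer seeds (stored in models and provenance records); repeated runs are
bit-identical.
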