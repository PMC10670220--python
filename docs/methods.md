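# Methods

This note records what the package computes, the conventions it fixes
where multiple reasonable choices exist, and what its synthetic harness
does and does not establish about real data.

## Masks, polarity, and thresholds

All continuous segmentation outputs ("logit masks") are exchanged as 8-bit
score masks. Real-valued model outputs enter through a per-image min–max
map onto [0, 255] (half-away-from-zero rounding); a constant input maps to
all zeros, on the view that an uninformative mask should claim no
foreground. PNG is the canonical storage format because the test suite
depends on bit-exact round trips; JPG is accepted read-only for
compatibility with pipelines that stored masks lossily.

Polarity is explicit everywhere. Promptable segmentators typically emit
high bytes for foreground while some conventional pipelines do the
opposite, so every `ScoreMask` carries a `foreground_high` /
`foreground_low` tag and the canonical internal polarity is
foreground-high; a foreground-low mask is reconciled by the involution
s ↦ 255 − s.

Binarization interprets its margin in the mask's *native* convention. For
a foreground-high mask, foreground is `score ≥ t`. For a foreground-low
mask with margin `t`, foreground is `255 − score ≥ 256 − t` — the 256 (not
255) complement makes the two rules partition the byte range identically,
so the strict margin 32 keeps exactly the scores 0–31. The default margin
is 128; the `strict32` preset restricts prompt extraction to the most
confident core of a foreground-low source mask while fusion still uses the
original continuous scores.

## Blobs and border mode

Foreground components are 8-connected: diagonal contact joins a blob,
which avoids splitting thin diagonal structures. Blobs are ordered by
(row_min, col_min, area) so labelling is deterministic.

Border mode erodes the source mask before prompt extraction so that
prompts keep away from unreliable boundaries. The structuring element is
the filled digital ellipse inscribed in a 10×10 box: pixel (i, j) belongs
iff ((i−4.5)/5)² + ((j−4.5)/5)² ≤ 1, a construction symmetric under flips
of either axis. Even-sized kernels have no center pixel; the anchor is
fixed at (4, 4) (upper-left of center), and out-of-image neighbourhood
counts as background, so border pixels erode away. Erosion is applied to
the whole mask and components are re-labelled afterwards; a blob erased
entirely by erosion is, by default, rescued by falling back to its
un-eroded pixel set (`rescue_on_empty_erosion`), since otherwise small
objects would silently receive no prompts.

## Checkpoint methods

- **A** returns the bounding-box center (half-away-from-zero rounding).
  It is deliberately allowed to fall outside concave blobs — that failure
  mode is part of what the method comparison studies.
- **B** returns the pixel centroid rounded to a pixel; if that pixel is
  not in the blob, the blob pixel nearest the real-valued centroid is used
  (ties by (row, col) order), so B always lies inside its blob.
- **C** draws uniformly from the blob's lexicographically sorted pixel
  list with a generator seeded by (seed, blob id): reproducible, and
  different blobs of one mask get independent draws.
- **D** lays the global lattice {(i·b, j·b)} anchored at the image origin
  and emits every lattice point inside a blob. A blob missed by the
  lattice triggers a per-blob fallback that shifts the lattice one pixel
  at a time — horizontally first (dx = 1…b−1 at dy = 0), then row-major
  over dy = 1…b−1, dx = 0…b−1 — and stops at the first shift hitting the
  blob. The enumerated shifts cover every residue class of the lattice,
  which proves termination and the invariant that every nonempty blob
  contributes at least one checkpoint. The shift step of one pixel is the
  smallest that makes this coverage argument exact.

Prompts serialize as JSON with (x = col, y = row), the axis convention of
point-prompt segmentators. In-memory everything is (row, col), 0-based.

## Fusion

The fused score is the weight-normalized average
(w₁·s₁ + w₂·s₂)/(w₁+w₂), rounded half away from zero, thresholded at 128
with ties to foreground. Dividing by the weight sum keeps the result on
the byte scale, so one fixed threshold works for any weights — an
unnormalized sum would demand a weight-dependent margin. Defaults w₁ = 2
(conventional segmentator), w₂ = 1 (promptable): the zero-shot mask is the
noisier voter. Both weights are configurable; the fused score is a convex
combination, hence bounded by the per-pixel envelope of the inputs, and at
extreme weight ratios the binarization converges to the dominant input's
own binarization.

## Metrics

IoU, Dice, and MAE follow their set definitions on binary inputs; an
empty-vs-empty pair scores as a perfect prediction of absence
(IoU = Dice = 1, MAE = 0), avoiding 0/0.

The **weighted F-measure** uses β² = 1, a 7×7 Gaussian with σ = 5
(zero-padded correlation), and the exponential distance weighting
B = 2 − 2^(−d/5) for false positives at Euclidean distance d from the true
object. The background error substitution takes the **mean over all tied
nearest foreground pixels** rather than an arbitrary one of them: pixel
distances are integers squared, so the tied set is recovered exactly, the
measure is deterministic, and it is exactly invariant under flips and
transposition. An empty ground truth scores 1 against an empty prediction
and 0 otherwise. One consequence of zero-padded smoothing worth knowing:
for a true object touching the image border, part of the smoothing window
falls outside the image and a completely missed object does not score
exactly zero.

The **E-measure** mean-centers both binary maps, computes the per-pixel
alignment 2·dP·dT/(dP² + dT²) — the denominator is strictly positive for a
mixed ground truth — enhances it as ((align+1)/2)², and averages over all
pixels, so an exact mixed match scores exactly 1 and values stay in
[0, 1] on masks of any size. Degenerate ground truths use the conventions
mean(1 − P) (all background) and mean(P) (all foreground). Note the
measure is not monotone under single-pixel corrections: a flip moves the
prediction mean and can lower alignment elsewhere; only the global optimum
(P = T) is characterized.

Dataset aggregation is the unweighted arithmetic mean over images; pairs
failing validation are excluded and counted.

## Synthetic harness

The generator draws `n_blobs` ellipses (default) or radially perturbed
polygons with radii 8–15 px in a 128×128 frame, rejection-sampled so
bounding circles stay ≥ 2 px apart (the minimum for 8-connected
separability) and the component count is verifiable. The degradation
model mimics independent failure modes of real segmentators — per-blob
boundary dilation/erosion up to ±`boundary_jitter` px, whole-blob dropout,
Poisson-many spurious small blobs, and clipped additive Gaussian score
noise — so tests can switch each on in isolation.

The mock promptable backend expands a prompt into the entire ground-truth
blob beneath it and ignores prompts on background; its output is degraded
by Gaussian score noise with sd = 255·(1 − fidelity) gray levels, so
fidelity 1 is a perfect oracle and fidelity 0 is noise at the full byte
range. This "a prompt selects its object" semantics makes prompt
*coverage*, not prompt count, the driver of recall — the property that
separates the lattice method D from the single-point methods A–C.

What passing tests show: the algorithmic contracts (lattice + fallback,
erosion, fusion arithmetic, metric definitions) hold exactly, and under
this noise model fusing a noisy source with a good prompted backend
improves mean IoU (paired sign test, 200 scenes). What they cannot show:
anything about real images — semantic confusions, correlated (non-Gaussian)
errors, texture-driven failures of a real promptable model, or the right
fusion weights for a specific dataset.

## Problem sizes and experiment defaults

Desk-scale experiments use 128×128 scenes with 3 blobs, lattice step
b = 8 (comfortably below the minimum blob diameter of 16, so every blob is
hit without fallback), source degradation sd 40 with ±2 px jitter, and
backend fidelity 0.85 for the fusion-benefit experiment; 20 scenes suffice
for the exact oracle-recovery check and 200 for the stochastic benefit
comparison. The acceptance script derives all per-scene seeds from its
`--seed` argument via `numpy.random.SeedSequence`.

## Known limitations

- Only two-way fusion with global scalar weights; no per-pixel or learned
  weighting.
- Box/text prompts and negative (background) points are out of scope.
- The weighted F-measure and E-measure are defined here for binary
  predictions; continuous maps must be thresholded first.
- JPG inputs are decoded as-is; lossy artifacts become part of the scores.
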