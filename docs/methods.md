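# Methods

## The problem

Plot-level UAV images of maize trials mix four pixel populations — soil,
shadow, foliage and tassels — and the quantity of interest is the number of
tassels per plot. The package implements two complementary routes to that
number: isolating tassel pixels with color-index filters and counting the
surviving components (counting by detection), and regressing local counts
from raw image patches via a density map (counting by regression, CBR).

## Color indices and the two-step filter

All indices operate on channel-normalized values R\*, G\*, B\* ∈ [0, 1].
Excess Green (ExG = 2G\* − R\* − B\*) is large for green vegetation; Excess
Red (ExR = 1.4R\* − G\*) and the tassel index ((2(G\* + R\*))² − B\*) are
large for reddish/yellowish pixels. The tassel index intentionally rewards
pixels with high red *and* green but low blue — yellow — which separates
tassels from foliage after ExG has removed the background.

Two parses of the tassel formula are plausible from its compact notation;
the default follows the verbal description (combine red and green, double,
then square), and the alternative `(2G* + R*)² − B*` is available via
`tassel_index(..., variant="compact")` so the two can be compared.

Design choices that matter:

* **Fixed-range rescaling.** Each raw index is mapped linearly onto
  [0, 255] using its *theoretical* range over the RGB cube (ExG [−2, 2],
  ExR [−1, 1.4], tassel [−1, 16]), not per-image min–max. A single
  threshold is only transferable across an image set if the mapping is
  image-independent.
* **Threshold convention.** A pixel is eliminated iff its rescaled score is
  strictly below the threshold (ties survive). Rescaled scores stay
  floating-point; quantizing them would create staircase artifacts in the
  sweep curves.
* **Independent masks.** Step-2 scores are computed on the original pixel
  colors, not on the step-1 output raster; the surviving set is the
  intersection of the two masks. Blacked-out pixels would score −1 anyway,
  but computing on originals makes the masks order-independent and
  separately auditable.

## Pixel sampling

Filter quality is measured on class-labeled sample pixels: copies of the
images are marked with four pure colors (blue = soil, green = shadow,
red = foliage, yellow = tassel), the index is evaluated on the
corresponding pixels of the unmarked originals, and per-class elimination
fractions are tabulated at all 257 integer thresholds 0…256 (the extra
endpoint represents total elimination). Marker matching is exact by
default; a per-channel tolerance exists for hand-marked data, and
overlapping marks of different classes are rejected as annotation errors.

## Counting by regression

A unit-mass bivariate Gaussian of bandwidth σ = 8 px (interpreted as the
standard deviation) is placed at each annotated center. Kernels are
evaluated on the integer pixel grid, truncated at ±4σ and at the image
borders, then renormalized per point, so density mass equals the point
count exactly — the invariant the patch targets and evaluation rely on.

Images are decomposed into 32×32 sub-images at stride 8; each sub-image's
target is the density mass under its footprint. The regressor is a small
convolutional network — four 3×3 conv blocks (default widths 16/32/64/128)
with batch normalization, ReLU, 2×2 max-pooling after the first three
blocks, dropout 0.25 before a scalar linear head — trained with Adam on the
L1 loss. Patch pixels are scaled to [0, 1]; no mean subtraction. A random
fraction (default 10%) of patches is held out for early stopping (patience
5 within a 50-epoch budget at the full-scale defaults); the parameters of
the best validation epoch are kept. The network and optimizer are written
directly in NumPy (im2col convolutions); training is single-threaded and
bit-reproducible from the config seed.

At prediction time, each sliding window's predicted count T̂ⱼ (clamped at 0)
is spread uniformly over its footprint, C(x,y) += T̂ⱼ/32², while P(x,y)
counts window visits; the image count is Σ C/P over visited pixels, and the
per-pixel C/P map doubles as a localization heatmap. This
redistribute-and-normalize rule is exact for a model that outputs true
window density sums up to a small boundary bias (edge pixels are covered by
fewer windows), and for a constant-output model it yields the constant
times (covered pixels)/32² — the constant itself only for a single-window
image.

`bootstrap_mae` resamples training patches with replacement, retrains per
replicate, scores each model's MAE on a fixed holdout, and reports the mean
with the 2.5th–97.5th percentile interval. A degenerate mode
(`resample=False`) trains every replicate identically and is used to verify
that the interval collapses to zero width.

## Evaluation metrics

MAE, NMSPE and predictive deviance (PD) are computed exactly as defined in
the README. NMSPE divides by T̂ₖ and PD takes its logarithm, either of which
breaks when aggressive filtering drives predictions to zero, so both apply
a configurable floor (default 0.5 counts) to T̂ₖ; PD additionally zeroes the
Tₖ·log term when Tₖ = 0, which keeps the statistic finite and non-negative.
r² is the squared Pearson correlation between observed and predicted counts
(not a regression-through-origin variant); Spearman uses average ranks for
ties.

The threshold sweep holds step 1 fixed (ExG 131), re-filters the test
images at every step-2 threshold 0…255, runs a counter and records r²
against the ground truth. Thresholds where the counter's predictions have
no variance (e.g. everything eliminated) are recorded as r² = 0 with a
degenerate flag rather than NaN so curves remain plottable; ties in the
argmax resolve to the lowest threshold. The built-in baseline counter
labels the surviving mask with 8-connectivity and counts components of
area ≥ 12 pixels (a plausible tassel footprint at plot-crop scale; both
exposed in config). Any callable `(image, threshold) → count` can replace
it, so a trained detector slots in unchanged.

## Synthetic scenes

`synthetic.generate_scene` renders a 128×256 plot crop: jittered brownish
soil (120, 90, 60) ± 3, dark shadow ellipses (40, 40, 45) ± 3, two rows of
elliptical foliage canopies at exactly (50, 140, 40), and 5–25 branched
tassel glyphs colored (200, 180, 80) with a per-glyph jitter of ± 3, drawn
without anti-aliasing so tassel pixels keep their palette color. Tassel
centers keep a minimum separation of 20 px so glyphs stay resolvable as
components.

The palette arithmetic is what makes the scenes diagnostic: on the rescaled
scale, soil sits at ExG 127.5 and shadow ≈ 126 (eliminated at 131), foliage
at 175.0 and tassel at 147.5 (retained); on the tassel index, foliage sits
at ≈ 45.96 and tassels at ≳ 139. Foliage canopies are deliberately
flat-colored so the foliage→tassel transition is sharp: the documented
separation band (46, 135) — within which foliage elimination is ≥ 95% and
tassel elimination ≤ 20%, with a working threshold of 95 mirroring the
field-data band 90–110 — then has exact edges, and the generation-time
contract check cannot fail for any seed. The jitter amplitudes are sized so
the ExG contract (≥ 99% of soil/shadow below 131, ≥ 95% of foliage/tassel
above) also holds deterministically.

What the scenes do *not* emulate: illumination gradients, anti-aliased or
motion-blurred edges, debris, tassels occluding each other, genotype or
growth-stage variation in color and shape. Passing tests therefore show
that the algorithms are implemented correctly and behave as designed when
their color assumptions hold — not that the specific thresholds transfer to
any particular field dataset, where pixel sampling must be repeated.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the smallest
sizes at which each property is meaningfully exercised: 60 scenes
(48 train / 12 test, ~18 000 training patches) with 8 training epochs,
conv widths (8, 16, 32, 64) and learning rate 1e-3 for the learnability
check — fewer gradient steps than a full-scale run warrant the larger step
size — and 10 bootstrap replicates on 64×96 scenes for the interval
machinery. Full-scale defaults (widths 16/32/64/128, lr 1e-4, 50 epochs)
remain in `CounterConfig`.

Other numerics: density kernels truncated at ±4σ then renormalized
(mass-exact by construction); max-pool tie-breaks go to the first maximal
element (deterministic); negative predictions clamped at 0 before
redistribution; pixels never covered by a full window contribute 0 to the
count; float32 arithmetic throughout the network, float64 elsewhere.

## Known limitations

* The CBR engine is NumPy-based and single-threaded; it is meant for
  method-level experiments, not for training on 10⁵–10⁶ sub-images.
* Redistribution has a small boundary bias on images whose size is not
  aligned to the stride grid (uncovered right/bottom margins are not
  counted).
* The baseline component counter undercounts when tassels touch and
  overcounts fragmented glyphs; it is a reference detector for the sweep
  machinery, not a production counter.
* Thresholds are static per dataset by design; per-image adaptive
  thresholding is out of scope.
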