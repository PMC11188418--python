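# Methods

## Peel roughness

The metric operates on the grayscale bounding rectangle of the fruit (the
rectangle of the mask's nonzero pixels when a mask is given, else the whole
image; both sides must be ≥ 12 px).  Each side of the H×W rectangle is
divided into four equal parts; the 3×3 interior intersection points, at
local offsets `round(H·k/4)`, `round(W·k/4)` for k ∈ {1, 2, 3}
(round-half-up), are the centers of nine sampling regions.  Each region
window is ⌈H/4⌉ × ⌈W/4⌉, centered on its point and clipped to the
rectangle — the windows tile the rectangle with near-complete coverage and
the 12-px minimum guarantees every window is at least 3×3.

Within a region, eight half-rays leave the center toward the compass
neighbors, numbered clockwise from the top-left diagonal
(1=NW, 2=N, …, 8=W), stepping until the window edge, center pixel
included.  Half-rays rather than full chords keep the eight directional
deviations distinct (full lines would pair opposite directions into four
duplicates).  Per ray, D_i = Σ|X_j − X̄|/N (mean absolute deviation,
intensity units); per region P_i = mean of its eight D_i; overall
P = mean of the nine P_i.  Ray pixels are read from the image regardless
of the mask: the measurement deliberately runs on the rectangular crop,
not the irregular silhouette, so a mask only positions the rectangle.

Properties the suite verifies: P is zero exactly on constant images,
invariant under intensity inversion, scales linearly with intensity
scaling (on float doubles, before 8-bit clamping), and increases with
i.i.d. surface-noise amplitude.

## R-LBP encoding

Per pixel and per clockwise direction d, the dispersion

    CV(x_1..x_n) = (Σ (x_i − x̄)²) / (n · x̄) × 100 %

is computed for the outward ray at offsets 1·d … (ray_length+1)·d
(CV_a, default 3 pixels) and for the same array with the target pixel
prepended (CV_b).  Bit d is 1 when |CV_a − CV_b| / CV_a > threshold
(strict; default 0.15).  Direction 1 is the most significant bit; the
8-bit word is the output code.  Note this dispersion is the sum of
*squared* deviations over count×mean — an index-of-dispersion-like
percent, not the textbook std/mean coefficient of variation.  The
encoding only ever compares the two quantities relatively, so the choice
affects nothing but fidelity to the definition, which the tests pin down.

Degenerate cases are explicit: CV_a = CV_b = 0 (locally constant) emits 0;
CV_a = 0 with CV_b > 0 means the target pixel introduces all the variation
— an unboundedly large relative change — and emits 1 by default
(`zero_cv_policy` exposes the alternative).  A zero mean can only occur
for an all-zero array under nonnegative intensities and yields CV = 0.

Borders: by default the image is edge-replicate padded by ray_length+1 so
every pixel receives a code; `zero_border` instead emits 0 where the
neighborhood leaves the image.  Classic LBP (bit = neighbor ≥ center over
the 3×3 ring) shares the bit order and border policy so arm comparisons
isolate the encoding.

The vectorised transforms are verified bit-exactly against straight-line
per-pixel, per-direction reference implementations; both encoders satisfy
90°-rotation equivariance (a two-position cyclic bit rotation), and R-LBP
is invariant to intensity scaling on interior pixels.  At borders of
float-valued inputs, replicate padding creates exactly-constant rays whose
CV_a = 0 classification depends on float rounding; integer images (the
real domain) are immune because small-integer means are exact.

## Composition

A composed training image is `rlbp_transform(gray)` where the mask is 1
and `gray` elsewhere.  The transform always reads neighbor intensities
from the full grayscale image, including across the mask boundary:
zero-filling the background would fabricate strong spurious edges at the
fruit contour.  Grayscale conversion uses ITU-R BT.601 weights
(0.299/0.587/0.114) with round-half-up — the convention of mainstream
imaging stacks.  Outputs are PNG by default so tests can be bit-exact;
JPEG export (quality 95) sits behind an explicit option.  Detection label
files are copied byte-identically because composition never moves objects.

## Synthetic scenes

A scene is a disc-shaped fruit (mask is exactly the disc inequality, no
anti-aliased fringe) on a leaf-like background.  The fruit surface carries
one additive Gaussian noise field shared across the RGB channels — so
grayscale conversion preserves its amplitude instead of averaging
independent chroma speckle — with std `noise_sigma`; the background
carries a spatially smoothed field (`bg_blur_sigma` 4 px), i.e.
low-frequency texture distinct from the fruit's grain.  Noise is applied
in float and rounded/clamped exactly once, so a spec is bit-reproducible
across runs and platforms.

Stage series model ripening on two coupled axes: amplitude σ = (30, 20,
12, 5) from stage A (unripe) to D (ripe), and surface smoothing width
(0.0, 0.7, 1.4, 2.1 px) applied to the noise field before renormalising to
the stage amplitude.  The smoothing axis reflects the physical mechanism —
wax deposition low-passes peel micro-texture rather than merely
attenuating it — and is what couples code-space encoders to the stage
structure at all: both LBP (rank-based) and R-LBP (a scale-free dispersion
ratio) are by construction insensitive to a pure amplitude rescaling of
the surface field.  Fruit color interpolates green → orange across stages.
Stage scene seeds derive as `base_seed·4 + stage`, group seeds as
`base_seed + group`, keeping all series pairwise independent and
deterministic.

What the generator does *not* emulate: real peel micro-structure (oil
glands, specular highlights), illumination conditions (exposure,
backlight), occlusion, multi-fruit layouts, and JPEG compression
artifacts.  Consequences for interpretation are below.

## Experiment harness

Per four-stage group and per arm (grayscale / LBP / R-LBP), each stage's
fruit bounding-rectangle crop is grayscaled, transformed (grayscale arm:
identity), and scored with the roughness metric; the group value is
mean(|P_A−P_B|, |P_B−P_C|, |P_C−P_D|).  Group values are summarised as
median, quartiles (linear interpolation between closest order statistics)
and IQR.  The three arms differ only in the transform step — the suite
verifies that stubbing the transform to the identity makes all arms equal.

Default problem sizes — 256×256 scenes, disc radius 60, 50 groups — keep a
full three-arm run of the experiment in the low seconds while giving every
fruit crop ≥ 3600 ray pixels per roughness evaluation.

### What passing (and failing) tests show

On orchard photographs, R-LBP is reported to enlarge stage-to-stage
roughness differences beyond grayscale and LBP.  On these synthetic
scenes, measured over the default 50-group set, the ordering is reversed:
the grayscale arm's differences are largest, because the generator encodes
ripeness chiefly as noise amplitude, which the roughness metric reads
directly, while both code images are nearly amplitude-invariant (R-LBP's
bit is a scale-free ratio; LBP's is a rank).  The code arms respond only
through quantisation degeneracies and the smoothing axis — and across the
(amplitude × smoothness × sensor-noise) space we mapped, LBP's smoothing
response dominates R-LBP's, so no monotone ripening schedule of Gaussian
surface fields ranks R-LBP first.  The corresponding acceptance test
asserts the reported ordering and therefore fails on synthetic data; it is
kept failing rather than weakened, as a precise record that this
qualitative claim is a property of real peel micro-texture (structured,
non-Gaussian) that the generator does not reproduce.  All
implementation-level claims — oracle exactness, degenerate cases,
symmetry, monotonicity, composition, determinism — pass.

## Numerical choices

* All dispersion/deviation arithmetic is float64; codes and images are
  uint8.
* Quartiles: linear interpolation (`numpy.percentile` default), documented
  because the reported statistics depend on the convention at small n.
* Round-half-up (`floor(x+0.5)`) everywhere a float becomes an intensity,
  for cross-platform determinism.
* 16-bit PNG inputs are rescaled by integer division by 256; no other
  16-bit path exists.
* Thresholds compare strictly (`>`), so a relative change of exactly 15 %
  emits bit 0.

## Known limitations

* The nine-region geometry requires a fruit bounding rectangle ≥ 12 px per
  side; tiny detections cannot be scored.
* Roughness is single-scale (pixel-step rays) and not rotation-averaged
  beyond the eight fixed directions.
* R-LBP's degenerate CV_a = 0 rule makes border codes of float inputs
  sensitive to rounding (see above); integer inputs are unaffected.
* The synthetic generator's Gaussian surface fields do not reproduce the
  code-space amplification seen on real peel texture, as detailed above.
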