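# Methods

## Measurement model

An ideal ortho-k fluorescein pattern is a set of four concentric zones
whose boundaries are circles centered on the lens: going outward from the
center, a dark central bearing, a bright tear reservoir, a dark
mid-peripheral (alignment) annulus, and a bright edge-lift ring.
`okfluor` measures the widths of these zones along the single horizontal
meridian of a photograph that has been cropped so the lens is centered.
The assumptions this rests on:

- the pattern is approximately rotationally symmetric, so one meridian is
  representative (the package does not measure other meridians or areas);
- the lens is centered in the crop; the automatic edge assignment flags
  (but does not correct) inferred centers offset by more than 5% of the
  image width;
- brightness increases with tear-film thickness, but no attempt is made
  to invert intensity into thickness — only edge *positions* are used,
  which is why every photometric step (contrast stretch) is monotone.

## Pipeline parameters

| parameter | default | units | role |
|---|---|---|---|
| `target_width` | 1000 | px | working width after proportional resize; all positions are 0-based columns of this image |
| `band_height` | 60 | px | vertical extent of the meridian band that is averaged into the profile |
| `reducer` | mean | — | band collapse; mean maximizes Gaussian-noise suppression, median resists specular highlights |
| `smoothing_sigma` | 2 | px | Gaussian pre-smoothing of the profile before differencing; 0 disables |
| `min_prominence_frac` | 0.1 | of max | derivative peaks below this prominence fraction are noise |
| `min_separation_px` | 10 | px | closer peaks are duplicates of one edge; the larger magnitude wins, ties toward smaller x |

The working width and band height are the two constants of the standard
processing protocol; the remaining values fill gaps where the protocol is
silent, chosen so that a typical photograph yields the eight true edges
plus at most a few spurious peaks, and all are exposed through
`MeasureConfig` and the CLI.

## Edge detection and localization

The profile derivative is the absolute forward difference; the value at
index *i* belongs to the transition between columns *i* and *i*+1 and is
attributed to position *i*. This uniform half-pixel convention cancels in
every diameter difference and hence in every zone width.

Peak **detection** runs on the smoothed derivative: smoothing suppresses
JPEG blocking artifacts that would otherwise create spurious local maxima.
Peak **localization** then snaps each detected peak to the argmax of the
*unsmoothed* derivative within ±⌈2σ⌉ px (clamped below half the minimum
separation so order is preserved). The two-stage (coarse-to-fine) design
matters because zone boundaries are circles: across a 60-px band a
boundary of radius *R* px drifts horizontally by up to
(band/2)²/(2*R*) ≈ 2.7 px for the innermost boundary, so the band-averaged
edge is a skewed ramp, and smoothing drags the derivative mode of a skewed
ramp sideways by ~1 px per edge. Reading the final position off the raw
derivative removes that bias while keeping detection robust.

Automatic edge assignment selects, among all candidate peaks, the four
nested left/right pairs that straddle the image midline and minimize the
total symmetry residual Σ|(Lk+Rk)/2 − W/2|. The search is exact
(enumeration over choices of four left and four right peaks; nesting is
then implied by sorting), feasible because candidate counts are small
(≲ 15). Ties break toward the lexicographically smallest position vector.
Manual assignment takes eight observer-chosen indices and enforces the
same nesting invariant.

## Calibration

mm/px is the nominal manufacturer lens diameter divided by the measured
total diameter in px, so the calibrated total diameter equals the nominal
diameter by construction and all other widths scale linearly. The nominal
diameter is an approximation to the imaged lens (real diameters vary by a
few tenths of a millimeter across eyes); per-image nominal diameters can
be supplied via per-image lens spec files. Widths keep full precision
internally; rounding to 0.01 mm happens only at presentation.

`check_lens_geometry` verifies the spec sheet itself: the zone widths
should tile the diameter, D0 + 2(D1+D2+D3) = total, within 0.01 mm.

## Synthetic patterns

The generator renders piecewise-constant concentric annuli in the green
channel (red/blue fixed at 25% of green, emulating a blue-light /
yellow-filter photograph), then optional Gaussian blur, seeded additive
Gaussian noise (clipped to [0,1]) and JPEG re-encoding. Ground-truth edges
are the analytic crossings cx ± d(k)/2. The outer ring may be clipped
top/bottom, as in real cropped photographs, but must fit horizontally.

What it emulates: zone geometry, edge contrast alternation, optical blur,
sensor noise, compression artifacts, and the band-curvature smear
described above (it renders true circles). What it does not: tear-film
photometry (intensity is not a thickness model), lens decentration and
tilt, specular reflexes, eyelid/lash occlusion, uneven illumination.
Passing recovery tests therefore demonstrates correct geometry and edge
localization under controlled degradation, not clinical robustness.

Default degradation levels used in the recovery studies: central bearings
spanning 3.5–4.5 mm (the clinically recommended range), blur σ ∈ {0..3} px,
noise SD up to 0.02, at 0.012 mm/px on a 1000×640 canvas — sizes chosen so
a full 52-pattern sweep runs in seconds on one core.

## Agreement statistics

Differences are (first-listed − second-listed), and every report labels
the order. SDs use the n−1 denominator. Limits of agreement use the
literal 1.96 multiplier, not a t quantile. Two confidence-interval
constructions for the limits are provided:

- **approximate** (default): SE = SD·√(1/n + z²/(2(n−1))), interval
  limit ± t₀.₉₇₅,ₙ₋₁·SE — the standard Bland–Altman large-sample form;
- **exact**: each limit is the normal quantile μ ± 1.96σ, whose pivot
  √n(x̄ − θ)/s follows a noncentral t with df = n−1 and noncentrality
  ∓√n·1.96; inverting the pivot gives an exact, asymmetric interval.

The two converge as n grows; at n = 26 the exact interval is visibly
shifted outward. The approximate form is the default because it is the
convention in agreement studies; the exact form is opt-in
(`mode="exact"`).

Degenerate inputs: identical series give SD = 0, a zero-width LoA and an
undefined t (reported NaN); a constant series makes Pearson's r undefined,
reported as `None` with an explanatory note rather than a number.

Between-method comparisons represent each eye by the mean of the two
observers' measurements for that method, matching how such studies
tabulate per-method columns.

## Numerical choices and edge cases

- Resize: bilinear with anti-aliasing on downscale; output height rounds
  half-up. Identity resize returns the input unchanged.
- Contrast stretch on a constant image raises a degenerate-contrast error
  (there is no pattern to measure) rather than returning NaNs.
- An all-zero derivative yields an empty peak set; the error surfaces at
  edge assignment with a message pointing to manual mode or relaxed
  thresholds.
- Batch measurement isolates per-image failures: remaining images are
  processed, failures are logged by name, and the CLI exits nonzero.

## Known limitations

- Single-meridian only; no area or multi-meridian analysis, no toric or
  elliptical boundary fitting.
- Calibration trusts the nominal lens diameter; any true-diameter
  deviation scales all widths proportionally.
- The automatic assignment assumes an approximately centered lens; for
  grossly decentered patterns use manual mode.
- The residual band-curvature bias on the innermost boundary (after
  coarse-to-fine localization, ≲ 1 px per edge at radii ≥ 145 px) is
  inherent to averaging a curved boundary over a fixed-height band.
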