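# Methods

`fasciatrack` measures the thickness of the three lateral abdominal
muscles — external oblique (OE), internal oblique (OI) and transversus
abdominis (TrA) — continuously through a B-mode ultrasound recording of a
stabilization exercise, and condenses each exercise repetition into a
preferential activation ratio (PAR). This note records the models and
procedures the package implements, the parameters that matter, what the
synthetic fixture does and does not emulate, and the design choices made
where the design was genuinely open.

## Measurement chain

### Initial frame and fascia segmentation

The semi-automated chain starts from a single well-chosen frame: the one
with the highest mean Sobel gradient magnitude, i.e. the frame on which
the fascia echoes are most visible. Ties break to the lowest index so runs
are reproducible.

On that frame the four fasciae bounding the three muscles (superficial OE
border, OE/OI, OI/TrA, deep TrA border) are extracted as *brightest
paths*: a path visits one row per column, left to right, and maximizes

    sum of brightness along the path  −  step_penalty · Σ |Δrow|

subject to |Δrow| ≤ `max_vertical_step` per column transition. This is
solved exactly by dynamic programming (a Viterbi pass over columns with
backtracking). Defaults: `step_penalty = 2.0` brightness units per pixel
of vertical movement, `max_vertical_step = 2` px, after a σ = 1 px
Gaussian pre-smoothing that suppresses isolated speckle maxima. All ties
break toward the smaller row, then smaller column, so the result is
deterministic; the suite verifies DP optimality against exhaustive path
enumeration on small images.

Four paths are peeled off sequentially, each time masking an exclusion
band (halfwidth 6 px) around the accepted path so the next path must find
a different ridge. A joint four-path DP would also be possible; sequential
extraction is simpler, matches the per-fascia framing of the procedure,
and ordering is imposed afterwards by an order-preserving projection
(sort per column, minimum 1 px separation).

Each accepted integer path is refined to sub-pixel precision: brightness
is smoothed *along* the fascia direction (σ = 4 px, which averages
speckle without blurring the cross-profile), the column is re-centered on
the local maximum within ±2 rows, a locally linear background (sampled
4 px off-crest on each side) is subtracted so asymmetric tissue contrast
does not drag the apex, and a parabola through the three central rows
gives the final row. Without the background correction the crest estimate
is biased by ~0.2–0.4 px toward the brighter adjacent tissue layer.

An operator correction is a JSON file with replacement polylines for one
or more boundaries; merging re-validates the non-crossing invariant and
reports offending columns. There is no interactive editor — the manual
step in practice is an operator action, not a computation.

### Propagation and point tracking

The keyframe segmentation is carried to every other frame with a dense
displacement field, and three measurement points per muscle — placed at
40 / 50 / 60 % of the column range on each muscle's upper fascia — are
tracked by sampling that field at the point locations. The package uses
the iterative Lucas–Kanade solver (`skimage.registration.optical_flow_ilk`)
rather than a sparse window tracker: the same local least-squares flow
model, computed densely, serves both the boundary propagation and the
point tracking.

For every frame the flow reference is *not* necessarily the previous
frame: it is the already-segmented frame with the highest zero-normalized
cross-correlation over the band of rows spanned by the keyframe
boundaries (padded 15 px). Frames are processed outward from the
keyframes, so references are always nearby at first and the candidate set
grows as tracking proceeds. Additional keyframes can be segmented and
supplied; each frame then chains to whichever segmented frame correlates
best.

Tracker parameters and their semantics in this implementation:

| parameter | default | meaning |
|---|---|---|
| `sigma` | 0.04 | Gaussian pre-smoothing of frames before flow, as a fraction of the LK window (0.04 × 21 ≈ 0.84 px) |
| `fgs_lambda` | 5000 | spatial scale of the edge-aware flow post-filter; smoothing σ = √λ / 25 px |
| `fgs_sigma` | 3 | edge sensitivity of the post-filter; weights decay as exp(−|∇I|/σ) on the 8-bit intensity scale |
| `window` | 21 px | LK window size |
| `levels` | 3 | coarse-to-fine warping iterations |
| `downscale` | 2 | flow computed at 1/2 resolution and rescaled |

The post-filter is a normalized convolution: each flow component is
Gaussian-smoothed with weights that collapse near strong image gradients,
so the field is regularized within tissue but not blindly across fasciae.
This is a hand-written realization of a "fast global smoother"-style
edge-aware filter; no installed library provides one.

Flow at half resolution costs a quarter of the full-resolution solve and,
on the synthetic scenes, loses nothing measurable (rigid translations are
recovered to < 0.05 px). Points that leave the image are flagged `lost`
and frozen, never silently dropped; a frame/muscle combination is usable
as long as one of its three points is valid.

### Thickness, contraction phase, PAR

Thickness at a tracked point is the vertical distance (same column) from
the point down to the muscle's lower boundary, times the mm/px
calibration. Vertical — rather than fascia-normal — distance is the
common convention in rehabilitative ultrasound imaging and is well defined
for polyline boundaries; for the near-horizontal abdominal-wall geometry
the difference is second-order.

The contracted phase is detected on the 3-point mean TrA thickness:

1. smooth with a 5-frame moving median;
2. baseline = median of the first 15 % of frames;
3. entry threshold = baseline + 0.5 · (peak − baseline); the contracted
   interval is the longest run above it,
4. extended by hysteresis in both directions down to
   baseline + 0.3 · (peak − baseline).

All four parameters are exposed (`PhaseParams`). The rule is invariant to
adding a constant to the trace; a trace with no rise above baseline gives
an empty contracted interval and a warning, not an exception. The
hysteresis deliberately admits the steep part of the ramps; because all
three muscles ramp synchronously, the PAR — a ratio of shares — is nearly
unaffected, which is why the end-to-end PAR tolerance is met even though
the detected interval is wider than the scripted hold.

Rest and contracted thickness per muscle are the 3-point mean averaged
over the respective phase frames (3-point mean first, then phase mean —
the order matters for ratios and is fixed here). The rest mean uses the
pre-contraction interval by default; pooling pre- and post-contraction
rest is available as `rest_mode="pooled"`.

The preferential activation ratio is

    PAR = TrA_C / (TrA_C + OI_C + OE_C) − TrA_R / (TrA_R + OI_R + OE_R)

with `_R`/`_C` the rest/contracted thicknesses. PAR is dimensionless,
lies in (−1, 1), is invariant to rescaling all six inputs (hence robust
to calibration error), zero under proportional thickening of all three
muscles, and positive exactly when the TrA's share of the summed
thickness grows during contraction.

## Group statistics

The per-repetition PAR table (participant × group × exercise ×
repetition) feeds:

- a **mixed-design ANOVA** (within: repetition, between: group) via
  `pingouin.mixed_anova`. The headline "group-related" statistic is the
  group × repetition interaction, whose degrees of freedom
  (k−1, (k−1)(n−g)) match the reporting convention of the study design
  this package targets. Subjects missing any repetition are dropped
  listwise and the count logged.
- **Mauchly's sphericity test** (`pingouin.sphericity`); when it rejects
  at α = 0.05 the interaction p-value is recomputed with
  Greenhouse–Geisser-scaled degrees of freedom. With two within-levels the
  test is trivial (W = 1) and flagged as such.
- **paired t-tests** between repetition pairs with Cohen's
  d = mean(diff)/sd(diff); zero-variance differences are rejected rather
  than reported as infinite t.
- **Mann–Whitney U** (smaller-U convention) with an exact p for small
  untied samples and the tie-corrected normal approximation otherwise.
  The nonparametric route is an explicit choice by the caller, never
  auto-selected, so runs are reproducible.
- report tables: per-repetition and pooled mean/SD with t-based 95 %
  confidence intervals (t-based rather than normal — the cohorts are
  small). Pooled rows aggregate each participant's repetition mean first
  (mean of PARs); this is *not* the PAR of mean thicknesses, and the two
  differ materially (0.025 vs 0.014 on the cohort-mean inputs bundled in
  the tests).

The test suite validates the ANOVA against a hand-coded textbook
sums-of-squares decomposition, Mauchly against a direct
contrast-covariance computation, and the Mann–Whitney exact p against
enumeration of all rank assignments. A 200-replicate null simulation
(12 participants per group, 3 repetitions, no group effect) checks that
the group test rejects at ≈ α.

## Synthetic fixture

The generator renders the abdominal wall as five piecewise-constant
tissue layers (subcutaneous 70, OE 35, OI 45, TrA 30, deep 55 on the
8-bit scale) separated by four bright fasciae, composited as Gaussian
cross-profile ridges (default width 3 px, level 160) that *replace* the
tissue echo at their location — alpha compositing keeps the rendered
crest exactly on the scripted boundary regardless of the contrast step
between adjacent layers. Multiplicative exponential speckle (scale 0.35)
and a σ = 0.8 px blur follow. Default geometry: 256 × 384 px at
0.1 mm/px (plausible for a 5–15 MHz linear probe), 60 frames at 20 Hz.

Contraction is scripted per muscle as rest → linear ramp → hold → linear
ramp → rest, with the scripted thicknesses as ground truth; the default
script uses the cohort-mean contraction amplitudes from the study design
this package targets (TrA 4.61→5.44 mm, OI 9.34→10.57 mm,
OE 5.22→5.40 mm; analytic PAR 0.0136). Sinusoidal fascia waviness and
lateral/axial drift are available for segmentation- and tracking-stress
scenarios.

Speckle is **tissue-attached**: the noise texture lives in the material
coordinates of frame 0 and is warped along with the scripted geometry
(piecewise-linear row map anchored at the fascia rows, column shift with
lateral drift). Fully developed speckle does move with tissue to first
order, and an image-fixed noise field would systematically bias any
motion estimator toward zero. A `static_speckle` switch freezes the noise
in image coordinates, which with a static script produces bit-identical
repeated frames for exactness tests.

What the fixture does **not** emulate: attenuation and depth-dependent
gain, refraction and reverberation artifacts, out-of-plane motion,
speckle decorrelation under deformation, probe pressure changes, and the
image degradation that made standing-posture recordings unusable in
practice. Passing on the fixture therefore demonstrates the algorithmic
correctness of the chain (optimal paths, unbiased localization, motion
recovery, calibrated arithmetic), not clinical robustness.

## Numerical choices and degenerate inputs

- Coordinates are 0-based; rows grow with depth, columns laterally; all
  modules share this convention. Column ranges are half-open.
- Tie-breaks: smallest row, then smallest column, then smallest frame
  index, everywhere.
- Boundary ordering is enforced by order-preserving projection with a
  1 px minimum separation; corrections that cross are rejected with the
  offending columns named.
- Degenerate statistics: zero-variance ANOVA input returns F = 0, p = 1
  (flagged); zero-variance paired differences raise; empty groups raise;
  single-participant summaries omit SD/CI with a flag.
- Videos are gated by an explicit quality score (mean Sobel energy +
  mean adjacent-frame correlation); below-threshold videos are flagged,
  never silently dropped — exclusion stays a logged, operator-level
  decision.
- Problem sizes in the reproduction script (25 seeds per recovery sweep,
  200 enumeration images, 200 null replicates, 50-frame translation
  videos) were chosen so the whole script completes in minutes on one
  CPU while keeping Monte-Carlo noise well inside the tolerances checked.

## Known limitations

- The brightest-path cost (brightness sum minus per-pixel step penalty)
  is a minimal faithful reading of "brightest path"; other Viterbi
  emission/transition models would also fit that description.
- `sigma`, `fgs_lambda`, `fgs_sigma` reproduce a published tracker
  configuration whose exact parametrization is not documented; the
  semantics above are this package's documented interpretation, and the
  defaults are kept.
- The contraction detector is a baseline-relative threshold with
  hysteresis — adequate for single-contraction repetitions, not for
  repeated or overlapping contractions within one recording.
- Whether "rest" should pool pre- and post-contraction frames is
  genuinely ambiguous; pre-contraction is the default and both are
  supported.
- Thickness is vertical, not fascia-normal; for steeply inclined fasciae
  the two diverge.
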