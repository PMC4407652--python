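# Methods

This note records the scientific and numerical choices behind `rsaquant`:
what each computation assumes, how the synthetic generator is parameterised
and what it does and does not emulate, and where the design was genuinely
open.

## Coordinate conventions

All geometry runs in the image frame: pixels, x positive rightward, y
positive **downward** (deeper into the growth pouch).  Every reported
coordinate trait (RCMX/RCMY, RCHCX/RCHCY) is re-expressed relative to the
seed origin, so RCMY = 30 mm means "the centre of mass sits 30 mm below the
seed".  The seed origin is taken from an explicit plant-level annotation
when the RSML carries one, else it defaults to the first vertex of the
first seminal root — seminal roots emerge from the seed, so for extracted
architectures the two coincide up to segmentation noise.

Conversion to millimetres happens once, at trait assembly, via
`TraitConfig.mm_per_px` (areas by its square).  The default scale 15/95 ≈
0.1579 mm px⁻¹ follows from the fixed angle-measurement point being
specified both as 95 px and as 15 mm of arc length; any real deployment
should override it with the camera calibration.

## Centre of mass

The root system is treated as a wire of uniform linear density.  Each root
is resampled at regular arc-length intervals (default 1 px; linear
interpolation within segments, terminal point always retained so total
length is preserved), and the centre of mass is the plain mean of all
samples.  With a common interval each root contributes points in proportion
to its length, so this is the length-weighted mean position; against the
exact line integral (per-segment midpoint weighted by segment length) the
1 px sampling agrees to well under 0.5 px on random curved systems.

## Convex hull, area, centroid

The hull is computed with Andrew's monotone chain — deterministic,
O(n log n), sorting ties broken by (x, then y), collinear boundary points
dropped — over **all resampled points** of all roots (seminal and lateral).
Since resampled points lie on the polyline segments, this hull equals the
hull of the polyline vertices; using the sample cloud keeps one input
feeding extent, centre of mass and hull alike.  Area and centroid use the
shoelace identities with the wrap-around convention; the trait RCH reports
|A|.

Degenerate hulls (all points collinear — e.g. a single straight seminal)
are represented as the two extreme points with a flag: RCH = 0, centroid =
arithmetic mean of the extreme points, and the flag propagates into
`TraitVector.flags` so single-root seedlings flow through the pipeline
rather than crashing it.  The degeneracy threshold is |A| ≤ 1e-9 px².

## Emergence angles

"Angle of emergence" is implemented as the angle subtended **at the seed**:
for each seminal root, take the point at the specified arc length (30 px,
95 px) or at the specified fraction of *that root's own* length (25, 50,
75, 100 %), form the vector seed → point, and measure its signed angle from
the downward vertical.  Tangent-based readings were deliberately excluded;
a subtended angle is what "emergence between roots" describes and is robust
to local segmentation wiggle.

Pair selection re-ranks the seminal roots by signed angle at *each*
measurement point: outermost = extreme ranks, second = ranks 2 and n−1.
With 2–3 seminal roots only the outermost pair exists; second-pair traits
are NaN with reason `insufficient_seminal_roots`.  Odd counts are fine (the
median root is simply unused).  A fixed measurement point beyond a short
root's tip is clamped to the tip and flagged `clamped_to_tip` rather than
dropping the root, so the angle traits degrade gracefully.  Because fans
can in principle open beyond 180°, the value is reported as the absolute
signed-angle difference in [0°, 360°) rather than folded to [0°, 180°].

The quartile fractions are interpreted per root — each root measured at
25 % of its own length — because a system-level arc length has no
well-defined location on an individual root.

## Synthetic generator

`SyntheticSpec` encodes the study conditions the generator emulates: a
pouch-grown wheat seedling at the two-leaf stage, seen in 2-D.

| parameter | default | meaning |
|---|---|---|
| `seminal_count_range` | (2, 6) | uniform per-plant seminal count |
| `seminal_length_log_mean`, `_log_sd` | ln 300, 0.3 | log-normal seminal length (px); median 300 px ≈ 47 mm |
| `fan_half_angle` | 40° | emergence headings uniform in ±40° about vertical |
| `gravitropism_rate` | 0.005 px⁻¹ | heading decay toward vertical per px grown |
| `lateral_density` | 0.02 px⁻¹ | Poisson rate of laterals beyond the basal zone |
| `lateral_length_mean` | 40 px | exponential lateral length |
| `basal_zone` | 60 px | seminal arc length bearing no laterals |
| `step` | 2 px | emitted vertex spacing (exercises the resampler) |
| `noise_sd` | 3°/step | heading jitter of the correlated random walk |

Each root follows θ_k = a·θ_{k−1} + ε_k with a = 1 − rate·step, evaluated
in closed form so paper-scale populations (≈1700 plants) generate in
seconds.  Laterals inherit the local parent heading plus a branching angle
uniform in [45°, 90°] to a random side — plausible cereal morphology, not
calibrated to data.  Ground truth records the drawn counts, lengths,
emergence headings, tip positions, coordinate extremes, and an
*independently computed* hull area (Qhull), so recovery tests never compare
the implementation against itself.

Randomness is split per plant via `SeedSequence(seed, line_index, rep)`;
populations are bit-stable under re-runs and under adding lines or reps.

What the generator does **not** emulate: root diameter and intensity
(there is no raster image), root crossings' occlusion effects, segmentation
and extraction error, adventitious roots, or biophysically calibrated
growth.  Passing recovery tests therefore demonstrates that the *trait
mathematics* inverts the generative geometry — not that any upstream image
segmentation is accurate.

## Cohort statistics

Per-line summaries exclude NaN values pairwise and report n after
exclusion; SE = sd/√n needs n ≥ 2.  Two-line contrasts use Welch's
unequal-variance t (two identical constant groups return statistic 0,
p = 1, rather than NaN).  The Spearman matrix uses average ranks for ties
and pairwise-complete observations per pair (minimum 3), with two-sided
p-values and Benjamini–Hochberg adjusted values over the unique pairs —
the adjustment is reported alongside raw p rather than chosen for the
user.  Mixed-model (BLUE/BLUP) adjustment for experiment effects is out of
scope; `center_by_experiment` offers a clearly-labelled fixed-effect
centering instead.

Trait *classes* formalise a verbal notion of "groups of strongly
associated traits": traits are nodes, pairs with ρ ≥ threshold (default
0.7, the conventional lower edge of "strong") are edges, classes are
connected components.  This is one faithful formalisation, not the only
one; the threshold is exposed.  On synthetic cohorts with an angle-driving
and a size-driving factor, the classes recover the planted structure
(angle traits / size-and-depth traits / x-coordinates separate).

## Problem sizes

The verification suite and the acceptance script use: 100 random 200-point
clouds for the brute-force hull comparison; 20 random convex polygons with
10⁶ Monte-Carlo samples each for the centroid; 50 three-root systems for
the line-integral centre-of-mass check; 100 noise-free and 500 default
(noisy) systems for ground-truth recovery; a 400-plant homogeneous pool
relabelled 1000× for the Welch type-I calibration; and one full cohort of
92 lines × 18 replicates = 1656 plants.  These sizes give comfortably
stable estimates (e.g. the type-I rate's binomial SE at n = 1000 is
~0.007) while keeping a complete run in the low minutes on one core.

## Known limitations

* 2-D only; no time series; exactly two root orders.
* The RSML dialect is the subset needed for this trait set; richer RSML
  (functions, properties, 3-D) is rejected loudly, not interpreted.
* Angle ranking at a measurement point can differ from ranking at the seed
  when roots cross; the measurement-point convention is used throughout.
* The generator is a geometric emulator, not a growth model; its defaults
  are field-plausible settings chosen once, not fitted parameters.
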