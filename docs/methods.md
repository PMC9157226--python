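# Methods

## Coordinate frame and input validation

All analysis happens in the plane of the (possibly tilted) arena floor, as
seen by a camera mounted perpendicular to it: origin at the lower-left
corner, `x` across-slope, `y` up-slope, lengths in cm. The inclination
angle is metadata; it never enters the geometry, because the tracker
already reports floor-plane coordinates.

Positions up to 1 cm outside the arena are treated as tracker jitter and
clamped to the boundary; anything further out is an error. Sessions with
more than 50% missing frames are rejected. Dropout runs of at most
`max_gap` frames (default 12, about 0.5 s at 25 fps) are filled by linear
interpolation between the flanking valid frames; longer runs are left
invalid and split every downstream computation into independent segments,
so no step is ever formed across a gap. These thresholds are the package's
own conservative defaults — typical tracker exports do not document their
dropout process.

Two CSV dialects are read: a canonical `t,x,y,valid` table with `# key=value`
metadata lines (lossless round trip with `write_tracking`), and a
raw tracker-export dialect (`Key: value` header block terminated by a
column-header row with `Trial time` / `X center` / `Y center`, `-` as the
missing token).

## Step vectors, headings, distance

One step per consecutive pair of valid frames. The heading is the compass
angle of the displacement against the up-slope unit vector, computed from
the normalized dot product and disambiguated by the sign of the
across-slope component; it is defined only for steps of at least
`min_step` = 0.2 cm. A zero-length step has no direction, and near-zero
steps are dominated by tracker jitter; excluding them from direction
histograms (but never from distance) suppresses that noise without biasing
the path-length integral. Distance is the plain sum of step lengths; an
optional centered moving-average smoother exists but is off by default
everywhere, so reported numbers are never silently filtered.

## Zones, traversals, strip occupancy

A frame within 20 cm of a wall is "at" that wall; the bottom strip is the
lowest 15 cm. Coast-to-coast traversals are scored per axis independently:
each ordered pair of consecutive visits to *opposite* wall zones on that
axis yields one event, spanning from the last frame of the first visit to
the first frame of the second. Scoring axes independently is deliberate:
an animal hugging the bottom edge while crossing left-to-right sits in the
bottom wall zone throughout, and that must not interrupt the horizontal
event (edge-hugging crossings are the dominant behavior at steep tilts).

Events are classified with a drift bound `drift_max` = 15 cm on the mean
absolute deviation of the cross-axis coordinate from its value at the
event start: horizontal events with mean y in the strip are
bottom-horizontal; otherwise drift ≤ 15 cm separates upper-horizontal and
(for the vertical axis) vertical events from diagonal ones. Whether the
~15 cm figure is a selection bound or a descriptive statistic of detected
events is ambiguous in the source experiments; both the bound (a
configurable parameter) and each event's drift are exposed so either
reading is reproducible. Mean y (not max y) decides strip membership so a
single-frame excursion cannot reclassify an event.

Strip occupancy assigns each step by its midpoint (error bounded by one
step length, i.e. millimeters at 25 fps); the expectation is the strip's
share of arena height (15% in the default arena) times total distance —
what a spatially indifferent walker would lay down.

## Direction profiles

Twelve 30° sectors *centered* on the cardinal directions (boundaries at
15° + 30k, half-open, lower edge inclusive), so "straight up", "straight
down", and the two horizontal directions are each a single sector. Sector
percentages are, by default, of the directed steps retained after the
strip and `min_step` exclusions, so they sum to 100; a `frames`
denominator (percentage of all session frames) is also available.

The choice matters for the statistics: with the retained-steps denominator
every subject sums to 100, so in the split-plot sector ANOVA the
between-subject stratum is identically zero (the package flags the result
as degenerate rather than reporting 0/0). Between-subject effects on
sector profiles are only estimable under the frames denominator, where
subjects differ in their retained fraction.

Hemisphere folding (summing mirrored sector pairs; an averaging mode
exists for 12-sector plotting parity) is gated by a paired two-sided t
test of each mirrored pair across animals with Holm correction over the
five pairs: folding is justified iff no corrected p < 0.05.

## Head roll

The lateral head axis is the segment joining the two eye (or ear-base)
keypoints; roll is the acute angle between it and the image horizontal,
unsigned in [0°, 90°] — the magnitude of roll indexes head leveling, and
the sign (available via `signed=True`) only encodes which way the head
tipped relative to the slope. The per-animal statistic is the arithmetic
mean over at least 9 frames (frontal-view captures of less active animals
can be that sparse; the minimum is configurable).

## The ANOVA layer

All designed analyses are balanced, and the engine verifies balance before
decomposing. Sums of squares use the classical balanced decomposition,
computed by inclusion-exclusion over marginal means (identical to
sequential least squares on the orthogonal design; the test suite checks
this equivalence against explicit design-matrix projections to 1e-8).
The split-plot layout tests between-subject terms against
subjects-within-cells and within-subject terms against the
subject-by-within residual, with uncorrected degrees of freedom by default
(matching how such tables are conventionally reported); a
Greenhouse-Geisser correction is available behind a flag. With 3 species ×
7 inclinations × 10 subjects × 12 sectors this yields the canonical df
pairs (2, 189) for species and (11, 2079) for the sector main effect.

Partial eta-squared is SS_effect/(SS_effect + SS_error-of-stratum), which
equals F·df₁/(F·df₁ + df₂) for every reported effect. Tukey HSD p-values
come from the studentized-range distribution (scipy) with the pooled
within-group mean square; the per-pair q statistic and simultaneous 95%
intervals are reported. Alpha is 0.05 throughout. When an error stratum
has (numerically) zero variance the result is flagged degenerate: F is ∞
if the effect is real, 0 if the effect is also zero; the zero threshold is
1e-12 of the total SS, so roundoff in exactly-null constructions does not
masquerade as an infinite effect.

## The synthetic generator

`simulate_trajectory` is a two-state behavioral model, not a biomechanical
one:

- a Markov chain alternates **edge-follow** (thigmotaxis: wall-following
  along the bottom strip) and **explore**, parameterized by the stationary
  edge probability `p_edge` and mean dwell `state_dwell` (default 100
  frames ≈ 4 s);
- in explore, each frame's target heading is drawn from a von Mises
  mixture centered on the four cardinal directions plus a uniform
  component (`heading_weights`, concentration `kappa` = 12), then blended
  with the previous heading through `persistence` = 0.75 — a correlated
  random walk;
- in edge-follow the animal first descends (heading 180° + noise) until it
  reaches the strip, then follows the bottom edge at ±90° + noise with y
  clamped to the strip, reversing direction on side-wall contact.
  Descend-first avoids the unphysical alternative of teleporting the
  animal into the strip on state entry;
- step lengths are Gamma (mean `step_mean` = 0.2 cm/frame ≈ 90 m per
  30-min session on the flat, CV 0.6); walls reflect; the session starts
  at the arena center. All randomness comes from one seeded generator, so
  a seed reproduces a session bit for bit.

`make_cohort` derives per-subject seeds from one root seed and applies a
per-inclination profile. The shipped profile makes `step_mean` fall
(0.210 → 0.105 cm/frame), `p_edge` rise (0.15 → 0.80), and the vertical
heading weight rise (0.28 → 0.80, uniform weight 0.40 → 0.06) from 0° to
90°. The vertical-weight gradient is deliberately steep: the measured
vertical fraction is compressed relative to the generative weights
(persistence smears headings, and exits from edge-follow leak horizontal
persistence into the zone just above the strip), and a shallower gradient
produced a profile whose measured vertical fraction was not monotone in
expectation at low tilts. With these settings the three observed trends —
distance falling, strip share rising, vertical fraction above the strip
rising — are monotone in the per-level means (rank correlation ±1.0 at
4 subjects × 3 replicate cohorts × 8-min sessions, the sizes used by the
trend checks).

`simulate_eye_keypoints` draws a signed roll from Normal(mu, sigma)
clipped to [−90°, 90°]; the *measured* roll is the unsigned acute angle,
so at mu = 0 the measured angles are half-normal with mean σ√(2/π) — the
closed form the tests check.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis is designed to
detect: activity levels, strip concentration, heading anisotropy, and
their trends with inclination. It does not emulate gait, body posture,
home-base behavior, session-internal habituation, or tracker artifacts
(dropout, jitter are added separately in I/O tests). Passing tests
therefore validate the measurement chain and the statistics, not any claim
about real animals.

### Estimator caveats verified by the tests

- `vertical_fraction` is a consistent estimator of w_up + w_down only for
  drift-free vertical weights (w_up = w_down) and concentrated headings:
  with unequal weights the reflecting walk pins at a wall, where realized
  step directions deviate from drawn headings (about 2 percentage points
  of bias at weights 0.4/0.3). The recovery check runs at 10× session
  length with kappa = 200 and no persistence or edge state.
- Monotonicity of strip share in `p_edge` is assessed with the *paired*
  (per-seed) rank correlation across the {0.1, 0.5, 0.9} grid: a pooled
  rank correlation over a 3-level grid is capped at 0.943 by tied ranks
  even under perfect separation, so the pooled form cannot measure the
  property.
- Type-I calibration of the inclination effect uses 200 flat-profile
  cohorts with short (40 s) sessions — the null rejection rate does not
  depend on session length, so short sessions are pure efficiency.

## Pipeline

`run_experiment1` maps a cohort to a per-animal metric table, group
summary tables (mean ± SEM distance per cell, formatted to one decimal
with full precision kept in the machine-readable CSVs), and the statistics
bundle; every group-table number is recomputable from the per-animal CSV,
and identical inputs give identical outputs. Subjects failing validation
are logged and excluded by default (`strict=True` raises instead); a
factor that ends up with a single level (e.g. a one-species cohort) is
dropped from the factorial rather than aborting the run.
`run_experiment2` does the analogous mapping for head-roll keypoint
sessions (one-way ANOVA + Tukey). The numbered scripts under `analysis/`
are thin narrative drivers over these functions and the library is the
single source of every computation.

## Known limitations

- Step-to-strip assignment by midpoint misallocates at most one step
  length per boundary crossing; at 25 fps this is sub-millimeter in the
  session totals.
- The traversal definition has no minimum-duration or minimum-speed
  criterion; a stationary animal drifting across a zone boundary in jitter
  could in principle score a visit (the `min_step` threshold does not
  apply to zone membership). Real sessions with heavy jitter should be
  smoothed first.
- The split-plot engine requires complete balance; it refuses (with named
  cells) rather than approximating unbalanced layouts, which would need a
  mixed-effects formulation that is out of scope.
- Sector percentages on the default denominator carry a sum-to-100
  constraint that makes between-subject main effects inestimable (see
  above); analyses of "how much" animals travel belong to the distance and
  occupancy metrics, not the sector profile.
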