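# Methods

## Measurement model

All coordinates are normalized to the image (x, y ∈ [0, 1]) with y
increasing downward; "up" means decreasing y. Every postural component is
reduced to a non-negative angular deviation in degrees, measured in one
viewing plane from named landmarks:

| component | view | measurement |
|---|---|---|
| hip_level | frontal | tilt of the left-hip → right-hip line from horizontal |
| trunk_fb | sagittal | inclination of mid-hip → mid-shoulder from vertical |
| trunk_ss | frontal | inclination of mid-hip → mid-shoulder from vertical |
| neck_front | sagittal | head axis (mid-shoulder → ear) deviation from the trunk axis |
| neck_side | frontal | mid-shoulder → nose deviation from the trunk axis |
| shoulder_relaxed | sagittal | forward-slump deviation: 180° − angle(shoulder; ear, hip) |
| shoulder_level | frontal | tilt of the shoulder line from horizontal |
| upper_arm | frontal | abduction: angle(shoulder; elbow, hip) on the instrument side |
| elbow | sagittal | forearm (elbow → wrist) inclination from horizontal |
| wrist | frontal | 180° − angle(wrist; elbow, index); the worse of the measurable hands |

Angles at a joint use the dot-product/arc-cosine relation with the cosine
clamped to [−1, 1]; coincident points (separation ≤ 1e-12) raise a
degenerate-geometry error naming the landmarks. Midpoints fall back to the
single visible side's landmark, since the sagittal camera sees the
operator's left side. The instrument specifies no particular landmark
triplets; this mapping is the package's declared reconstruction, kept in
one place so alternatives can be tested.

Two conventions are worth calling out. First, neck angles are measured
against the trunk axis rather than the image vertical (`neck_reference:
trunk`), so a leaning trunk is not double-counted in the neck score — the
instrument scores head/neck separately from trunk. The `vertical`
alternative is available in the thresholds configuration. Second, the
shoulder-slump proxy stores the *deviation* of the ear–shoulder–hip chain
from straight (180° minus the interior angle) with a 20° tolerance, which
is identical to requiring the interior angle to stay above 160° but keeps
every component's rating monotone non-decreasing in the stored value. The
proxy is a heuristic: a flexed neck moves the ear and therefore also this
chain, so "relaxed" is only approximately independent of neck posture in
real images.

## Rating bands and the scorecard

Printed band edges of the assessment sheet: trunk and neck ≤ 20°
acceptable, strictly between 20° and 45° compromised, ≥ 45° harmful; wrist
flexion/extension ≤ 15° acceptable (no harmful band); upper-arm abduction
below 20° compromised; forearm beyond 60° harmful. Where the sheet leaves
an exact boundary unassigned, the package resolves it explicitly:
upper-arm abduction of exactly 20° is rated harmful (conservative,
mirroring the trunk's ≥ 45 pattern) and a forearm at exactly 60° is
compromised. "Parallel to the torso" is operationalized as abduction
≤ 5°, since literal 0° is unattainable; hips/shoulders are "level" within
5° of horizontal. These tolerances (τ) are not stated by the instrument;
the defaults are conventional ergonomic tolerances and all live in a YAML
thresholds file (`Thresholds.from_yaml`), alongside the instrument side
(default right) and the neck reference.

Points are 1/2/3 for acceptable/compromised/harmful; only trunk (both),
neck (both), upper arm and elbow may score 3. Totals therefore span 10–26
with overall categories 10 / 11–20 / ≥ 21.

## Occlusion policy

A landmark is usable when present with confidence ≥ c_min (default 0.5,
the conventional visibility cut; absent ≡ confidence 0; exactly c_min is
kept). Each component declares its required landmark groups; the wrist
accepts either hand. Under the default strict policy a subject failing any
component is excluded entirely, matching whole-participant exclusion in
observational practice; a partial policy instead keeps the subject and
marks components unmeasurable. Exclusions are logged per subject with the
failing component, the missing landmarks and the reason.

## Synthetic data

The generator is the forward model inverse to the measurement mapping:
given one target angle per component it places landmarks so that
measurement recovers every target to within 1e-6° noise-free. Frontal
construction is direct (tilted hip/shoulder lines symmetric about the
midline, a leaned trunk axis, a rotated head axis, an abducted instrument
arm, a deflected hand with the other hand kept straight so the worst-hand
rule is exact). Sagittally, the neck and slump measurements share the ear,
so the generator emits far-side landmarks mirrored about the midline — as
2D pose estimators do for the hidden side — and solves, in closed form,
a small common offset of the near-side shoulder/hip chain (horizontal or
vertical, whichever admits the smaller in-frame solution) that realizes
the requested slump deviation while leaving the midline points, and hence
the trunk and neck measurements, untouched. Target combinations with no
in-frame solution (for example a perfectly straight ear–shoulder–hip chain
with the head flexed far past horizontal) raise a feasibility error.

Cohorts draw each subject's per-component category independently from
per-group probability vectors, then draw the angle uniformly within that
category's band, kept 1e-3° clear of the edges so sub-micro-degree
measurement error cannot flip a rating. Harmful bands are capped at 80°
(trunk/neck) and 90° (elbow), binary-component bands at 30° (tilts) and
60° (slump, wrist abduction), to stay anatomically plausible. When a drawn
angle set is geometrically unrealizable the angles are redrawn within the
*same* categories (rejection sampling), so category probabilities are
preserved exactly. A single global seed drives one derived stream per
subject, making cohorts bit-reproducible and stable under subsetting.

The shipped study-like preset has 75 analyzable subjects — 18/19/18/20
across the four academic levels, 36 male / 39 female, 5 loupes wearers at
fixed positions — with level-specific acceptable/compromised splits for
hip and wrist and cohort-wide marginals for the remaining components. One
published upper-arm row covers only 74 of 75 subjects; the preset assigns
the missing subject to harmful. The published total-score mean (14.2)
is not exactly implied by those same marginals (they imply ≈ 14.3), so the
preset targets the marginals, not the mean. With `n_occluded = 7` the
preset appends seven extra subjects whose elbow-side landmarks carry
confidence 0.1 — only landmarks distinctive to the upper-arm component,
so the exclusion is attributed to that component alone.

What the generator does *not* emulate: correlated components within a
subject (categories are sampled independently; real posture couples trunk,
neck and shoulders), realistic landmark noise structure (jitter is
isotropic Gaussian, optional), body-shape variation, and the
gender-by-wrist association (wrist probabilities are level-specific, so
gender effects appear only through the level composition). Passing tests
therefore validate the measurement/rating/exclusion machinery and the
statistics, not claims about real photographic cohorts.

## Statistics

Exact tests enumerate the full fiber of contingency tables with the
observed margins — directly over the free cell for 2×2, recursively row by
row for r×c (capacity-limited to totals ≤ 200 and ≤ 8 levels; beyond that
an explicit error is raised rather than a silent approximation). Table
probabilities are multivariate hypergeometric, computed with log-gamma
sums; the two-sided p is the sum of probabilities ≤ the observed table's
× (1 + 1e-7), the probability-mass ordering used by mainstream packages.
Every run verifies that the enumerated probabilities sum to 1 within 1e-9
and that the enumeration count matches an independent dynamic-programming
count of the fiber.

The Mann–Whitney U uses midranks; the asymptotic two-sided p uses the
tie-corrected normal approximation without continuity correction, and an
exact mode (N ≤ 12) enumerates all C(N, n₁) group assignments, counting
those at least as far from n₁n₂/2 as observed. The normal approximation is
known to deviate substantially from the exact p at these sizes — the
exhaustive worst case over all tie-free configurations with N ≤ 10 and
both groups ≥ 2 is 0.24 — so the exact mode is preferred whenever its
enumeration is feasible.

Logistic regression is fitted by iteratively reweighted least squares
(convergence |Δdeviance| < 1e-10, ≤ 50 iterations), standard errors from
the inverse observed information, Wald intervals with z = 1.959964 (the
97.5 % quantile at the precision SPSS uses — 1.96 shifts printed bounds at
two decimals). With a single categorical predictor the model is saturated,
so each Exp(B) equals the level-vs-reference cross-product ratio; this
closed form is asserted in the tests. A zero cell makes the MLE infinite
and raises a separation error — no silent ridge penalty. Binary logistic
is used throughout because only two outcome categories occur in the
analysis layer; a multinomial model over two categories reduces to it
exactly.

Printed odds ratios in source tables of this kind match truncation rather
than rounding (for example 170/27 = 6.296 printed as 6.29); the reporting
layer supports both conventions (`round_mode`), with p-values always
rounded half-up.

## Numerical and degenerate-input choices

Arc-cosine arguments are clamped to [−1, 1]; coordinates within 1e-9 of
the [0, 1] bounds are clamped, anything further out is an error. Zero-
margin exact tests return p = 1 with a warning. Identical constant groups
give U = n₁n₂/2, p = 1. Empty cohorts are contract violations in the
crosstab layer. Run manifests include a timestamp; the byte-identical
re-run guarantee covers the data outputs (landmark files, scorecards,
exclusion log, stats report), not the manifest itself.

## Problem sizes

The shipped preset uses the study-scale cohort (75–82 subjects); property
suites use 2000-subject cohorts for parameter recovery (observed category
frequencies within 4·√(p(1−p)/n) of the configured probabilities) and
complete enumeration up to N = 12 for exact rank tests. These sizes make
the full test suite and the acceptance script run in a few minutes on a
single CPU while keeping binomial sampling error well below the tested
tolerances.

## Known limitations

The component-to-landmark mapping is a reconstruction, not a published
standard; alternative mappings plug in via the thresholds/configuration
layer. 2D projection conflates out-of-plane rotation with in-plane angle
changes, and no camera calibration is modeled. The slump proxy couples
weakly to neck posture. The synthetic cohort's independence assumptions
are stated above; cohort-level conclusions about real operators require
real captures.
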