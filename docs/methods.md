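# Methods

This note documents the models, conventions and design choices behind
`vestigait`, in the spirit of a lab's standard-operating-procedure
document: enough detail that another movement-analysis group could
re-derive every number the package produces.

## Coordinate conventions

The lab frame is right-handed: X is the nominal progression
(antero-posterior) axis, Y medio-lateral (positive to the participant's
left), Z vertical; the origin lies on the floor at the walkway midline.
Positions are in meters, times in seconds from trial start, frames are
0-based, and the default sampling rate is 100 Hz.  All direction-dependent
parameters are computed against the *estimated* walking direction (the
principal axis of the horizontal mid-pelvis path, signed by net
displacement), so a trial recorded obliquely through the volume gives the
same numbers as one along lab X.  Turn-pivot trials get a piecewise
direction: the path is split at the extremum of progression and each
straight leg is fitted separately.

## Preprocessing

**Gap filling.**  Marker dropouts (NaN) of at most 10 frames are filled
per channel by cubic spline.  Longer gaps (up to 100 frames) are
reconstructed from marker inter-correlations: iterated low-rank
(rank-10 SVD) completion of the full frames × channels matrix,
initialized from the spline fill, up to 50 iterations or 1 µm
convergence.  Gait marker sets are highly redundant, so a trunk marker
blanked for 30 frames is recovered to a few millimeters.  Observed
samples are never modified; gaps longer than the limit are reported and
left unfilled.

**Filtering.**  4th-order low-pass Butterworth at 6 Hz, applied forward
and backward (`filtfilt`).  Zero-phase filtering is the gait-lab norm: it
preserves event timing at the cost of squaring the magnitude response (a
15 Hz component of 10 mm survives at well under 1 mm).

**Virtual joint centers.**  Hip centers by an inter-ASIS regression
(Bell-style fractions 0.19 posterior / 0.36 lateral / 0.30 distal of the
inter-ASIS distance, overridable).  Knee, ankle and elbow centers are the
lateral marker offset medially by marker radius + half joint width
(defaults 7 mm radius; widths 0.10 / 0.07 / 0.07 m) perpendicular to the
segment line.  Degenerate pelvis geometry (collinear ASIS/PSIS markers)
raises rather than producing silent nonsense.

**Gait events.**  The detector is coordinate-based: foot-strike
candidates are maxima of the heel-minus-mid-PSIS coordinate along the
local walking direction, foot-off candidates are minima of the
toe-minus-mid-PSIS coordinate (peak separation ≥ 0.55 s, prominence
≥ 4 cm).  Each candidate is then refined to the peak of the foot marker's
*upward vertical acceleration* within ±0.15 s: at landing the downward
heel velocity is arrested, at lift-off the toe acquires upward velocity,
and both transients put a sharp acceleration impulse exactly at the
event.  Unlike progression extrema or speed-threshold crossings, the
impulse peak is unbiased under symmetric (zero-phase) filtering and
insensitive to cadence and walking speed; against the synthetic walker's
ground truth all strikes land within ±10 ms (median ≤ 1 frame) across
comfortable, slow, fast, tandem, eyes-closed, turn and backward walking.
Per side, events are greedily reduced to a strictly alternating
strike/off sequence; trials without progression (standing) return an
empty table, and fewer than two strikes on a side raises a warning that
propagates as a missing value for cycle-based parameters.

## Body models

The CoM model has 9 segments (head+trunk, pelvis, lumped arms, thighs,
shanks, feet) with adult mass fractions, CoM ratios and gyration radii in
the de Leva / Dumas tradition, stored in code and overridable; fractions
must sum to 1 to 1e-9 (asserted at model build).  The whole-body CoM is
the mass-fraction-weighted sum of segment CoMs; velocity by central
differences.

Whole-body angular momentum uses a 13-segment model (head, thorax,
pelvis, upper arms, forearms+hands, thighs, shanks, feet).  Each segment
contributes a remote term `mᵢ(rᵢ−r_CoM)×(vᵢ−v_CoM)` and a spin term
`Rᵢ Iᵢ Rᵢᵀ ωᵢ`, with the inertia tensor diagonal in the segment frame
(gyration radii × segment length) and ω extracted from the antisymmetric
part of `Ṙ Rᵀ` of the marker-triad segment frame.  The CoM reference for
the momentum sum is the 9-segment CoM (recorded in the run metadata; the
two CoM definitions differ by millimeters).  WBAM is reported
dimensionless, normalized by body mass × height × walking speed; trials
slower than 0.1 m/s (standing) are left in absolute units, and the
normalization is configurable (`none` available).  Plane components are
tied to the walking direction: *sagittal* about the ML axis, *coronal*
about the AP axis, *transverse* about the vertical.  (Clinical usage
sometimes lists "coronal" and "frontal" as if distinct; they are synonyms
and map to the same component here.)

## Parameter battery

Twenty parameter columns are produced.  Side-dependent parameters (MoS,
step width, WBAM, GaitSD) use the left side for BV and HS and the
pathological side for UV, as a pure function of the subject metadata
(overridable).  When a parameter yields one value per gait cycle, the
per-trial value is the median across cycles, with the contributing cycle
count logged.  Three tasks carry a single parameter — tandem walk
(Step_number), backward walking (Walking_speed) and stairs (Task_time);
which single parameter survives for the latter two is this package's
choice, made on clinical-signal grounds — and every other cell of those
tasks is emitted as NR.

Selected conventions:

- **MoS** is evaluated at each leading-foot strike only (no
  continuous-time minimum).  ML sign: positive when the xCoM is medial to
  the lateral malleolus of the leading foot (mechanically stable).  AP
  sign: positive when the xCoM is behind the malleolus along progression;
  in steady forward gait the AP margin is typically negative (the xCoM
  passes the leading foot — that is what makes walking a controlled
  fall).  The pendulum length l is the mean vertical CoM height over the
  trial (standing calibration if available), after Hof's convention.
  Note `ω₀ = √(g/l)`: a longer pendulum *lowers* the eigenfrequency and
  so *increases* the velocity contribution `v/ω₀`.
- **Zone scores** overlay nested medio-lateral bands about the fitted
  walkway midline with half-width boundaries 0.1524 / 0.254 / 0.381 m
  (the 6/10/15-inch deviation bands of level-surface FGA scoring) and
  weights 0/1/2/3, both configurable.  The CoM score counts lateral
  *excursions*, each scored by the outermost zone it reaches — so a
  deviation-plus-catch-up event scores once at its maximal zone.  The
  foot score integrates *time*: for each outer zone z, the fraction of
  trial time during which both heels lie in zone ≥ z contributes
  weight(z).  The count/time asymmetry between the two scores is
  deliberate and preserved from their original definitions.  The
  alternative reading of "both feet in the zones" (each foot merely
  outside zone 0) is selectable via the zone weights.
- **Step width** is the ML distance between the leading heel at its
  strike and the contralateral heel at its previous strike, measured
  normal to the walking direction.  The step reference line is fitted to
  midpoints of consecutive opposite-side placements (these lie exactly on
  the centerline, where a fit to the raw alternating placements tilts on
  finite windows) with one robust re-fit that drops outlying midpoints
  (3×MAD, floor 2 cm) so catch-up steps cannot drag the line.
- **Tandem step count** measures heel deviation from the *physical* line
  on the floor — the lab X axis at a configurable lateral offset — not
  from a line fitted to the observed placements, which would absorb a
  systematic off-line drift.  Default tolerance 5 cm.
- **Double support** per cycle is the summed overlap of left and right
  stance intervals inside the cycle, with stance assumed from trial start
  when a side's first event is a foot-off.  The interval arithmetic is
  tested against brute-force boolean stance integration.
- **Head anchoring index** uses SDs of Cardan orientation angles
  (yaw–pitch–roll about walking-direction-aligned axes, unwrapped), per
  the usual definition; a variance-based variant is selectable.
  Angular-velocity RMS is normalized per percent of gait cycle by
  default (multiplying deg/s by cycle duration / 100), which removes
  cadence differences; `none` (deg/s) is available and the choice is
  echoed in run metadata.
- **GaitSD** uses nine lower-body variables (pelvis tilt/obliquity/
  rotation, hip flexion/abduction/rotation, knee flexion, ankle
  dorsiflexion, foot progression), each cut into gait cycles of the
  analysis side and resampled to 101 points; GaitSD is the square root of
  the mean over variables and time points of the between-cycle variance.
  The joint angles use simplified segment-frame definitions (long-axis
  angles for knee and ankle) — adequate for a variability statistic,
  not a substitute for a clinical kinematics report.

## Statistics

Normality is screened per group with Shapiro–Wilk, for reporting only —
with n = 10 per group the pipeline is nonparametric throughout.  Each
task × parameter cell gets a tie-corrected Kruskal–Wallis test across
BV/UV/HS (χ² reference, 2 df); constant data yield H = 0, p = 1 rather
than an error.  When p ≤ 0.05, Dunn's post-hoc z-tests on the pooled
ranks (tie-corrected, two-sided — the usual convention; sidedness is not
dictated by the design) are Holm-adjusted over the three pairs.  A strict
flag additionally marks cells with Kruskal–Wallis p ≤ 0.01; both
thresholds are configuration, and the strict flag annotates rather than
replaces the primary α.

Convergent validity is the Pearson correlation between each parameter and
the DHI, per patient group (BV and UV separately), with missing DHI
excluded pairwise and a minimum of 3 pairs.  Categories follow fixed
thresholds — discriminant: excellent p ≤ 0.001, good ≤ 0.01, moderate
≤ 0.05, fair < 0.1, else poor; correlation on |r|: excellent > 0.8,
good > 0.6, moderate > 0.4, fair > 0.2, else poor.  The p feeding the
discriminant category is the best (minimum) Holm-adjusted Dunn p when
post-hocs were run, else the Kruskal–Wallis p: group-level relevance
should be claimed on a pair-level difference, not on the omnibus alone.

The relevance tier conjoins three conditions: *relevant* = discriminant
≥ moderate AND convergent ≥ moderate AND excellent clinical
applicability; *interesting* = both validities ≥ moderate with weaker
applicability; else *not-relevant*.  The applicability ratings are an
editable table (they encode a subjective expert judgment of how easily a
clinician can assess the parameter without specialized equipment): the
seven "excellent" parameters are ML CoM rom, foot score, step width, ML
step, walking speed, step number and task time; CoM score and double
support are "moderate"; the model-heavy parameters (MoS, WBAM, anchoring
indices, angular velocities, GaitSD) are "poor".  The short-form report
lists, per retained task, its relevant parameters with a
direction-of-effect note derived from the BV vs HS group medians.

Descriptive statistics use linear interpolation between order statistics
at (n−1)·q (numpy's default percentile convention); the convention is
configurable.  The Monte-Carlo power routine draws normal groups at given
(mean, SD, n), applies the tie-corrected Kruskal–Wallis test to each
simulated cohort (vectorized over replicates) and reports the rejection
fraction; drawing parametrically and testing nonparametrically is the
design choice, recorded here because "nonparametric power calculation"
admits several readings.

## The synthetic walker

The walker is kinematic, not dynamic: marker positions are analytic
functions of gait phase plus noise.  That is sufficient because every
analysed parameter is positional/kinematic — no forces are ever needed.
Per trial it lays down a step timeline (cadence with Gaussian timing
noise), alternating heel placements (programmed width, ML placement
noise, a slow random-walk lateral veer, Poisson-timed lateral catch-up
steps), and drives: a pelvis following the step centerline with
step-locked ML sway and double-bump vertical oscillation; feet that
alternate stance (fixed placement) and swing (smoothstep horizontal,
sinusoidal lift — the smoothstep ends at zero velocity and the lift ends
with a velocity discontinuity, which is exactly the landing transient the
event detector keys on); legs closed by two-link inverse kinematics
(thigh = shank = 0.275 × height, distance clamped to 99.9% of full
extension); a trunk with phase-locked yaw/roll/pitch oscillation and
per-cycle amplitude jitter scaled by the kinematic-noise parameter; arms
as sagittal pendulums in anti-phase with the legs; and a head whose
orientation is `coupling × trunk motion + (1 − coupling) × independent
small stabilized motion` — coupling 1 reproduces "en bloc" head-trunk
rigidity (anchoring index −1), coupling 0 a space-stabilized head.

Task modifiers: slow/fast gait scale speed and cadence; dual tasks slow
slightly; eyes-closed multiplies step width, sway and the lateral veer
(vision normally clamps the veer); tandem walking places heel-to-toe
steps on the line with a per-step off-line hazard; turn-pivot walks out,
turns 180° over four steps and walks back; head-turn tasks superimpose
large 0.4 Hz head yaw or pitch oscillation; backward walking reverses
the heading at reduced speed.  Stairs trials reuse the walking generator
(only task time is analysed for them).

Group presets: walking speeds are anchored to the three groups'
comfortable-gait means and SDs (BV 1.09 ± 0.22, UV 1.05 ± 0.17, HS
1.29 ± 0.09 m/s).  The remaining contrasts are synthetic choices made
once to reproduce the qualitative clinical picture — patients walk wider
(step width 0.16 / 0.12 / 0.10 m for BV / UV / HS), sway more (32 / 24 /
18 mm), couple the head more rigidly to the trunk (0.75 / 0.55 / 0.35),
take occasional catch-up steps (2 / 1 / 0 per minute), drift more without
vision, and fail the tandem line more often (per-step hazard 0.25 / 0.10
/ 0).  A per-subject latent severity couples the gait deviations to the
simulated DHI (so convergent correlations are recoverable by
construction); `null_presets()` gives the negative control: all three
groups share one profile and the DHI is dispersed but severity-decoupled,
leaving neither discriminant nor convergent signal.

What the walker does *not* emulate: muscle dynamics and ground-reaction
forces, soft-tissue artifact, marker occlusion patterns of real labs,
asymmetric pathology (UV subjects walk symmetrically apart from the
analysis-side convention), double-bump CoM power exchange, and gross
balance losses.  Passing tests therefore demonstrate that the pipeline's
estimators recover the quantities they claim to measure from marker
kinematics with realistic noise — not that the group contrasts of any
particular clinical cohort will reproduce.

## Problem sizes

The default synthetic cohort is 10 subjects per group — the scale the
statistical design (Kruskal–Wallis at n = 10 × 3) is built around — with
12 steps per trial at 100 Hz.  The test suite exercises the full 14-task
battery at reduced subject counts and runs the cohort-scale checks
(parameter recovery, relevance synthesis) on one- and two-task subsets at
the full 10-per-group size; the null-calibration experiments use 40
fixed-seed marker-level cohorts on the comfortable-gait task plus ≥ 2000
parameter-level null cells for the type-I rate.  The power routine uses
20 000 Monte-Carlo replicates (binomial SE ≈ 0.002 near 0.9).

## Known limitations

- The event detector's vertical-acceleration refinement expects a
  heel-strike transient; on heavily smoothed real data (cut-offs well
  below 6 Hz) it degrades toward the raw progression-extremum timing.
- Zone scores rarely leave zone 0 on the synthetic cohort (the walker's
  veer is modest relative to the 15 cm innermost band), so their
  discriminant behavior is exercised mainly by constructed trajectories
  in the tests.
- Turn-pivot parameters use the piecewise straight-leg approximation;
  quantities during the turn itself (≈ 4 steps) inherit whichever leg's
  frame they fall into.
- Anthropometry is scaled only by total mass and height; no
  subject-specific inertia beyond that.
- The DHI is simulated from a single latent severity; real
  patient-reported outcomes are noisier and multi-factorial.
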