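# Methods

`septostrain` measures mechanical discoordination of the inter-ventricular
septum from B-mode cine-loops and quantifies how reproducibly it can be
measured in an exercise-echo protocol. This note records the models,
estimators, numerical choices and limitations behind each stage.

## Discoordination indices

A septal longitudinal strain curve ε(t) (percent, negative = shortening,
zero at mitral valve closure) is decomposed over the closed systolic
window [MVC, AVC] into alternating *shortening* and *stretch* segments:
consecutive sample increments of equal sign are merged into one segment;
zero increments extend the running segment. From the decomposition:

- **SS** (systolic shortening) = Σ |negative changes| — effective work;
- **SRSsept** (systolic rebound stretch) = Σ positive changes over
  stretch segments occurring *after* the first shortening onset —
  wasted work. Stretch preceding any shortening ("pre-shortening
  stretch", the early septal motion typical of LBBB) is flagged and
  excluded; a single flag (`include_pre_stretch`) switches to counting
  all systolic stretch for sensitivity analyses.
- **SDI** = SRSsept / SS. Exercise raises afterload and shrinks all
  systolic strain amplitudes, so only the ratio is labelled comparable
  across intensities. SS = 0 raises an explicit undefined-SDI error.

Because segment changes sum the raw increments, the telescoping identity
SS − (SRSsept + pre-shortening stretch) = −(ε(AVC) − ε(MVC)) holds to
machine precision on every curve; the test suite checks it, and checks
the whole decomposition against a brute-force sign-run oracle, on
thousands of random curves. An optional `noise_floor` (default 0, i.e.
the literal definition) treats increments below a magnitude threshold as
zero for segment *classification* while still summing them, preserving
the identity.

Exercise response classification: SDI at 30% and 60% of the ventilatory
threshold each compared with rest; both lower → consistent improvement,
both not lower → consistent worsening (ties conservatively counted as
worsening), otherwise reciprocal.

## Valve timing under exercise

Systole is bounded by MVC and AVC, measured at rest (Doppler or visual).
During exercise no Doppler timing exists, so the resting systolic
duration is rescaled: smoothing splines (generalized cross-validation by
default; `lam=0` interpolates) are fitted to a reference table of
systolic/diastolic duration versus heart rate, and

    systole(HR_ex) = systole(rest) × spline_sys(HR_ex) / spline_sys(HR_rest),

with the cycle length set to 60/HR_ex and AVC = MVC + scaled systole.
The packaged default table uses the classic linear
electromechanical-systole relation of the systolic-time-interval
literature (QS2 ≈ 0.546 − 0.0021·HR seconds, diastole the cycle
remainder, tabulated 50–130 bpm); any user table with the same columns
can be substituted, including phase-specific (stress vs relaxation)
tables. Heart rates outside the table range are clamped with a warning.
At 0.34 s of ejection and 90 Hz the frame counter returns 31 frames
(half-open [MVC, AVC) convention; the closed convention would add one),
consistent with roughly thirty frames of ejection in this protocol.

## Synthetic data

No public dataset of exercise septal cine-loops exists; the generator is
therefore a first-class, tested component that defines the study
conditions.

**Strain curves.** Piecewise cubic-smoothstep segments between knots
whose *times* land exactly on the frame grid and whose *values* are
solved from the targets (SS, SRS, pre-stretch, optional peak systolic
strain): with zero slope at every knot and monotone segments between
them, the sampled curve's decomposition reproduces the targets to
machine precision. The seed jitters knot timing only (±2% of systole).
LBBB-type curves carry two rebound stretches by default; non-LBBB curves
shorten monotonically. Post-systolic behaviour is either recoil to zero
by mid-diastole or a plateau with late recoil; both return to 0% at the
cycle end so cycles concatenate.

**Geometry and kinematics.** The septum is an annular band segment
(centre at the image bottom, radius 0.55·height, 1.1 rad span, thickness
0.055·height for 800×600; scaled for other sizes). Deformation stretches
the centerline arc by λ(t) = 1 + ε(t)/100 about the mid-arc with
incompressible thickness compensation (radial offsets divided by λ), so
centerline longitudinal strain is exactly the prescribed curve; across
the 11 radial rows the arc-length strain deviates by under 0.05% strain
at this geometry, which the tests verify by re-deriving strain from the
stored mesh trajectory.

**Speckle.** ~2000 point scatterers uniform over the band (Rayleigh
amplitudes) plus ~3000 dim background scatterers, each rendered as an
exact sub-pixel Gaussian PSF (σ = 2 px); no wave simulation. Frames are
the advected scatterer field plus Gaussian noise of SD = `noise_level` ×
the noise-free stack SD. A `dropout_fraction` of frames (never frame 0)
receives an occlusion disc of random size (0.06–0.16 of the arc length)
and position, zeroing part of the septum — the mechanism standing in for
out-of-plane motion and shadowing. The intensity→(noise, dropout) table
defaults to values that make the good/moderate/poor mix and the
exclusion rate worsen from rest to 90% VT; it is configuration, not a
claim about physics.

**Cohorts.** Each subject carries base targets (SS ~ U(10, 18)%; SRS ~
U(2.5, 5.5)% for the LBBB-type fraction, default 44%), a response type
(improve / worsen / reciprocal with probabilities 8:4:3) that multiplies
SRS at the exercise stages, and an SS amplitude reduction with intensity
(down to ×0.85 at 90% VT). Heart rates rise monotonically from rest
(~60 bpm) through 30/60/90% VT (~79/90/97 bpm) with recovery elevated.
Each visit's targets are the subject base plus independent zero-mean
Gaussian noise (SD = `visit_noise_sd`), so a test–retest difference has
SD = √2 × `visit_noise_sd`; observer variability is modelled downstream
as additive reading noise (SD = `observer_noise_sd`) on SRS and SS, with
SDI recomputed from the noisy pair. All randomness flows from explicit
seeds; identical seeds give bit-identical datasets.

## Mesh and tracking

**Mesh.** The segmentation polygon (manual in practice; the band outline
in simulation) is rasterized, its medial axis extracted (fixed RNG —
scikit-image's skeletonization otherwise breaks ties randomly),
low-clearance corner branches pruned, the longest skeleton path smoothed
with a parametric spline, extended to the band ends, and resampled into
31 equidistant stations; 11 points span the thickness along the local
normal, inset from the boundary. Local frames: longitudinal = medial
axis tangent, radial = its normal. Degenerate polygons (self-
intersection, area < 50 px², aspect ratio < 1.5) are rejected.

**Block matching.** For every consecutive frame pair and mesh point the
normalized cross-correlation of a 21 px block is evaluated over a ±10 px
search window (both configurable; at 90 Hz per-frame motion is a few
pixels, so tests and the acceptance script use ±5 where noted).
Sub-pixel refinement is a full 2-D quadratic fit (with cross term) to
the 3×3 log-correlation neighbourhood — a separable parabola is biased
wherever the band runs obliquely to the pixel axes — followed by one
differential (gradient/optical-flow) step: the target block is resampled
cubically at the fractional displacement and a 2×2 least-squares system
gives the residual shift. The differential step was added because
correlation-peak interpolation alone leaves a per-point bias of
~0.02 px/frame that accumulates over the ~80 frames of a cycle to
~1.5 px of trajectory drift; with it, noise-free full-size loops track
to ~0.3 px RMSE. Matches with peak NCC < 0.4, zero-variance blocks, or
blocks leaving the image are flagged invalid (never silently zeroed) and
in-filled with the median of valid mesh neighbours; a frame pair with no
valid match aborts the loop. No drift compensation is applied across the
cycle; residual cycle-closure drift feeds the quality grade instead.

**Strain estimator.** Mesh positions are the initial mesh plus
cumulative summed displacements. At each point, longitudinal strain is
the least-squares slope of the cumulative longitudinal position change
(displacement projected on the initial local tangent) versus the initial
arc-length coordinate, over a sliding 7-station kernel (shrunk at the
band edges; 7 of 31 balances noise against spatial resolution). The
curve is the mean over valid points, in %, zero at the first frame.
Uniform translation yields exactly zero strain; a linear contraction
yields its slope exactly.

**Quality grading.** Four component scores in [0, 1]: septal/background
intensity-SD contrast; structure definition (correlation of frames with
a lightly smoothed copy — diffuse noise decorrelates it); plane
stability (cycle closure of the mean mesh position, saturating at 5 px);
artefact burden (1 − invalid-match fraction). Grade: *poor* if any
component < 0.3 or the mean < 0.45; *good* if the mean ≥ 0.70 with all
components ≥ 0.3; else *moderate*. Exclusion is separate and mirrors the
incomplete-septum rule: any frame pair losing > 30% of mesh points.
Diffuse noise degrades the grade but rarely excludes (per-block NCC has
small sampling spread); occlusions exclude. All thresholds are exposed.

## Agreement statistics

Bland–Altman (bias, sample SD, bias ± 1.96·SD in absolute strain units),
Pearson correlation of amplitude-normalized curves (the longer cycle
down-sampled by linear interpolation to the shorter's length — Pearson r
is scale-invariant, so amplitude normalization affects only reported
curves), the paired Student's t-test, Cohen's kappa from marginal
products, and ICC(A,1) — two-way model, absolute agreement, single
measurement — computed explicitly from the ANOVA mean squares with the
McGraw–Wong F-based 95% CI. Independent oracles (a hand-rolled ANOVA
decomposition, pingouin, scikit-learn, scipy) verify each estimator in
the tests; missing pairs are dropped listwise with a logged count, and
degenerate inputs raise typed errors rather than returning NaN. For the
kappa of exercise-induced changes, "no change" is dichotomized as
worsening (conservative; a flag exposes the alternative).

## Pipeline

`run_pipeline` executes simulate → segment (`build_mesh` on each loop's
polygon) → track → grade/exclude → time-scale → indices → observer
readings → agreement, and emits a report (JSON + CSV + optional
Bland–Altman panels) containing the feasibility table, per-condition
agreement for SRSsept and SDI in the three contexts (test–retest,
intra-, inter-observer), the ΔSDI response counts and the 30%-vs-60%
kappa per observer, and a provenance block (config, config hash, seed).
Reports contain no timestamps; a fixed seed makes the run byte-
reproducible. `analytic_only=True` skips imaging and uses the analytic
indices — used for the large Monte-Carlo cohort studies.
`analyze_existing` applies the same tracking/index stages to externally
supplied loops (DICOM or PNG stacks with segmentation and timing
annotations), skipping loops with missing annotations.

## Problem sizes

The strain-recovery check runs 20 noise-free 800×600 loops at 90 Hz
(HR 75, ~77 frames) in the test suite and 10 in the acceptance script;
the index oracle uses 1000 random curves; ICC recovery 500 replicates of
a 200×2 design; cohort recovery 200 cohorts of 50 subjects (analytic
indices); degradation monotonicity 10 seeds × 3 dropout levels at
256×192 / 60 Hz. These sizes give stable Monte-Carlo estimates while
keeping a full run in the minutes range on one CPU.

## What passing tests do and do not show

The generator produces fully developed Gaussian-PSF speckle advected by
an exactly known 2-D deformation. Real exercise echocardiography adds
out-of-plane motion (true decorrelation, not just occlusion),
depth-dependent PSF and gain, reverberation and rib shadowing with
structure, probe repositioning between visits, and genuinely deforming
surrounding tissue. Recovery of truth here therefore validates the
*estimators* (tracking, strain, indices, statistics), not clinical
accuracy; the observer-noise model is additive and cannot reproduce
segmentation-driven observer disagreement. Timing scaling inherits
whatever reference table it is given — the packaged default is a
literature-shaped stand-in, swappable by design.
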