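# Methods

## What is being modelled

The package reproduces, in simulation, a dual-resolution imaging rig for
*C. elegans* motility assays: a whole-plate backlit view in which every worm
is tracked in software, and a motorized high-resolution view that follows
one worm at a time.  The analysis target is the displacement-module index
`M_k` — the per-instant Euclidean magnitude of the tracking controller's x/y
step commands — and the strain comparisons built on it.  Every component the
physical rig would provide (plates, worms, cameras, display, laser, motors)
is replaced by an explicit model with exact ground truth, so each algorithm
can be validated against truth rather than against another estimate.

## Scene simulation

**Worm motion.**  No quantitative per-strain motion model is available for
the strains of interest, so strains are parameterized by a deliberately
minimal persistent random walk: at each time step `dt` the heading turns by
`(1 − p) · U(−π, π)` with persistence `p`, and the worm advances
`v · E · dt`, where `E ~ Exponential(1)` and `v` is the strain's mean crawl
speed; with probability `pause_prob` the step is zero.  The exponential
speed draw gives heavy-ish bursts and stalls within a track, which spreads
the module histogram over several bins as real crawling does.  Worms reflect
off a wall 1 mm inside the plate edge, keeping the population constant as in
a walled dish.

**Strain presets** (stand-ins, not calibrated to real worms; magnitudes
chosen once from the usual *C. elegans* crawl-speed range):

| preset | mean speed (µm/s) | pause prob | persistence |
|---|---|---|---|
| wt-like | 150 | 0.05 | 0.9 |
| mild-deficit | 110 (−27%) | 0.10 | 0.9 |
| severe-unc | 25 | 0.50 | 0.6 |

The mild preset sits in a 20–30% speed reduction band relative to
wild-type-like, i.e. a deliberately subtle phenotype; the severe preset
moves rarely and slowly.

**Rendering.**  Worms are drawn as dark oriented capsules (default 1 mm ×
80 µm, grey level 60 below the backlight) — undulatory posture is a
non-goal, since the module index depends only on centroid motion.  The
macro camera images the plate at 27.31 µm/pxl on a 2592 × 1944 sensor; the
micro camera crops around the head position at 1.09 µm/pxl with Gaussian
defocus blur of sigma `defocus_gain · |z − focus_z|` pixels.  The laser
renders as a saturated disc, optionally doubled with a larger dim halo to
mimic the beamsplitter reflection.  Coordinate conventions (world mm with y
up, pixel row/col with row down, step axes aligned with pixel axes) are
documented once, in `scene_sim`'s module docstring.

What the simulator does *not* emulate: body posture and self-occlusion,
bacterial-lawn texture, agar surface artefacts, sensor noise, and worm–worm
contact dynamics (worms pass through each other; overlapping silhouettes do
merge in the rendered image, which is what triggers censoring).  Passing
tests therefore demonstrate correctness of the control and analysis logic
under clean imaging, not robustness to real-plate image noise.

## Active vision

The display (800 × 480 texels) and macro camera are related by a projective
transform fitted by least squares on bright-dot correspondences (5 × 5 grid
in the bundled calibration routine; ≥ 4 non-collinear dots required).  Each
texel owns the image pixels nearest its mapped centre; a proportional
controller (default gain 0.5) moves each texel by
`gain · (reference − mean grey of owned pixels)`, clipped to [0, 255].  For
any gain in (0, 2) this is a contraction toward the reference on a linear
camera, so a fixed point rather than integral action is the design choice.
The high-intensity circle used during micro capture follows a logistic
radial profile `I(d) = low + (high − low) · σ((radius − d)/slope)`; its
maximum gradient is `(high − low)/(4·slope)` per pixel, which is what keeps
the illumination compatible with adaptive-threshold segmentation.  The
logistic was chosen as the sigmoid; only "sigmoidal" is specified by the
rig's description, and the exact on-rig parameterization is unknown.

## Macrotracking

Segmentation is local-mean adaptive thresholding (box filter of odd window,
default 25 px, foreground = pixel < local mean − offset, default 15 grey
levels), 8-connected labelling, and an area gate (default 20–600 px², which
brackets a 1 mm × 80 µm worm at 27.31 µm/pxl ≈ 110 px²).  The window, offset
and gates are free parameters exposed in config and should be set to the
rendered (or imaged) worm size.

Identity association solves the optimal (minimum total Euclidean distance)
bipartite assignment between previous worm positions and current detections
— optimal rather than greedy matching makes the minimum-distance criterion
well-defined when several worms move at once.  Pairs farther than
`max_jump` (default 60 px ≈ 3× the expected per-frame travel) are broken;
identities without a detection may coast for `max_misses` frames (0 by
default, 3 in the closed-loop controller, where the laser spot transiently
corrupts segmentation near the tracked worm) before being **censored**.
Censored identities are never re-identified — recovering identity after
contact is out of scope — and new detections always get fresh ids.

## Robot model and controller

Pixel errors convert to step commands by multiplication with a configured
steps-per-pixel constant and rounding half away from zero.  The physical
step pitch is taken as 1.09 µm/step, the unit in which module histograms
are reported; with the micro camera at 1.09 µm/pxl the true micro ratio is
then 1.0 steps/pixel.  The rig description also quotes a micro pixel/step
ratio of 1.14, which implies a slightly different pitch; the two printed
values are mutually inconsistent at the 5% level, and the histogram unit was
chosen as authoritative because the metrics depend on it.  The 1.14 ratio
remains available as an explicit `StepModel` configuration and appears as
such in the unit tests.  Conversion constants default to values derived
from the simulated camera geometry, never hard-coded, and a
`step_scale_error` multiplier lets tests emulate a miscalibrated model
(the proportional loop contracts the pixel error by `|1 − s|` per iteration
for a model mis-scaled by factor `s`, e.g. 0.2 per iteration at 20% error).

Motion timing follows a trapezoidal velocity profile per axis under
v_max = 8000 stp/s and a_max = 25 000 stp/s² (triangular for moves shorter
than v²/a).  The parallax of the fixed-camera step model under agar-height
variation is `Δx = Δz · tan α` with half field of view α = 20.7°, i.e.
0.378 mm per mm of height offset — small enough that the proportional
regulator absorbs it.

The session state machine runs macrotracking constantly (1 fps) and cycles
SELECT → GOAL_ACQUISITION → MICROTRACK → FOCUS → CAPTURE per worm: lowest-id
untested worm first (a deterministic choice; selection order is otherwise
unconstrained), laser-guided acquisition until the pixel error drops below
15 px (retry limit 5, then the worm is skipped and flagged), centroid
servoing at 2 fps with the laser off, one 9-point focus sweep maximizing the
mean squared intensity gradient, then exactly
`round(micro_rate · micro_duration)` = 60 capture frames with the step
commands logged at each instant k (2 fps, matching the capture rate —
whether the real controller logs at its internal rate instead is unknown;
the rate is exposed in config).  Microtracking continues during the focus
sweep.  Losing the worm in the micro frame falls back to re-acquisition.

## Metrics and statistics

Modules are computed from logged control actions (steps) or from
ground-truth positions sampled at the capture rate and converted at
1.09 µm/step; a closed-loop property test keeps the two within one step per
instant of each other.  Per-worm sums are expressed as percent of the
maximum worm sum in the experiment (the normalization base is otherwise
unspecified; percent-of-group-total is available in config).  Histograms
use unit-width step bins starting at 0 with an overflow bin; the [0–1) bin
is interpreted as "most probably static", and such instants are kept, not
dropped.  Strain histograms pool all module values within a strain
(per-worm averaging is the exposed alternative).  All rank-sum tests are
two-sided; the exact branch enumerates all C(n+m, n) label assignments of
the pooled midranks (ties handled exactly) when min(n, m) ≤ 8 and
n + m ≤ 16, and the normal approximation applies tie and continuity
corrections otherwise; the two branches agree within 0.02 at n = m = 8.

## Numerical and testing choices

- Determinism: every stochastic component takes an integer seed
  (`numpy.random.default_rng` via `SeedSequence`); identical seeds give
  bit-identical scenes, frames and reports.
- Degenerate inputs raise typed errors (`InvalidParameterError`,
  `CalibrationError`, `FocusFailureError`, `InsufficientSampleError`, ...)
  rather than returning sentinel values; all-uniform focus stacks and
  identical constant samples (p = 1) are handled explicitly.
- Test problem sizes: unit and end-to-end tests run on small plates
  (radius 5–8 mm), small sensors (400–640 px macro, 256–512 px micro) at
  the physical pixel scales, and 0.1 mm worms that fit the micro crop with
  margin; the statistics suites use the full 30 worms × 4 replicates design
  image-free from ground-truth trajectories.  These sizes are the package's
  test design; the defaults in `RunConfig` remain the full-rig values.
- The acceptance script reports the largest of the four replicate p-values,
  i.e. the significance level that *every* replicate reaches.

## Known limitations

- Module histograms of the synthetic strains match the qualitative ordering
  of real strain data (least mobile strain highest in the [0–1) bin), but
  absolute bin frequencies depend on the invented motion parameters and are
  not calibrated to any real recording.
- Worm–worm contact is handled only by censoring; scenes with frequent
  contacts lose a corresponding fraction of identities.
- The micro view segments the largest dark blob; two worms in the same
  micro crop can swap which is servoed if the tracked worm is the smaller.
- Illumination is greyscale only; spectral ("light colour") control is out
  of scope.
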