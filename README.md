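# wormrig

A software re-creation of a dual-resolution Cartesian-robot rig for
motility-based healthspan assays of *Caenorhabditis elegans* in standard
55 mm Petri dishes.

The physical system this package models tracks every worm on a plate in a
low-resolution whole-plate view (27.31 µm/pxl, "macrotracking", pure
software) while a motorized head mechanically follows one worm at a time
with a high-resolution camera (1.09 µm/pxl, "microtracking"), guided by a
laser spot that marks the head position in the macro image.  A backlight
display under the plate is servoed against the camera so the image reaches a
uniform reference grey level (active vision).  Because no plates or cameras
are available in software, a built-in scene simulator generates ground-truth
worm trajectories per strain and renders both camera views, so the whole
control and analysis stack can be exercised and validated against exact
ground truth.

The package is aimed at researchers building or evaluating automated
*C. elegans* locomotion assays: it provides the tracking/servoing algorithms,
the motility statistics, and a simulator to test them end to end.

## The motility index

During each 30 s capture (2 fps, 60 images) the controller logs its x/y step
commands at every instant *k*.  The **displacement module** at instant *k* is

```
M_k = |AB| = sqrt((x_k − x_{k−1})² + (y_k − y_{k−1})²)
```

in motor steps (1.09 µm/step).  Because the control loop keeps the worm
centred, the commanded shifts reproduce the worm's own displacement to within
step quantization, so `M_k` is a per-instant speed measure.  Per-worm module
sums ("amount of movement", expressed as percent of the most mobile worm),
per-strain relative-frequency histograms of `M` in unit step bins, and
pairwise two-sided Wilcoxon rank-sum tests on the per-worm sums complete the
analysis.  The rank-sum test enumerates the null exactly for small samples
(min(n,m) ≤ 8, n+m ≤ 16) and uses a tie- and continuity-corrected normal
approximation otherwise.

## Worked example

Simulate three synthetic strains — wild-type-like (150 µm/s mean crawl,
5% pause), mild-deficit (110 µm/s, 10% pause) and severe-uncoordinated
(25 µm/s, 50% pause) — on 4 replicate plates of 30 worms each, and compare
them:

```
$ cat demo.yaml
scene:
  n_worms_per_plate: 30
  n_replicates: 4
  duration: 30.0
seed: 1

$ wormrig run --config demo.yaml --out demo_run
wt-like vs mild-deficit: p = 3.278e-34
wt-like vs severe-unc: p = 7.144e-41
mild-deficit vs severe-unc: p = 7.144e-41
```

All three pairwise rank-sum tests on per-worm module sums are significant,
including the deliberately subtle wild-type vs mild-deficit pair.  The run
directory contains per-worm metrics (`per_worm_metrics.csv`; mean module
sums here: wt-like 3899, mild-deficit 2727, severe-unc 343 steps), the
module histograms (`histograms.json`; the [0–1) step bin frequencies order
as severe-unc 0.538 > mild-deficit 0.118 > wt-like 0.064 — the
least mobile strain piles up in the "static" bin), the comparison report
(`comparison.json`) and one trajectory CSV per plate.

The closed-loop rig itself (rendered frames, laser-guided goal acquisition,
centroid servoing, autofocus, 60-frame capture per worm) runs with
`wormrig track --scene <trajectory.csv> --out <dir>` or
`wormrig run --track`, and from Python via
`wormrig.tracking_controller.run_session`.

## Layout

- `wormrig.scene_sim` — strain motility models, persistent-random-walk
  trajectories, macro/micro frame rendering
- `wormrig.active_vision` — texel↔pixel calibration, backlight control loop,
  sigmoid illumination circle
- `wormrig.macrotracking` — adaptive-threshold segmentation, size gate,
  minimum-distance identity tracking with censoring
- `wormrig.robot_model` — step kinematics, laser projection, parallax model,
  trapezoidal motion timing
- `wormrig.tracking_controller` — the acquisition/track/focus/capture state
  machine
- `wormrig.motility_metrics` — displacement modules, histograms, rank-sum
  comparison
- `wormrig.config` / `io` / `pipeline` / `cli` — configuration, file formats
  and the `wormrig` command

See `docs/methods.md` for the models, parameter choices and limitations.
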