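# Methods

This note documents the models, parameters and design choices behind each
pipeline, what the synthetic generators do and do not emulate, and the
numerical conventions used throughout.

## Two-photon ΔF/F pipeline

**Model.** A recording is raw fluorescence F(t, z, y, x) of a
noradrenaline sensor, acquired at 1.13 Hz for ~3 min (203 frames), with a
10 s odour air puff starting at frame 68 (1-based). The z-stack is
sum-projected; ΔF/F is computed per pixel against the baseline-window mean
F₀ (frames 20–67); each FOV is partitioned into 36 subtile ROIs (6×6); the
response statistic is the mean ΔF/F over frames 89–91 — the window where
an odour response peaks at this frame rate; ROIs are classified increase /
decrease / none; fractions are pooled over the cohort.

**Frame conventions.** All user-facing windows are 1-based inclusive and
converted internally to 0-based half-open slices. The first 20 frames are
retained in arrays but flagged invalid (startle/settling artefacts);
frame 20 is simultaneously the last dropped frame and the first baseline
frame: F₀ uses the full window 20–67, while trace statistics (the baseline
σ) use only retained frames (21–67). This keeps frame numbers aligned with
the acquisition's while excluding onset artefacts from noise estimates.

**Normalisation ambiguity.** Per-pixel F₀ is the default because it
supports spatial response maps; a `normalization="frame_mean"` switch
normalises to the whole-frame baseline mean instead. ROI traces are tile
means of ΔF/F.

**Classification threshold.** The increase/decrease call uses a dead band
of k = 2 baseline standard deviations of the ROI's own ΔF/F trace
(configurable). A pure sign rule would force increase + decrease = 100 %
and leave no "none" class; a ±2σ band is the conventional smallest effect
worth calling against baseline noise.

**Vessel handling.** Pixels whose F₀ falls at or below 10⁻⁶ of the movie's
global mean are excluded from tile means (division blow-up guard). The
animal-level grand average uses the 3 brightest ROIs per FOV by *raw*
baseline brightness — bright neuropil rather than dark vessel lumens — with
brightness ties broken by ascending ROI index (row-major) for determinism.

**Rigid correction.** An integer per-frame translation is estimated by
phase correlation against the temporal mean, clamped to ±`max_shift`, and
applied with edge padding. It removes bulk drift only and is the
transparent stand-in for non-rigid motion correction, which is out of
scope. Registration against the temporal mean aligns frames to the
majority position; it is exact when most frames share one position. It is
off by default for synthetic movies, which are generated without motion.

## Fibre-density pipeline

Area % = 100 × foreground / region pixels after thresholding. Manual
brightness/contrast adjustment is replaced by 1st–99th percentile
intensity normalisation (reproducible) before Otsu; fixed-threshold mode
is available for audits. Slices (4 per animal typically) are averaged per
animal; loss is computed on group means of animal means. Thresholding bias
is multiplicative to first order and cancels in the case/control ratio,
which is why recovered losses track planted losses to ~1 pp. Microglia and
plaque channels reuse the same operations; an optional connected-component
count (8-connectivity, physical-units size filter) supports cell-count
densities.

## 3D volumetry

Segmentation of a raw channel is threshold (Otsu or fixed) + removal of
components below a physical size, with 26-connectivity. Voxels are
anisotropic (e.g. 0.5 × 0.25 × 0.25 µm); all size filters and dilation
radii are specified in µm and rounded per axis, so the z-step need not
match the xy pixel size. Engulfment is the triple intersection
NET ∧ CD68 ∧ Iba1 in µm³; contact at radius r is
(dilate(Iba1, r) ∧ NET) − direct overlap, reported both as volume and as a
count of connected interface components, since "contact points" have no
canonical unit. Normalisation to axon density divides a volume by
(NET volume / stack volume). The segmentation is a documented, transparent
stand-in for commercial surface reconstruction and is not claimed
parameter-equivalent to it.

## Behaviour

Fusion averages the shared x axis of the two views, takes y from the top
and z from the side view, linearly interpolates frames missing from one
view (flagged), and requires overlapping frame ranges. Zone membership is
strict (`distance < 2 cm`; a frame at exactly 2 cm is outside). Entries
are debounced: exits shorter than 5 frames (configurable) do not split a
visit, because tracking flicker at the zone boundary would otherwise
inflate counts. The default phase schedule of the sensitivity test is
2 min baseline, 2 min low odour, 1 min break, 2 min high odour. Latency
tables are consumed as data; video scoring is out of scope.

## Phagocytosis assay

Index = total integrated intensity per image / cells per image; rows with
zero cells are flagged missing rather than set to zero. Group means are
across wells at the reference time (12 h); normalisation reports fold and
percent difference versus the control group. Fold is invariant to any
common rescaling of intensities.

## Synthetic generators

The generators define the study conditions; their defaults are the preset
parameters listed in `noradscope.presets` and are not tuned per run.

- **Movies**: smooth positive baseline texture (Gaussian-filtered noise
  mapped to [40, 100] intensity), 3 vessel-dark tiles per FOV (×0.05
  brightness), per-tile evoked plateau starting at the stimulus frame with
  amplitude ±0.04 ΔF/F, per-voxel Gaussian noise scaled so projected pixel
  ΔF/F noise σ is 0.005 (amplitudes are 8× the noise σ, comfortably
  classifiable — the real per-ROI amplitudes are not reported numerically,
  so these are not claims about data). Movies default to 120×120 px and 8
  z-slices so a cohort generates in seconds; the tiling is size-agnostic.
- **Fibre images**: random-walk polylines stamped with a circular brush
  until the planted area fraction is reached (±1.5 pp rasterisation
  tolerance), intensity 120 on background 20, noise σ 6, clipped at 0.
- **Volumes**: ellipsoidal cells with nested lysosomes (clipped to their
  parent), random-walk tubes, a configurable fraction routed through cell
  centres; stored intersections are always voxel recounts of the masks.
- **Trajectories**: reflected random walk in a 20 cm box, step σ 0.5 cm,
  drift of `attraction` step-σ toward the tip; camera views are exact
  orthogonal projections plus optional jitter.
- **Latencies / uptake**: lognormal latencies (mean 40 s, CV 0.3, case
  ratio 1.6); logistic uptake curve (plateau 20, midpoint 6 h, width
  2.5 h) with the case curve a constant fold (1.33) of control and a
  per-well multiplicative noise factor (CV 0.1); an optional cytoD group
  has zero uptake.

**Variance control.** Per-subject draws use jittered stratified (quantile)
sampling, and the two-photon cohort plants class labels with exact rounded
counts placed at random, rather than iid draws. The emulated cohorts are
small (5 animals, 12 wells, 324 ROIs); stratification keeps each sampled
group representative of its population parameters, the way the reported
group contrasts are, while remaining random and seed-deterministic.
Population parameters are unchanged by this choice.

**What the generators do not emulate**: optics (PSF, photobleaching,
depth-dependent scattering), non-rigid tissue motion, sensor kinetics
beyond a step plateau, correlated biological variability across slices of
one animal, real pose-estimation failure modes. Passing recovery tests on
these data therefore demonstrates the correctness of the measurement
chain, not robustness to every artefact of real recordings.

## Determinism and numerics

Every generator draws from one `numpy` Generator seeded per call, with
per-FOV/per-image substreams spawned deterministically, so identical
(parameters, seed) give bit-identical outputs. Degenerate inputs are
rejected with explicit errors (constant images for Otsu, empty regions,
disjoint camera frame ranges, zero-cell images flagged missing). Tile
grids distribute remainder pixels one each to the first tiles along an
axis, making the partition exact for any image size. Problem sizes in the
tests and the acceptance script are the preset defaults above, chosen so a
full verification run completes in a few minutes on one CPU.
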