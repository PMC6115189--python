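# Methods

This note documents the models, conventions, parameters and numerical
choices behind `pcpdyn`, and what the synthetic validation does and does not
establish about real data.

## Coordinate and angle conventions

The mediolateral (ML) tissue axis is +x, the anteroposterior (AP) axis is
y with anterior at −y (image top); lengths in µm, times in s, frame
indices 0-based. Junction and cell-axis orientations are *axial*
quantities: they are folded into [0°, 90°] relative to the ML axis, and all
means/dispersions use the double-angle transform
(`R·e^{2iθ̄} = mean(e^{2iθ_k})`), under which orientations 0° and 90° are
antipodal (R = 0) and R = 1 means all orientations coincide mod 180°.
Junctions are classified V for angles in [0°, 45°] and T in (45°, 90°];
the boundary angle 45° is assigned to V, consistent with integer-binned
conventions ("0–45" vs "46–90") while covering the continuum.

## Data model

A `TissueFrame` is a planar cell complex: shared vertices, simple cell
polygons (validated with shapely), and junctions derived by chaining the
polygon edges shared by each cell pair into polylines. Junction identity is
the unordered cell-ID pair; a pair that loses and later regains contact
yields two distinct tracks, matching T2→T3 semantics in which the regained
contact is a new junction. A junction is "fully contracted" (T2) below
ε_T2 = 0.3 µm — no numeric criterion exists in the source literature, so a
sub-resolution threshold was chosen; it is configurable everywhere it is
used. Frame validity is checked via polygon simplicity, positive areas and
the Euler relation V − E + F = 2 of the complex.

Cell long-axis orientation and aspect ratio come from the closed-form
second central area moments of the polygon (uniform density); the aspect
ratio is √(λ_major/λ_minor) of the covariance eigenvalues, and isotropic
cells (equal eigenvalues within tolerance) carry an undefined (NaN) angle.
A dense point-sampling covariance oracle agrees to <0.5° and <1% aspect in
the tests.

## Synthetic tissue generator

The generator is *kinematic*: contraction schedules are prescribed, not
emergent from force balance, because its purpose is controlled ground truth
for the analysis stages. Design:

* **Geometry.** A vertex-jittered brick-wall tessellation (valence-3
  vertices, topologically equivalent to a hexagonal packing). Defaults:
  10 × 8 µm cells, 0.5 µm uniform vertex jitter (giving a realistic spread
  of junction angles around the two lattice orientations). A Voronoi/Lloyd
  sheet was considered and rejected: the T1/rosette machinery needs exact
  control of edge quartets, which the brick lattice gives for free.
* **Convergence flow.** An area-preserving anisotropic scaling about the
  tissue centroid with strain rate γ = 1.5·10⁻⁴ s⁻¹ (control), so ML
  junctions shrink ~9% and AP junctions grow over a 600 s movie — enough to
  produce the V-shrink/T-grow ensemble pattern without degenerating the
  mesh. Disrupted regimes set γ = 0.
* **T1 events.** n = round(rate · n_cells · duration_hr) junctions
  (override: `n_t1_events`) contract linearly to 0.5·ε_T2 over up to 10
  frames, then a topological swap replaces the junction by a new one of
  length 2·ε_T2 between the two lateral quartet cells, growing
  perpendicularly at the contraction speed (capped at 45% of the cell
  dimension). `shrink_bias` sets the V-class fraction of scheduled events
  (0.9 control, 0.5 disrupted). Events never share vertices or junction
  identities; sharing a quartet cell is allowed. The default control rate,
  0.25 cell⁻¹ hr⁻¹, gives a handful of events in a desk-scale movie.
* **Rosettes.** Two co-linear V-junctions of one cell contract onto their
  shared vertex, producing a ≥5-cell vertex held for 3 frames, then
  resolved by an AP-oriented junction between the two lateral cells.
* **Intensities.** Cytoplasm baseline 1.0 (intensities are in cytoplasm
  units, so planted enrichments read directly as ratios). PCP junction
  signal = enrichment_class + κ·(L_first − L(t)) + pulse mix + N(0, σ);
  i.e. dI/dt = κ·(−dL/dt) with κ = 0.2 µm⁻¹ by default, so a fully
  contracting 5 µm junction roughly doubles its baseline — of the order
  seen in live recordings — while slow flow-driven changes stay small.
  Myosin = myosin_enrichment_class + pulse mix. Membrane = 1 +
  0.15·(L₀/L − 1): the weak passive density term. Pulses are raised-cosine
  bumps (amplitude 0.35, duration 60 s, Poisson rate 1 min⁻¹) and are
  mean-centred so the planted enrichment baselines stay unbiased.
* **Pulse coupling.** Each junction owns three i.i.d. pulse trains S, U, W;
  the PCP channel adds √ρ·S + √(1−ρ)·U and myosin √ρ·S(t − lag·dt) +
  √(1−ρ)·W. Because the trains are i.i.d., the delta-series correlation at
  the planted lag is exactly ρ in expectation; measurement noise and the
  κ-term attenuate the *observed* correlation on full presets, which is the
  realistic situation.
* **FRAP.** Bleach traces follow
  F(t) = floor + M(1−floor)(1−e^{−(t−t_b)/τ}) on a raw scale with optional
  photofading shared with the unbleached reference (default 2·10⁻⁴ s⁻¹)
  and relative noise 0.02; sampling 5 s over 300 s post-bleach, 5 pre-bleach
  frames. Cohorts plant a negative ΔL–nonmobile relation
  (nonmobile = (1−M₀) − 0.22·ΔL + N(0, 0.04), clipped to [0.05, 0.9]).
* **Reorientation epochs.** Cell long-axis reorientation is driven by
  intercalation in vivo; a single affine flow cannot both shrink ML
  junctions and reorient cell axes toward ML. The epoch generator therefore
  emits independent early (AP-elongated, axis ratio 1.35²) and late
  (ML-elongated for `control`, unchanged for disrupted regimes) snapshots
  of the same cell field.
* **Determinism.** All randomness derives from `SimConfig.seed` through
  fixed `SeedSequence` spawn keys per purpose (geometry / intensities /
  FRAP / epochs); identical configs give bit-identical meshes, traces and
  images.

### Regime presets

| preset | PCP V/T | myosin V/T | flow γ | shrink bias | T1 rate | rosettes | reorientation |
|---|---|---|---|---|---|---|---|
| control | 2.0 / 1.0 | 1.8 / 1.0 | 1.5e-4 | 0.9 | 0.25 | 2 | toward ML |
| xdd1_like | 1.4 / 1.4 | 1.8 / 1.75 | 0 | 0.5 | 0.08 | 0 | none |
| pk2dpdl_like | 1.1 / 1.0 | 1.05 / 1.0 | 0 | 0.5 | 0.08 | 0 | none |

The xdd1-like regime flattens PCP enrichment by elevating T-junction
myosin to V levels; the Prickle-deletion-like regime removes V enrichment.
Both erase the polarized junction-shrinking and reorientation phenotypes.

## Analysis choices

* **Polarity tables** measure each junction once, at its first observed
  frame (the still-image procedure). A movie-time-average variant
  (`at_frame=None`) exists but conflates baseline polarity with the
  shrinkage-coupled dynamic component: growing junctions drift below their
  class baseline, biasing the V/T ratio. Cytoplasm normalization uses the
  unweighted mean of the two adjacent cells' (time-averaged) cytoplasmic
  means; boundary junctions are excluded from population statistics. The
  same definition is applied to every channel and regime.
* **Outlier removal** is a single pass at |z| > 3 computed from the full
  sample; an SD-0 sample removes nothing. No iteration — observed outlier
  counts in this kind of data are rare, and iterating changes the null.
* **Mann-Whitney** uses the exact null when min(n, m) ≤ 8 *and* the pooled
  sample is tie-free (the exact distribution assumes continuity); otherwise
  the tie-corrected normal approximation (scipy).
* **ΔL vs angle** uses a 1800 s window from each track's start (shorter
  tracks contribute their span, flagged); per-track orientation is the
  axial mean of the angle series, and orientation drift (max − min) is
  reported alongside to support stability statements.
* **T-transition detection.** T1→T2 = a track ending mid-movie with final
  length < ε_T2 whose cells do not merge into a rosette-scale vertex
  (rosette-mediated exchanges are detected and counted separately — whether
  published transition counts include them is ambiguous, so both numbers
  are reported). T2→T3 = a subsequently appearing junction between the two
  lateral cells of the resolved junction's endpoint quartet (recorded one
  frame before the loss); unrelated adjacency gains are ignored. The rate
  denominator counts cells present in ≥50% of frames.
* **Contraction rate** = −60 × the least-squares slope of L(t) on the
  window from the last frame within 5% of the running length maximum to
  the final frame (≥3 points enforced).
* **Rosettes**: a vertex with ≥5 incident cells (`rosette_min_cells`,
  configurable — the standard criterion in the intercalation literature).
* **FRAP fits** fix F₀ to the first post-bleach value (freeing it is
  available via `fit_f0=True` but increases parameter covariance on short
  recoveries); τ is bounded to [10⁻³, 10⁵] s and flagged at a bound; M is
  clamped to [0, 1] with a warning. Group recovery curves are averaged on
  the common post-bleach time grid (intersection of spans, linear
  interpolation). ΔL is measured from the bleach frame to the last
  analyzed frame; shrinking means ΔL ≤ −0.5 µm, with the boundary exactly
  at −0.5.
* **Cross-correlation** operates on first differences (differencing removes
  the shared shrinkage trend that would inflate raw-trace correlations) and
  uses Pearson ρ per junction over the full overlap at each lag
  (default ±5 frames), then unweighted across-junction means with SEM.
  Spearman is used for the scatter analyses (ΔI vs ΔL, velocity vs mean
  intensity), matching nonparametric practice for those plots.
* Single-component recovery only; a two-component exponential is out of
  scope (and unidentifiable at the simulated sampling).

## What the synthetic validation shows — and what it does not

Passing tests establish that each estimator recovers the quantity it
targets from data that *satisfy its model*: polygonal geometry without
segmentation error, linear contraction schedules, exponential recoveries,
stationary pulse statistics, Gaussian noise. They do not establish
robustness to segmentation/tracking errors, bleaching beyond a shared
multiplicative fade, non-exponential recovery kinetics, spatially varying
background, or out-of-plane motion — all present in real recordings. The
generator also does not model the deep mesenchymal cell layer, cell
division, or mechanics (forces are never inferred).

## Problem sizes and tolerances used in validation

Test tissues are 16–144 cells over 2–31 frames at dt = 20 s — large enough
that class means average over ≳100 junctions while a full run of the suite
plus the acceptance script stays comfortably on one CPU. Tolerances:
planted V/T ratio and raster round trip within 5%; planted zero-lag ρ
within ±0.05 at the 22-junction × 80-frame design; FRAP median |M̂−M| <
0.05 and median relative τ error < 0.15 on the (M, τ) grid with noise 0.02;
T1 recall/precision exactly 1.0 on noiseless meshes (events are matched by
cell pair within ±1 frame); rosette axes within 5° with R > 0.9; analytic
identities (axial cases, swap symmetry, identity correlation, Fisher
formula) to 10⁻¹² or exactly.
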