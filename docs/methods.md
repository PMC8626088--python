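# Methods

This note documents the models, numerical choices and limitations behind
`connatlas`, in the order the pipeline runs.

## Coordinate and data conventions

All volumes share the axis order (slice, row, column) = (anterior→posterior,
dorsal→ventral, left→right).  Voxel indices are 0-based; voxel `i` along an
axis with spacing `s` and origin `o` occupies the half-open interval
`[o + i·s, o + (i+1)·s)` and its center is `o + (i+0.5)·s`, which makes
point-in-voxel tests unambiguous.  Files in other memory orders are permuted
at load.  Region hierarchies are tables with parent links; quantification
runs over the flagged *analysis set*, labels without a flagged ancestor pool
into a reserved "Others" id, and label 0 (non-annotated space) maps to a
reserved "NA" id.  The real Allen CCFv3 annotation can be read through the
NRRD interface but is never required; all tests run on generated toy
atlases.

## Synthetic data generator

The generator emulates the features of tracer-labeled whole-brain data that
the pipeline's correctness depends on, at desk scale:

- **Toy brain**: an ellipsoid filling ~90% of the volume, partitioned into
  contiguous regions by seeded Voronoi cells; the most central region is the
  injection region.
- **Axons (outputs)**: biased random walks from the injection-region
  centroid toward per-axon termination points.  A target region is drawn
  with probability proportional to the configured target fractions; the
  termination point is Gaussian-distributed around the target's centroid
  (σ = region RMS radius / 3), so tubes arborize across the region without
  saturating into one bundle and without blanketing the region's periphery.
  Step direction mixes the target direction with an isotropic jitter
  weighted by the tortuosity parameter (default 0.3).  Walks are rasterized
  as tubes (Euclidean distance-to-segment ≤ radius, default 2 voxels) at
  the signal amplitude, and each walk terminates exactly on its sampled
  target point so every axon provably enters its target region.  Ground
  truth output fractions are *recounted from the planted tube voxels*
  (injection region excluded, renormalized), so fibers of passage — which
  the quantification deliberately does not distinguish from terminals — are
  part of the truth, not an error source.
- **Somata (inputs)**: non-overlapping spheres (default radius 3 voxels)
  placed uniformly inside requested regions with minimum center separation
  2·radius, entirely inside the brain.
- **Background and noise**: a linear per-section gradient (default
  amplitude 20 gray units across the column axis) plus i.i.d. Gaussian
  noise (default σ = 10), clipped at zero.  The noise model is Gaussian
  rather than Poisson because the detection stage thresholds intensities;
  Gaussian noise exercises it with a single SNR knob.
- **Speckle noise blobs**: small spheres planted for validation tests, kept
  ≥ 25 µm from real signal *and* capped at 4 blobs per 10 µm cell so that
  clustered speckle can never reach the 5% foreground-density threshold and
  masquerade as a signal corridor.  Without the cap, blobs crowd into the
  few empty pockets and form pseudo-corridors, defeating the premise of
  "isolated" noise.
- **Injection mask**: a sphere (default radius 10 µm) around the
  injection-region centroid, standing in for the hand-segmented injection
  site of a real experiment.

Default study conditions: 100³ voxels at 1 µm isotropic, 8 regions,
200 axons, 6 somata per region, amplitude 300 over σ = 10 (SNR 30).  The
recovery benchmarks use a *selective* projection profile (four of the seven
non-injection regions at fractions 0.4/0.3/0.2/0.1), as in real tracing
data where most regions receive no projection; the resulting empty
territory is where isolated noise lives.  Every generator output is a pure
function of (config, seed).

What the generator does **not** emulate: optics (PSF, depth attenuation),
photobleaching, mosaic-stitching artifacts, realistic neuron morphologies,
or registration error.  Passing tests therefore demonstrate correctness of
the quantification machinery under idealized imaging, not robustness to
those effects.

## Signal detection

Per coronal section: `B₀` = section median (robust to sparse bright
signal); `B` = min(I, B₀) mean-filtered 10 times with a 9×9 uniform
template; subtraction `max(I − B, 0)`; smoothing with a 5×5 truncated,
renormalized Gaussian (σ = 1.0); binarization at
`max(4·B(p), clip(t_Yen, [t_min, t_max]))` with strict `>`.

Numerical notes:

- All convolutions reflect at borders (scipy `reflect`, i.e. edge-including
  symmetric padding).
- Yen's criterion is computed with *reversed* cumulative sums for the upper
  class; the naive `total − cumsum` form cancels catastrophically when the
  upper class is tiny and can pin the threshold at the top bin.
- Ties in the criterion break toward the lower gray level.  Histograms use
  native levels for integer data and 256 equal-width bins for float data.
- The clip range default is [95th percentile of the smoothed section, ∞).
  The percentile is taken on the smoothed, background-subtracted section
  because that is the image being thresholded.  For the synthetic study the
  clip floor is instead *predetermined* as amplitude/3 — the analog of a
  dataset-specific threshold range chosen from known tracer brightness;
  with the per-section percentile alone, the blur halo around thin tubes
  passes threshold and voxel-level F1 plateaus near 0.8.

## Soma detection

A deliberately simple stand-in for dedicated soma-localization tools:
26-connected components of the detected mask, size-filtered to
[0.2·V, 5·V] with V = (4/3)πr³ the nominal soma volume.  Components above
1.5·V (the geometric center of the band) are split by a watershed seeded at
local maxima of the Gaussian-smoothed intensity with peak spacing equal to
the nominal radius — smoothing is essential because the intensity inside a
soma is flat plus noise, and raw-intensity peaks would fragment it.
Accepted components contribute intensity-weighted centroids; centroids
closer than the configured separation merge, keeping the brighter one, in a
brightness-sorted order that makes the result independent of component
enumeration order.  No claim of equivalence to sphere-fitting localization
tools is made; an accept/reject override CSV stands in for manual curation.

## Path validation

- **Density grid**: fraction of foreground voxels per 10 µm cell; boundary
  cells use their true voxel counts.
- **Speed law**: `F = density + ε` with ε = 10⁻³.  The affine law keeps
  empty space traversable — a path through empty cells lowers confidence
  rather than being impossible — which matches the role of the confidence
  cutoff.
- **Eikonal solver**: multistencils fast marching on four orthogonal
  stencil frames (the axis frame and the three 45°-rotated frames covering
  the 18-neighborhood), second-order upwind differences where two finalized
  upwind neighbors exist, with a drop-slowest-direction fallback ladder
  when the quadratic loses causality.  Arrival times are in cell units on
  an isotropic grid.  Two safeguards:
  - *Source initialization*: fast marching loses accuracy at the
    rarefaction fan around a point source; cells within `source_radius`
    (default 4 cells) of a seed are initialized by straight-ray integration
    with trapezoidal speed averaging (exact under uniform speed).  On the
    41³ uniform-speed benchmark this brings the maximum relative error at
    ≥ 5 cells from ~11% to 2.5%.  `validate_signal` disables it
    (`source_radius = 0`): its seeds are extended injection regions over a
    heterogeneous speed field, where straight-ray times would be wrong.
  - *Causality clamp*: a trial value is never allowed below the arrival
    time of the cell that triggered the update, which guarantees a
    non-decreasing finalization order.
- **Back-tracking**: gradient descent on the trilinearly interpolated
  arrival-time field, central differences, fixed step 0.5 cells.  A step is
  accepted only if it decreases T by at least 5% of `step · |∇T|`;
  otherwise the tracker falls back to the steepest-descent 26-neighbor
  (walked in sub-steps so consecutive path points stay within one step).
  The fallback is required in two regimes: plateaus, and narrow corridors
  between high-arrival-time walls, where the interpolated gradient makes
  the descent zigzag laterally with negligible forward progress.  On a
  marched field the discrete fallback provably terminates at a seed.
- **Confidence**: fraction of path points in cells with density > 0.05,
  with injection-site (seed) cells counted as foreground — the injection
  site is tracer-saturated by definition, and scoring its detected density
  would spuriously fail short paths that terminate across partially covered
  seed cells.  Cells that fail to reach a seed or reach it with confidence
  < 0.8 have their voxels cleared; cells overlapping the injection mask are
  left untouched (quantification excludes them separately).  An optional
  override mask stands in for manual noise inspection.

The foreground-density threshold (0.05), confidence cutoff (0.8) and speed
floor are declared, logged parameters.

A note on the 26-neighbor Dijkstra cross-check used in the tests: the graph
oracle carries the lattice's chamfer metrication error, up to +11.55% along
(1,1,2)-type directions, which does not decay with distance.  An accurate
continuum solver therefore cannot match it per-cell within that margin; the
oracle-equivalence test checks the mean relative deviation (< 10%) and the
one-sided admissibility bound `T ≤ T_dijkstra · 1.02` (graph paths are
feasible continuum paths), which is what the oracle can actually certify.

## Quantification

Output volume = validated foreground voxel count (1 voxel ≡ 1 µm³ in the
isotropic space), per analysis region, excluding voxels in the injection
mask from numerator and denominator; proportions sum to 1.  Inputs: soma
counts per region with injection-flagged somata dropped.  Output/input
ratios: zero input with nonzero output → +∞ (output-biased); both zero →
undefined; the boundary values 0.25 and 4.0 belong to "balanced", reading
the strict inequalities of the bias definitions literally.

## Statistics

- One-way ANOVA from the classic sums of squares; Tukey HSD adjusted
  p-values from the studentized range distribution with Tukey–Kramer
  standard errors for unbalanced designs.  Fully degenerate regions (no
  variance anywhere) report F = 0, p = 1.  scipy/statsmodels serve as
  independent cross-checks in the tests, not as the implementation.
- Hierarchical clustering: correlation distance (1 − Pearson r), average
  linkage, via scipy.
- Multiscale bootstrap: for each scale r in 0.5…1.4 (step 0.1), `n_boot`
  column resamples of size round(r·p) are reclustered; BP(node, r) is the
  fraction of replicate trees containing the node's item set, and the
  reported BP is the value at r = 1.  AU comes from the weighted probit
  regression `z(r) = v·√r + c/√r` with `z = Φ⁻¹(1 − BP)`, binomial-variance
  weights, fit over scales where BP is informative (not pinned at 0 or 1);
  `AU = 1 − Φ(v − c)`.  Nodes observed in essentially every replicate at
  every scale are saturated, and their AU is reported as their BP with a
  flag; AU is flagged experimental throughout.  Zero-variance rows arising
  in resamples are treated as uncorrelated (distance 1).  No multiple-
  testing correction is applied across regions beyond Tukey within each
  region; this mirrors common practice in connectivity mapping and is a
  documented limitation.

## Pipeline

All randomness descends from one root seed split deterministically per
(stage, group, sample) via `numpy.random.SeedSequence`, so identical
configs reproduce byte-identical artifacts.  The demo study (2 groups × 2
samples on a 60³ toy brain) gives each group a distinct projection-target
profile and a distinct, region-varying input profile — a flat soma count
per region would make every input profile constant and its correlation
undefined.  The manifest records the config, software version, per-artifact
SHA-256 checksums and wall-clock times, and suffices to re-execute a run.

## Problem sizes

The test suite and the reproduction script run on 100³-voxel brains
(8 regions, 200 axons, ~42 somata), 41³ and 15³ solver benchmarks, and
bootstrap designs of 8 samples × 60–200 features with 150–2000 replicates —
sizes chosen so the full suite completes in minutes on one CPU while every
stage still operates above the regime where its failure modes (overlapping
somata, corridor corner-cutting, saturated bootstrap nodes) actually occur.
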