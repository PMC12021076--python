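# Methods

## Scope and model of the data

`axonquant` implements the whole-mount quantification scheme used for
nerve-crush regeneration studies: CTB-labeled regenerating axons in
cleared optic nerves imaged as confocal stacks (2-µm z-spacing), EGFP
axons in sciatic whole mounts, and immunostained retinal whole mounts.
All computations live in the library (`src/axonquant`); the scripts in
`analysis/` and the CLI are thin drivers.

Coordinates are physical micrometres throughout: the crush plane is at
x = 0, regeneration runs toward +x, and the nerve's longitudinal axis is
+x in simulation. Image stacks are 0-based voxel grids `[z, y, x]` whose
metadata (pixel size, z-spacing, origin) maps voxels back to this frame,
so geometry and images share one coordinate system.

## The synthetic-data generator

The generator exists to give every metric a ground truth. It emulates:

- **Trajectories.** Each axon is a correlated random walk from a random
  entry point on the crush plane: fixed step (default 5 µm), per-step
  angular perturbation (`tortuosity_sd`, degrees), and a per-step
  relaxation of the heading back toward the axis (`heading_reversion`,
  default 0.05). The relaxation models guidance along the nerve; without
  it a correlated walk drifts laterally without bound
  (sd ∝ n^{3/2}), which is not how guided axons behave and makes fibers
  unresolvable in projections. The heading is also confined to an 80°
  forward cone, so that *only* an explicit reversal event can produce a
  terminal direction beyond 90° — this keeps the U-turn ground-truth label
  unambiguous by construction.
- **Extension lengths.** Truncated-exponential law: `length_scale` is the
  exponential scale, truncated at 95 % of the nerve length (the truncated
  mean is therefore slightly below `length_scale`). The law is a stand-in
  chosen for its qualitative match to the decay of fiber counts with
  distance; it is pluggable (`lengths=` replaces it with a fixed list) and
  is not a claim about the biology.
- **U-turns.** With probability `p_uturn` a smooth reversal arc is
  appended: the heading sweeps ~170° over six steps, then runs ≥ 45 µm
  backward. Any terminal-direction window up to ~40 µm therefore sees an
  angle well above 90°. U-turn axons are given ≥ 150 µm of extension so
  the reversal does not re-enter the crush plane.
- **Branches.** A Poisson process along arc length (`branch_rate` per mm)
  places branch points on the proximal 15–60 % of the arc; daughters
  diverge by 25–60° off the parent shaft (a definite angle, so daughters
  separate from the trunk tube) and never out-grow the main path, keeping
  "longest path terminal" well defined.
- **Tip morphology.** Each main terminal is a retraction bulb with
  probability `p_bulb`; its true tip/shaft width ratio is drawn uniformly
  from `bulb_ratio_range` (default 5–8) or `gc_ratio_range` (default 1–2).
  The config rejects ranges that straddle the classification threshold 4,
  so ground-truth labels are never ambiguous. The terminal 6 µm of the
  tube is widened to the true ratio at rasterization.
- **Rasterization.** Tubes are stamped as balls along each edge at
  half-voxel spacing; voxel intensity is `photon_scale ×` local thickness.
  The expected image is blurred by an isotropic Gaussian PSF
  (`psf_sigma`, µm), then Poisson shot noise and Gaussian read noise are
  applied over a constant background; `noise=False` yields the exact
  expected image, so a threshold just above background recovers the exact
  tube mask — the oracle case. The grid origin is snapped to whole voxels
  so that translating the scene by whole voxels reproduces the identical
  rasterization and the z = 0 midplane of a planar nerve sits on a slice
  centre. A voxel cap (2²⁷) guards against accidental huge grids.
- **Planar mode.** `planar=True` confines each axon to its entry plane
  (z constant), emulating a nerve whose fibers lie within a single 8-µm
  optical section. Interval-count oracle checks use this mode; 3D mode is
  the default everywhere else.
- **Chiasm.** `simulate_chiasm` draws each axon a fate from configured
  probabilities over {pre-chiasmic, ipsi tract, contra tract, contra
  nerve} and routes a jittered path to a terminal inside the matching
  landmark region. The landmark frame (OCTZ plane, midline, three
  axis-aligned region boxes, injured nerve at lateral offset −100 µm) is
  our construction; only the taxonomy and the landmarks themselves
  (midline, OCTZ) come from the field's convention. U-turns arise only
  among pre-chiasmic axons, consistent with "turned-back ⇒ pre-chiasmic".
- **Retina fields.** Cells are placed uniformly with a minimum separation
  of 2.2 cell radii (Poisson counts at `cell_density`, injured arm scaled
  by `survival_fraction`); Cre/p-S6 positivity is Bernoulli per cell;
  channels are rendered as uniform disks with Gaussian-distributed
  intensities over background plus Gaussian noise. A placement-attempt cap
  turns an overfull field into a configuration error.

**Randomness.** One root seed; per-axon trajectory and placement
substreams are derived by counter (`SeedSequence(seed, spawn_key)`), so
adding axons never perturbs earlier ones and identical config + seed give
bit-identical output.

## Tracing

`binarize` thresholds a stack (Otsu, fixed, or percentile; provenance
recorded; lower thresholds give superset masks). `trace_axons` reduces
each mask component touching the crush plane to a centerline tree by
iterative geodesic path extraction (TEASAR-style): a Dijkstra
shortest-path tree is grown over the component's 26-connected voxel graph
(physical edge lengths) from the most central near-plane voxel; the
geodesically farthest remaining voxel defines the next path; voxels
within twice the local tube radius of an accepted path are retired; side
paths shorter than the 10-µm prune length are never added, which makes
pruning idempotent. We deliberately avoid voxel-thinning skeletonizers
here: 3D thinning removes entire thin ribbon-like structures of certain
even widths — precisely the geometry of a thin axon confined near one
z-slice. The proximal tube cap behind the crush plane is trimmed so
lengths are measured from the crush site; node radii carry the local
half-width from the anisotropic Euclidean distance transform. Components
with more than two crush-contact clusters are flagged as suspected
merges; no disentanglement of crossing axons is attempted.

Defaults: spur-prune 10 µm, root tolerance to the crush plane 20 µm,
minimum tree length 50 µm; all configurable.

## Quantification choices where the procedure is under-specified

- **"No visible signal"** is formalized as: every optical section yields
  zero suprathreshold runs at a counting line; counts beyond that stop
  distance are reported as zero.
- **A "fiber" on a counting line** is a maximal suprathreshold run of
  ≥ 2 px; runs separated by ≥ 1 background pixel are distinct. This
  suppresses single-pixel noise while matching how a reader counts
  distinct fluorescent profiles. Consequently two fibers closer than
  ~1 px in a projection merge — interval counts presume resolvable
  fibers.
- **Sum over projections is literal**: an axon spanning two optical
  sections is counted once per section. The alternative (deduplicating
  across sections) is *not* applied; the choice is recorded in the
  profile metadata.
- **One U-turn per axon**: the rate divides flagged axons by axons
  analyzed and is bounded by 1. The terminal direction is the chord over
  the last 20 µm (`direction_window`) of the longest root-to-tip path.
- **Tip windows**: tip width is the largest inscribed disk of the
  projected mask within 10 µm (`tip_window`) of the terminal; the shaft
  diameter is the median local width over a 20-µm window starting 10 µm
  proximal to the tip window. Widths are measured on the Z-projection —
  the convention for whole-mount morphometry — which also sidesteps the
  strong z-anisotropy (2-µm slices vs ~2-µm shafts). Ratio exactly 4
  classifies as growth cone (strict inequality).
- **Chiasm fate precedence**: the named post-chiasmic regions are tested
  before the OCTZ rule, because the contralateral nerve lies anterior of
  the OCTZ plane; a terminal in no region falls into an explicit
  `unassigned` bucket.
- **Survival/marker ratios** are computed on summed counts over fields
  (robust to empty fields; per-field counts retained for dispersion), and
  cell positivity is "background-subtracted mean > 3 robust SDs of
  background" — a formalization of visual positivity calls.

## Cell detection

`detect_cells` smooths with a Gaussian of ⅓ cell radius and finds local
maxima above a scale-invariant threshold (a fraction of the bright-tail
contrast, floored at 5 robust noise SDs), with a minimum peak separation
of 1.4 cell radii. Doubling all intensities leaves detections unchanged;
empty fields return no cells. Per-cell mean intensity is taken over a
disk of the nominal cell radius after subtracting the background median.
Channel matching is greedy nearest-neighbour within 5–6 µm, each cell
matched at most once.

## Statistics

Pooled-variance two-tailed Student's t (df = nA+nB−2), one-sample t
against a reference (for control-normalized data), and one-way ANOVA with
Tukey's HSD via the studentized-range distribution, all through
scipy/statsmodels-grade routines; statsmodels is used as an independent
cross-check in the tests, never as the implementation under test's own
oracle path. Zero-variance one-sample input off the reference is flagged
with an infinite statistic and a machine-floor p-value rather than an
exception.

## Problem sizes used in validation

The test and acceptance runs use desk-scale sizes chosen to keep the
checks exhaustive where they are exact and statistically informative
where they are sampled: crossing-count oracle on 20 single-section nerves
of 12 axons; U-turn flag equality on 200 axons × 50 seeds per probability
level, with the image-pipeline leg at 15 axons × 3 seeds per level; tip
classification on 10 fixed ratios spanning both classes, once noise-free
and once at moderate noise; survival recovery over 50 seeds of 20 fields
per arm; type-I error over 10,000 null replicates per test. Pipeline
nerves are kept sparse (minimum entry separation ≳ 8 tube diameters)
because the tracer does not disentangle overlapping tubes.

## What passing tests do and do not show

The simulator produces clean, well-separated tubes with uniform labeling,
no photobleaching, no spectral bleed-through, no tiling seams, and
uniform background. Passing oracle and recovery tests demonstrates that
the *quantification scheme* is implemented correctly and is recoverable
through a realistic imaging model — not that the tracer would handle
densely fasciculated real nerves, nor that the detection thresholds are
optimal for any particular microscope. On real data the merged-component
flags, threshold provenance, and per-field dispersion outputs are the
intended guardrails.

## Known limitations

- The tracer reports merged overlapping axons as flagged single trees;
  densities where tubes routinely touch will undercount axons.
- Interval counts inherit the projection's resolution limit: fibers
  closer than the run-separation rule merge, and an axon ending within a
  cap radius of a counting line can add a spurious run. Both effects are
  visible in the acceptance agreement staying slightly below 100 %.
- The axon-length law and the chiasm landmark frame are modeling
  conveniences, not biological claims.
- 2D sciatic whole-mount inputs are handled as degenerate 3D (single
  plane); no dedicated 2D tracer is provided.
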