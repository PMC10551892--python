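# Methods

This note documents the models, conventions and numerical choices behind
`vesselvox`, the assumptions they rest on, and what validation on synthetic
phantoms does and does not demonstrate about real microscopy data.

## Image model and conventions

A volume is a 3D grid of integer gray levels (8- or 16-bit) with per-axis
voxel spacing in µm, possibly anisotropic (light-sheet stacks are commonly
1×1×3 µm in x×y×z). Arrays are stored `(z, y, x)`; all reported coordinates
are physical `(x, y, z)` µm, voxel-centre based and 0-based (the centre of
voxel *i* along an axis with spacing *s* is at `i·s`). Images are exchanged
as multi-page TIFF with a sidecar JSON carrying the spacing; tables as
RFC-4180 CSV; reports as JSON.

## Segmentation

The pipeline assumes three gray-level populations: non-tissue background
(mounting medium, darkest), unlabeled tissue whose gray values follow a
Gaussian law, and labeled vessels (brightest). Two thresholds are derived
from the histogram alone, with no operator judgement:

* **Tissue/non-tissue (OOS)** — default: the inflexion point between the
  two lowest-gray modes. Operationally: the histogram is smoothed with a
  fixed Gaussian kernel of 2 bins; scanning upward from the inter-mode
  valley (midpoint of a flat valley), the first sign change of the second
  derivative is the threshold, refined by linear interpolation. For
  well-separated modes this lands at the foot of the tissue mode; for
  overlapping populations it converges to the curvature change where the
  tissue population emerges from the non-tissue tail. The alternative
  `oos_mode="ci"` places the threshold at `mean − z·SD` of the fitted
  tissue Gaussian, which retains a known 1 − α/2 of tissue voxels and is
  the better choice when the OOS volume is used as a normalization
  denominator (the inflexion cut can exclude an unquantified tissue
  fraction). `oos_mode="none"` treats the whole volume as tissue, for
  interior crops with no mounting-medium region.
* **Vessel (OOI)** — the histogram restricted to the OOS mask is fitted
  with a Gaussian `A·exp(−(g−mean)²/2SD²)` by least squares, and the
  threshold set at `mean + z_{α/2}·SD` (z = 1.96 at α = 0.05). The fit
  window is chosen automatically: from the OOS threshold up to four
  estimated sigmas above the tissue mode (located as the lowest-gray
  prominent peak, since the vessel population can carry a taller spike),
  then iteratively tightened to just below the first gray level where
  observed counts exceed the fitted curve by more than 3× the residual SD
  (the onset of the vessel tail), twice. A manual window override exists.

Real-valued thresholds are compared to integer gray values with `≥`
semantics, without rounding. Because the threshold deliberately retains
α/2 of the background as salt noise, the OOI mask is post-processed:
26-connected components smaller than 27 voxels (one 3×3×3 neighbourhood)
are removed, and a 3³ majority (median) filter strips the single-voxel
pimples and pits that gray noise puts on the partial-volume edge — left in
place, thinning turns each pimple into a spurious skeleton branch. Both
steps are configurable and on by default.

**Partial-volume model.** A cylinder of length L and radius r at voxel
pitch d occupies `Nv(V) = Lπr²/d³` voxels, of which `Nv(S) = L·2πr/d²`
surface voxels carry intermediate gray values; their proportion is
`Nv(S)/Nv(V) = 2d/r`. (One printed form of this ratio circulates as
`r/2d`; the algebra of the two counts above gives `2d/r`, which is what
the package uses and tests.) The consequence is a structural density bias:
a threshold placed to exclude background cuts the edge voxels at an
occupancy fraction well below ½ when contrast is high, so the voxel-count
density of thin tubes (r ≲ 3d) overestimates the true lumen fraction by
tens of percent relative. The `threshold_sensitivity` operation quantifies
exactly this: it re-runs the downstream pipeline at t ± δ gray levels and
reports the signed percent change of segment count, node count, volume
density and total length.

## Skeletonization and distance mapping

Thinning is iterative, topology-preserving 3D erosion (26-connected
foreground, 6-connected background) on the voxel grid as stored;
anisotropy is handled downstream by measuring lengths and radii in
physical units. An optional pre-resampling to isotropic voxels
(nearest-neighbour, finest spacing) is provided because thinning on
strongly anisotropic grids can bias centrelines toward the coarse axis.
The specific boundary-point deletion test is not part of the contract —
the property suite (component count and cycle rank invariance on a fixture
library, centredness within one voxel diagonal on straight tubes,
idempotence) is.

The Euclidean distance map is exact and anisotropic (per-axis spacing),
with the volume border treated as background, giving conservative radii at
the image edge. The raw map holds the distance to the nearest background
voxel *centre*; when mapped onto the skeleton, half the finest spacing is
subtracted (floored at half a voxel) so the radius measures distance to
the estimated vessel *surface* — a one-voxel tube then reports r = d/2,
and a 5 µm cylinder at 1 µm voxels reports 5 ± 0.6 µm.

## Graph extraction

Skeleton voxels are classified by 26-neighbour count: 1 endpoint, 2 slab,
≥ 3 junction. Adjacent junction voxels are merged into one node at the
clump centroid (unmerged clumps inflate node counts). Segments are traced
slab-to-slab between nodes; segment `real_length` is the physical polyline
length through voxel centres including the links to the node centroids,
`euclidean_length` the chord between extremities. Voxel-centre polylines
overestimate smooth curve length by a few percent (staircase bias); no
path smoothing is applied and the bias is visible in the phantom recovery
(~5–7% median length error). Isolated cycles become loop segments with
coincident extremities, excluded from straightness/tortuosity statistics
(the chord is zero) and counted separately.

Two artifact-suppression rules, both derived from the local radius rather
than fixed lengths:

* **Junction-ball consolidation.** Where tubes of radius r meet, their
  union forms a ball of radius ≈ √2·r inside which the medial axis is not
  meaningful; thinning fragments it into a web of close nodes.
  Junction–junction segments shorter than `√2·(r_a + r_b)` (node radii =
  the largest mapped radius in each clump) are contracted, merging the two
  nodes at their voxel-weighted centroid.
* **Radius-aware spur pruning.** Endpoint twigs shorter than
  `2√2·r_node` of the junction they hang from are thinning spurs (they
  run from inside the furcation ball to the tube wall) and are removed;
  junctions reduced to degree 2 dissolve into their through-going segment,
  with lengths recomputed from the stored paths. The base prune length
  (outside the radius-aware pipeline default) is one fine-voxel diagonal.
  Genuine dead-end branches shorter than about 1.5 vessel diameters are
  lost to this rule; both pruned and raw graphs are available
  (`prune_graph` is a pure function).

On the capillary phantom (below) these two rules take the traced graph
from ~2.7× the true segment count to within 1% of it.

## Network-level descriptors

Volume density is the pure voxel-count ratio 100·|OOI|/|OOS| (spacing
cancels); segment/junction counts and total length are normalized per mm³
of OOS. The furcation spectrum N(i) counts junction nodes by degree
(bifurcation i = 3, trifurcation i = 4); endpoints are excluded from N(i)
and reported separately, since published node counts are ambiguous on this
point. For a closed meshwork the handshake identity `S = ½ Σ N(i)·i` is
exact and is used as an internal consistency check (reported only when the
endpoint fraction is negligible).

Box-counting fractal dimension: occupied-box counts N(ε) over a ladder of
box edges ε = 2, 4, 8, … voxels up to a quarter of the shortest axis, grid
anchored at the origin; fd = −slope of the least-squares line of log N
against log ε, with the r² of that fit reported and a warning below 0.98.
Computed on the skeleton by default, optionally on the mask — the two
differ materially: at desk scale (a 96 µm block, ladder 2–16 voxels) a
capillary skeleton measures fd ≈ 1.6 (line-like at those scales) while the
filled mask measures ≈ 2.5, in the 2.3–2.6 band reported for organ-scale
capillary networks. Literature comparisons should match the variant and
the scale window.

## Segment-level distributions

Descriptor samples (length, diameter, tortuosity) are binned with uniform,
left-closed bins (Freedman–Diaconis width by default) and the *counts* are
fitted by non-linear least squares — mirroring how such plots are usually
drawn — so the amplitude absorbs n and bin width and the shape parameters
are scale-invariant. Models: first-order exponential decay
`A·exp(−(x−x₀)/τ) + y₀` anchored at the first bin x₀ (decorrelating A and
τ) with A, τ > 0 and y₀ ≥ 0 (the offset is a flag; whether published decay
fits include one is usually unstated); Gaussian `A·exp(−(x−µ)²/2σ²)` with
the mode constrained to the observed support — without that constraint the
fit can push µ far below the data and degenerate into a monotone tail
indistinguishable from an exponential; and an optional power law `A·x^−k`
(self-similar geometry does not imply power-law descriptor distributions,
so it is not a default candidate). Candidates are ranked by AIC computed
from the residual sum of squares, r² as tiebreak, exponential before
Gaussian on exact ties. Initialization is moments-based and deterministic.

## Phantom generator

The generator is the ground truth side of every end-to-end claim. Default
parameters emulate a capillary bed as imaged in a cleared organ:

| parameter | default | basis |
|---|---|---|
| diameter | Gaussian, mean 5 µm (radius 2.5 ± 0.25) | reported capillary diameters ≈ 4.8–5.1 µm |
| segment length | mean 12 µm | reported capillary lengths ≈ 12–13 µm |
| voxel spacing | 1 µm isotropic (anisotropic supported) | fine light-sheet sampling |
| tissue gray | N(60, 8), 8-bit | mid-gray Gaussian background |
| non-tissue gray | N(10, 3) | dark mounting-medium slab (width configurable) |
| vessel gray | 220, noiseless interior | idealized saturated labeling |
| supersampling | 3³ subsamples/voxel | partial-volume rendering |

Meshwork topology is a jittered cubic lattice (pitch = mean length, ±15%
node jitter) with random edge deletions that preserve connectivity and
minimum degree 3 — the ground-truth graph is *closed* (no endpoints) and
satisfies the handshake identity exactly; lattice edge lengths concentrate
near the pitch rather than following the exponential law, which is sampled
literally only for tree topology (rooted, bifurcating, exponential branch
lengths). Tortuosity is produced by bowing each chord with a half-sine of
the given amplitude (amplitude 0 ⇒ tortuosity exactly 1). Radii are
Gaussian truncated to > 0. Tubes are rendered as capsules (hemispherical
ends); voxel occupancy is the fraction of supersamples inside the capsule
union, so overlapping tubes are counted once. One seed drives two
independent streams (geometry, noise), so a geometry can be re-rendered
under a different noise realization.

Two ground-truth volume notions coexist: the analytic `Σ L·π·r²` (stored
in `GroundTruth`; overcounts junction-shared volume — ~6 points of density
at capillary pitch) and the occupancy-union volume (computable from
`occupancy_volume`; the true lumen volume). Recovery comparisons state
which is used.

**What the phantoms do not emulate:** light-sheet point-spread functions,
stripe artifacts, depth attenuation, labeling heterogeneity (vessel
interiors are noiseless), Murray-law radius tapering, and hierarchical
tree ordering. Passing the phantom suite therefore demonstrates the
correctness of the *computational* chain under the stated image model, not
robustness to every optical artifact of real acquisitions.

## Validation protocol and problem sizes

The validation suite runs at desk scale, chosen so the full suite
completes in minutes on one CPU:

* capillary recovery: 20 seeds of the default 96³ µm meshwork (≈ 990
  segments each). Median matched segment-length error ≈ 6–7% (staircase
  bias dominated), median diameter error ≈ 0.6 µm, segment and junction
  counts within 1%.
* density recovery: 20 seeds of a sparse thick-vessel meshwork (radius
  5 ± 0.5 µm, pitch 48 µm, 128³ µm, ≈ 10% lumen fraction) with CI-based
  OOS — the regime where the partial-volume proportion 2d/r = 0.4 keeps
  the voxel-count density meaningful; median error ≈ 0.8–1.5 points
  depending on the ground-truth convention. At capillary scale
  (2d/r = 0.8) the same pipeline overestimates density by ~10 points of
  ~25 — an inherent property of confidence-interval thresholding of thin
  bright tubes, reported as such, not corrected away.
* calibration fixtures: 10⁶-voxel Gaussian noise for the 97.5% exclusion,
  256-voxel line/plane for box counting, ball/torus/theta/two-tubes for
  topology preservation, a 100 µm straight cylinder for straightness.

## Known limitations

* Path-length staircase bias (~5%) is uncorrected; subvoxel centreline
  smoothing is out of scope.
* Degree-2 nodes cannot be represented except transiently; a junction that
  genuinely has two branches (e.g. a pruned side branch) dissolves into
  its through segment.
* The inflexion-point OOS threshold is not guaranteed to preserve a known
  tissue fraction; use `oos_mode="ci"` when densities matter.
* Volumes are processed in memory as a whole; the practical ceiling is
  roughly 512³ voxels.
* The radius-aware pruning and junction-ball consolidation assume tubes at
  least ~2 voxels in radius; at the resolvability limit (r ≈ d) they have
  nothing to correct but also little signal to work with.
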