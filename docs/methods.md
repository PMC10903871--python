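# Methods

## Model

The segmentation target is a field of branched cells imaged in two
fluorescence channels: a nuclear stain and a cytoplasmic/membrane cell
marker. The method assumes (i) each cell is one connected component of
the cell-marker foreground, (ii) each cell contains exactly one
nucleus, and (iii) the marker intensity within a cell peaks towards the
soma interior, so that a cell carries one dominant intensity mode while
its processes contribute only shallow secondary bumps.

Segmentation proceeds in four stages.

**Foreground.** A single global Otsu threshold is computed over the
whole 3D cell-marker volume (256-bin histogram over the observed
min–max range; never per-slice, so the threshold does not drift along
z). The foreground rule is `intensity ≥ threshold`. The nuclei×cells
channel product is computed only to flag which clusters contain
nuclear-bright voxels in the run report; it plays no role in the
density, since it is nonzero only inside nuclei and cannot carry
process morphology.

**Persistence-based clustering.** Foreground voxels form a graph with
grid adjacency (26-connectivity by default; 6 and 18 available).
Density is the raw marker intensity — no rescaling, so δ is expressed
in the image's own intensity units. Voxels are processed in strictly
decreasing density (ties broken lexicographically by (z, y, x)); a
voxel with no previously processed neighbor founds a fine cluster,
otherwise it joins the fine cluster of its highest-density processed
neighbor. When clusters meet at a voxel `v`, any cluster whose peak is
within δ of `f(v)` is absorbed into the highest-peak cluster present at
`v`; clusters whose prominence clears δ persist side by side. When three
or more clusters meet at one voxel the pairwise rule is ambiguous, so
the canonical order above (absorb all sub-δ peaks into the highest peak
at the meeting voxel) is fixed and used identically in the production
union-find implementation and the explicit-set reference oracle.
Equal-height peaks are ordered by lexicographic peak coordinate, so the
whole labeling is a deterministic function of the input.

The persistence diagram is computed from the *ungated* filtration (one
birth/death pair per fine cluster; the surviving peak of each connected
component dies at the component's minimum density and is flagged
`is_global`), so recorded lifespans never depend on δ. δ itself is a
required user parameter: the data give no universal scale, and the
sensible choice sits between the prominence of process bumps and that
of somata. For the synthetic scenes below (plateau 100, ramp gain
20 /μm, soma radii 3–5 μm), process bumps have prominence ≲ 20 and
somata ≳ 60, so examples and tests use δ = 30.

Noise handling: coarse clusters smaller than `min_cluster_voxels`
(default 1, i.e. disabled) are flagged noise and can be dropped when the
hierarchy is cut to a label volume. An isolated component whose every
peak is sub-δ still yields one cluster — something was imaged there —
subject only to the size floor.

Voxel spacing never changes adjacency (edges are grid steps); it enters
only physical-size reporting and the geodesic split below.

**Nuclear anchoring.** Nuclear instance labels come either from an
external segmenter via TIFF ingestion (the first-class path for real
data) or from a deliberately simple fallback (global threshold +
26-connected components + size filter) adequate for well-separated
nuclei. Refinement applies, in this order: R1 — coarse clusters
overlapping no nucleus (fewer than `min_overlap_voxels` shared voxels,
default 1) are removed; R3 — clusters overlapping `k ≥ 2` nuclei are
split; R2 — everything overlapping the same single nucleus is merged
into one cell. Running R3 before R2 means a cluster spanning nuclei A
and B is first divided, after which its A-piece can merge with any other
cluster of A; the final cell ↔ nucleus map is a bijection on the nuclei
that touch surviving foreground, and a second application of the rules
is the identity (idempotence, asserted in tests).

The split heuristic is multi-source shortest-path propagation on the
cluster's voxel subgraph: each nucleus's overlap voxels seed a region,
edge lengths are Euclidean steps scaled by the physical spacing (so
anisotropic z does not distort the boundary), every voxel joins the
nearest seed set, and exact distance ties go to the smaller nucleus id.
Pieces are provably connected and partition the cluster. This is this
package's own construction, validated against the one-cell-per-nucleus
contract and synthetic ground truth, not a reconstruction of any
particular published heuristic.

**Editing.** Proofreading operates at fine-cluster granularity only:
`add` assigns a basin to a cell (required adjacent unless forced),
`remove` detaches it, removing the last basin deletes the cell. Every
operation is appended to a log; the session invariant — current labels
equal the base segmentation with the log replayed — is what makes
"refine a previous segmentation" safe, and is asserted over random edit
scripts. Sessions serialize as a JSON manifest (schema version 1) plus
base/fine label TIFFs. Edits can never create voxels outside the
original foreground.

## Evaluation

Predicted and true instances are paired greedily by descending shared
voxel count (ties by gt id then pred id; zero overlap never matches) —
a declared procedure of this package, since matching conventions vary.
Per matched pair: `F1 = 2TP/(2TP+FP+FN)`, `Jaccard = TP/(TP+FP+FN)`,
`FP% = 100·FP/|gt|`, `FN% = 100·FN/|gt|`. The ground-truth denominator
is what allows FP% above 100 for oversized predictions. The identity
`F1 = 2J/(1+J)` holds exactly and is property-tested. Summaries report
mean ± SD with each segmented cell as one data point. Error maps code
voxels 1/2/3 = TP/FP/FN.

## Synthetic scenes

The generator emulates the intended imaging situation: spherical somata
(radius 3–5 μm) with 3–6 random-walk tube processes (10–25 μm long,
0.8 μm radius, tortuosity 0.3), nuclei as concentric 2 μm spheres
strictly inside the somata, on a 64×128×128 grid at 1.0×0.5×0.5 μm
spacing. Intensity inside a cell is a plateau (100) plus a ramp
proportional to each voxel's depth from the cell surface (20 per μm,
computed per cell), guaranteeing one dominant soma peak and shallow
process bumps — the persistence structure the method assumes. Scenes are
blurred with a Gaussian PSF (σ = 0.5 μm) and corrupted with additive
Gaussian noise (sd 5 = 5 % of the plateau; Poisson optional). A
requested fraction of cells is generated as physically touching pairs:
somata share at least one 26-adjacent voxel pair but no voxel, and all
other cell–cell contacts are prevented by truncating processes before
they touch a foreign cell. Everything derives from one seeded generator,
so scenes are bit-reproducible.

What the generator does **not** emulate: realistic PSF anisotropy
beyond a scalar σ, depth-dependent attenuation, background gradients,
touching *nuclei*, autofluorescent debris, or light-sheet striping.
Passing tests therefore demonstrate the algorithmic contracts — oracle
equivalence, bijection, recovery under modest noise — not performance
on real tissue, where δ and the nuclear segmenter matter far more.

On noise-free, blur-free scenes with separated cells the pipeline is
exactly recoverable (per-cell Jaccard 1), because each connected
component is one cluster equal to one true cell. For touching pairs the
recovered *count* is still exact, but the basin or geodesic boundary at
the interface need not coincide with the geometric ground-truth
boundary voxel-for-voxel, so Jaccard is slightly below 1 there unless
the split seeds (nuclei) are symmetric.

## Numerical choices and problem sizes

Ties everywhere are broken lexicographically by (z, y, x) or by smaller
id, making every stage deterministic. Geodesic distances compare exact
float sums of identical step lengths, so symmetric ties resolve to the
smaller nucleus id reproducibly. Label outputs are uint16, widened to
uint32 beyond 65535 instances. Degenerate inputs fail loudly: constant
volumes (no Otsu threshold), empty masks, empty ground-truth cells,
disconnected clusters handed to the splitter.

The validation suite runs the clustering core against an independent
explicit-set oracle on hundreds of random grids of ≤ 200 foreground
voxels (the oracle is quadratic), and the end-to-end contract on
64×128×128 scenes with 2–4 cells — sizes chosen so the whole suite and
the acceptance script each complete in minutes on one CPU while still
covering every rule path (touching pairs, splits, merges, removals).

## Limitations

- δ has no auto-selection; users must pick it from the persistence
  diagram (the CSV export exists for exactly this).
- The core loop is pure Python over a numpy scaffold; hundreds of
  thousands of foreground voxels are seconds of work, but whole-brain
  light-sheet volumes need tiling upstream of this package.
- The fallback nuclear segmenter cannot separate touching nuclei; real
  data should bring external nuclear masks.
- Edits move whole basins; voxel-level painting is deliberately out of
  scope.
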