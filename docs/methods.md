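# Methods

This note documents the models, numerical choices and limitations of
the detection pipeline and of the synthetic phantom used to test it.

## Detection pipeline

### Iterative mean threshold

The density threshold is the fixed point of the two-cluster mean
recurrence: `IT ← mean(I)`, then repeatedly `T ← (mean{I ≤ IT} +
mean{I > IT})/2` with `IT ← T`, stopping when `|IT − T| ≤ tolerance`
(default 0.9 intensity units on a 12-bit scale). Pixels equal to the
current threshold belong to the lower cluster, which makes the split a
total partition; if a cluster is empty its mean is replaced by the
threshold itself, keeping the recurrence defined on constant-heavy
images. The recurrence is monotone on any finite image, but a
`max_iter` cap (100) guards pathological inputs and is reported via a
`converged` flag. All arithmetic is floating point even on integer
images — cluster means are not integral. The recurrence runs on the
raw slice (it precedes enhancement in the processing order).

### Lung segmentation

Binarize at `I ≤ T`; remove components touching the image border
(exterior air and artifacts); fill closed holes (bright vessels and
nodules punch holes in the dark lung field); keep the two largest
components (the trachea is dark like the lungs but smaller than either
lung — with two or fewer components the mask passes through unchanged,
since near the carina the lungs genuinely merge); close the boundary
with a disk of radius 2; refill holes sealed by the closing.

The final refill is a deliberate addition to the classical five-step
sequence. A pleura-attached nodule is bright, so it binarizes to
background *connected to the chest wall* — an open notch that plain
hole filling cannot touch. The radius-2 closing seals the narrow mouth
of the notch, and the refill then restores the nodule's area to the
lung field. Without it, juxtapleural nodules are masked out before
detection can see them.

Connectivity: 8-connected foreground components, 4-connected
background for the hole fill — the standard dual pairing that avoids
topological paradoxes on the pixel grid.

### Anti-geometric diffusion

`∂I/∂t = I_gg`, the second directional derivative along the gradient,
discretized with central differences (including the mixed term),
reflective boundaries, and explicit Euler steps. Where the squared
gradient falls below `eps = 1e-8` the update is zero: the formula is
0/0 at flat points, and gating preserves exact identity on constant
and linear images. The explicit scheme empirically preserves the input
range for `dt ≤ 0.25` (checked over seeded random images; the enforced
stability bound).

Defaults: `dt = 0.2`, 3 steps, i.e. diffusion time 0.6 and an
across-edge smoothing scale of ≈1.1 px, matched to the shape-index
scale. Longer diffusion (e.g. 10 steps) measurably erodes thin vessels
and the tips of sub-8 mm nodules out of the threshold-band range,
defeating the enhancement's purpose; 3 steps suppress pixel noise and
improve the connectivity of the shape-index map while preserving
3 mm-scale structure. Diffusion is restricted to the lung field;
outside pixels are set to the median lung intensity (a neutral fill
that avoids an artificial cliff at the lung boundary).

### Multistep threshold candidates

`step = max(lung region intensity)/10`, measured on the same image the
bands are applied to and restricted to the lung mask so exterior fill
values cannot distort it. Thresholds `(T+2s, T+s, T, T−s, T−2s)`;
bands are half-open `(lo, hi]`, so the four raw bands exactly
partition `(Th5, Th1]` — a tested identity. Each band is opened with
a radius-2 disk; the opened masks are summed and binarized (the raw
bands are disjoint, so binarization only matters after the opening's
re-dilation). By default the bands are applied to the enhanced image;
`mask_source="original"` applies them to the lung-masked raw slice
instead (measurably worse on the phantom: raw noise survives the bands
and inflates false positives).

### Shape index

Principal curvatures default to the eigenvalues of the
Gaussian-derivative Hessian (scale `si_sigma`, default 2.5 px). This
is the graph-surface second-fundamental-form in the low-slope limit
and is scale-free in intensity: the shape index depends only on the
eigenvalue ratio. The full graph-surface operator (II/I fundamental
forms) is available as `metric="graph"`, but on calibrated 12-bit
amplitudes the first fundamental form is dominated by the huge slopes
of any structure's flanks, pushing all of them towards cylinder-like
SI ≈ 0.75 and destroying the cap/ridge separation the 0.76 threshold
relies on. Sign convention: a concave-up bowl has positive curvatures,
so bright blobs (intensity maxima) are caps with SI → 1.

The σ = 2.5 px default balances two failure modes: below ≈2 px the
derivative-kernel noise response exceeds the gentle deterministic
curvature on top of 20–30 mm nodules, randomizing their SI towards
0.5 and dragging component means under the threshold; much above 3 px
adjacent structures blur together. Images are mean-centred before
filtering and kernels are truncated at 8σ so constant and linear
surfaces have numerically zero curvature; pixels with both curvature
magnitudes below `1e-8` are flagged undefined and excluded from means.

Per candidate component (8-connected, at least 3 px and at least 2 mm
equivalent diameter — candidate components capture only a nodule's
bright core, so the gate sits below the task's 3 mm size floor), the
mean of defined SI values decides retention: mean > 0.76 keeps the
component; a mean of exactly 0.76 removes it. Raising the threshold
can only shrink the retained set (tested monotonicity).

## Synthetic phantom

One 256 × 256 slice at 0.6 mm pixels on a 12-bit-like scale: exterior
air 0, chest body 3000, lung fields 500, trachea 200, vessels 1900,
nodules 1700 (+ per-nodule contrast offset), additive Gaussian noise
σ = 40. The intensity ordering body > vessel ≥ nodule > lung is
enforced, and on defaults all four threshold bands are nonempty.

* **Nodules** are rendered as domes `I = lung + A·(1 − (r/R)²)^0.35`.
  The exponent is a fixed compromise: the pure sphere-chord projection
  (exponent 0.5) spreads a small nodule's intensity across several
  threshold bands, splitting its candidate region into annuli thinner
  than the opening footprint, while a plateau profile removes the cap
  curvature the SI filter needs on large nodules. Truth masks are the
  full geometric disks, rendered noise-free.
* **Vessels** are random-walk tubes with a cylinder-projection
  (chord) cross-section, width 6–8 px, tapering to 2 px at both ends —
  a bluntly truncated tube would end in an artificial cap-class stump
  that the SI filter rightly keeps. Tubes stay strictly interior to
  the lung so that, like real intraparenchymal vessels, they binarize
  to closed holes the flood fill restores.
* **Attachment classes.** `isolated` nodules are placed clear of
  vessels and the pleura; `juxtapleural` and `diaphragm` nodules
  overlap the lung boundary by ≈2 px (diaphragm restricted to the
  inferior sector); `juxtavascular` nodules sit at the end of a tube —
  a feeding vessel terminating at the nodule rim — because a brighter
  tube crossing the dome would either swallow or carve up the nodule
  under the max-composition rendering. Placement is rejection sampling
  with deterministic seeding; for the largest nodules the clearance
  constraints are progressively relaxed rather than failed.

Everything is deterministic given the spec seed; truth masks are
independent of the noise draw.

### What the phantom does and does not show

The phantom exercises the pipeline's failure modes (border-connected
artifacts, trachea, vessel false positives, pleural attachment, size
dependence) but is not a CT simulation: no beam hardening, no
reconstruction kernel texture, no 3-D partial-volume coupling between
slices, and nodule/vessel intensity profiles are idealized analytic
shapes. Passing the phantom study shows the chain is implemented
coherently and that its stated mechanisms work at realistic geometry,
contrast and noise — not that clinical sensitivity would match.

## Phantom study and expected behaviour

The acceptance study runs 60 pseudo-scans of 3 slices each (the scale
of the method's original evaluation), nodule diameters uniform over
3–30 mm, attachment mix 50/20/20/10 % isolated / juxtapleural /
juxtavascular / diaphragm, ~270 nodules in total. Under the default
configuration the frozen run yields scan-level sensitivity 0.861,
0.17 false positives per scan, pure-vessel false positives removed on
95.6 % of vessel-bearing slices, and per-bin sensitivities 0.52 /
1.00 / 1.00 over 3–10 / 10–20 / 20–30 mm.

The sub-6 mm floor is structural: a radius-2 disk opening erases any
band chunk that cannot contain its 13-px footprint, and a small
nodule's captured region — further split across bands by its intensity
profile — falls below that for diameters under ≈6 mm at 0.6 mm pixels.
The method's detection rate genuinely rises with nodule size; the
size-stratified report makes that trend explicit.

## Evaluation semantics

A truth nodule is detected if a retained component contains its
centroid or overlaps it with IoU ≥ 0.1 (both rules individually
selectable). The disjunction is the robust default: an attached vessel
can carve the centroid pixel out of an otherwise well-overlapping
component. A retained component that overlaps no truth nodule pixel
at all counts one false positive; partial overlaps below the hit rule
are neither credited nor penalized. Per-slice detections of one truth
nodule are merged by label before scan-level counting. With zero truth
nodules sensitivity is reported as undefined (`None`), never 0 or 1.

## Known limitations

* Per-slice 2-D processing only; a 3-D nodule spanning several slices
  is detected (or missed) slice by slice and merged only in evaluation.
* The mean-SI decision is fragile for components that mix a large
  vessel with a small attached nodule; sub-6 mm juxtavascular nodules
  are the weakest case.
* The 0.76 threshold and the five-threshold band construction assume
  bright-on-dark solid nodules; ground-glass opacities are out of
  scope.
* DICOM support covers rescale slope/intercept and pixel spacing only
  (no orientation handling); slices are assumed axial and isotropic
  in-plane.
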