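# Methods

## Scope and assumptions

The pipeline consumes a post-implantation CT volume and a brain mask
that are already co-registered on a shared voxel grid (and, if a
standard space is wanted, already normalized); registration,
segmentation, and normalization are upstream of this package and are not
re-implemented. All coordinates are world-space millimetres through the
NIfTI affine, voxel indices are 0-based, and no resampling is performed
on load — volumes on mismatching grids are rejected rather than silently
interpolated. The contact count K of every array is taken from the
implantation notes; no attempt is made to estimate it from the image.

## Localization model

Metal contacts appear in CT as compact blobs, brighter than any tissue
except dense bone. After masking out the skull (3×3×3 cubical
dilation/erosion of the brain mask, default 0 iterations, exposed
per-array) and thresholding at ≥ 1,800 HU (inclusive, so voxels exactly
at the threshold are kept), the surviving voxels of one array are
partitioned by K-means on their world coordinates. Clustering is
deliberately unweighted: intensity enters only afterwards, in the
per-cluster intensity-weighted centroid that defines each contact
coordinate. K-means uses k-means++ initialization with 10 restarts and a
fixed seed; restarts guard against the merged-contact failure mode at
low thresholds. Distances are in mm, not voxels, so anisotropic grids
would cluster correctly.

Interactive voxel selection is replaced by three programmatic
equivalents: explicit 26-connected component ids, predicates on
component centroids, and proximity to guide points (e.g. samples of the
planned trajectory). Component labeling is made deterministic by
numbering components in order of their minimal voxel index.

## Numbering

Depth arrays and strips are one-dimensional: contacts are ordered by
projection on the first principal axis of L, contact 1 at the deep end.
"Deepest" is resolved by a hint coordinate; when none is given it is
derived as the array endpoint with the larger distance-to-mask-boundary
(Euclidean distance transform of the brain mask). This matches the
anatomical convention that contact 1 is the tip.

Grids go through the hull/ideal-grid/permutation procedure described in
the README. Numerical choices that the procedure leaves open:

- Transition angles are the absolute turn between consecutive hull
  segment directions, in degrees. Ties among corner candidates are
  broken by distance from the hull centroid (corners are extremal).
- The hull traversal starts at the corner with lexicographically
  smallest 2D coordinates, and the PCA axis signs are canonicalized
  (largest-magnitude component positive), so the whole numbering is a
  pure function of the contact set — invariant to storage order. The
  leftover global flip/rotation is inherently unresolvable from the
  image and is left to the documented manual `flip_rotate` step.
- The ideal grid is oriented by comparing the two corner-edge lengths
  against (cols−1)·pitch and (rows−1)·pitch.
- The sphere fit seeds a linear algebraic fit and refines the center by
  Levenberg–Marquardt on the geometric residual with the radius profiled
  out. Exactly or nearly coplanar grids defeat the algebraic system
  (it is rank-deficient and returns a small bogus sphere), so the fit
  competes against a PCA plane on rms residual and falls back to
  orthogonal-to-plane projection whenever the plane fits at least as
  well, or the fitted radius exceeds 10× the grid extent.
- Greedy assignment sorts all real–ideal pairs by distance with ties
  broken by (real row, ideal index), making it deterministic.
- The permutation refinement runs the real–ideal objective first, then
  the real-grid neighbour-distance objective, each sweeping all
  lattice-adjacent index pairs and restarting after any strictly
  improving swap; strict decrease guarantees termination. The second
  pass can in principle revisit the first pass's optimum; both
  objectives are computed on demand and the order follows the procedure
  definition.

## Anatomical labeling

Probabilistic atlases are 4D NIfTI volumes (one map per region) with a
TSV name table, compatible with the FSL-distributed Harvard–Oxford
files. Sampling is nearest-voxel, not trilinear: labels are categorical
evidence and interpolating across region boundaries manufactures
probabilities no atlas voxel contains. Reported probabilities are the
raw sampled values, unrenormalized, ranked descending with lexicographic
tie-breaks; a contact outside the atlas bounding box is flagged rather
than erroring the whole table.

## Smoothed cortical envelope and brain-shift correction

Grids localized on a post-implantation CT sit below the pre-implantation
cortical surface because of perioperative fluid build-up. The envelope
(SCE) is built from the brain mask by morphological closing with an 8 mm
Euclidean ball (implemented by two distance transforms; 8 mm bridges
typical sulcal widths), marching-cubes iso-surfacing at 0.5, largest
connected component, and 20 iterations of Laplacian smoothing at factor
0.5. A triangular surface mesh is used; only surface nodes matter to the
constraint, so no volumetric mesh is needed. On a 1 mm grid the mesh
density comfortably exceeds the target of 1 node per 4 mm² (meshes below
it are subdivided), keeping the node-coincidence discretization error
around the voxel scale. Hemisphere splitting uses the x = 0 midline.

The projection energy (README) is constrained to mesh nodes. The
constraint as stated — each contact coincides with its own nearest node
— is circular, so it is operationalized by alternating minimization:
snap to nearest nodes, continuously minimize the energy plus a quadratic
attachment to the snapped nodes whose weight doubles each outer
iteration (L-BFGS-B with analytic gradients), and repeat until the node
assignment is stable. A final discrete coordinate-descent pass over each
contact's 16 nearest candidate nodes leaves the result exactly on nodes
and makes the reported energy trace provably non-increasing; on coarse
meshes it reproduces the exhaustive minimum over candidate node tuples.
Non-convergence returns the best iterate with a warning flag.

The displacement field applies the printed weight formulas with
σ_R defaulting to half the grid pitch (the regularization width is not
prescribed; half a pitch localizes the field to the nearest contacts
without creating per-contact steps) and 2σ_D = mean distance of the
projected grid contacts to the SCE centroid. The attenuation weight
w′ⱼₖ is pairwise in ‖Lⱼ−Lₖ‖ as printed, although the motivating idea —
contacts near the brain's geometric center shift less — suggests a
variant keyed to the depth contact's own distance from the envelope
centroid; that variant is available behind `attenuation="centroid"`
without guessing which was intended. Since w′ ≤ 1 and the field is a
convex combination of the Dₖ, ‖Fⱼ‖ ≤ max ‖Dₖ‖ always.

## Validation statistics

The gold standard is the per-contact mean of manual localizations across
raters; errors are Euclidean distances. Krippendorff's alpha uses the
interval metric with no missing data; 3D coordinates enter as scalar
units by treating each contact's x, y, z as separate units (the
coefficient is defined for scalar ratings; per-axis reporting is a
keyword away). If every rating is identical the expected disagreement is
zero and alpha is defined as 1. The paired permutation test flips the
signs of the paired differences (the paired-t permutation scheme; the
pooled-repartition reading of "random partition" would break pairing),
uses 100,000 permutations by default, and reports the two-sided p with
the observed permutation counted, so p ≥ 1/(n_perm+1). Identical
samples return p = 1; constant non-zero differences make t undefined and
raise.

## Synthetic phantoms

`make_phantom` emulates what the pipeline actually sees: a spherical
brain (default radius 80 mm, ~50 HU) inside a 1,500 HU skull shell, each
contact rendered as an isotropic truncated-Gaussian intensity kernel
(sd = radius/2, cut at 2.5 sd, peak 3,200 HU), grids laid on a spherical
cap by the sphere's exponential map (geodesic pitch exact along the two
central axes, default 10 mm), depth arrays collinear (5, 6, or 10 mm
pitch), optional marker blob between grid contacts 1 and 2, and i.i.d.
Gaussian voxel noise. Artifact radii are 3.0 mm (depth) and 2.4 mm
(grid). These were derived analytically from the operating envelope the
phantoms must reproduce on a 1 mm grid, not from physical contact sizes
(CT blooming makes artifacts wider than the metal): every contact keeps
at least one voxel above 2,200 HU at the worst-case half-voxel alignment
(peak·exp(−0.866²/2sd²) ≥ 2,200), 5 mm-pitch neighbours remain separate
components down to 1,200 HU but merge by ~800 HU (midpoint value
3,200·exp(−6.25/4.5) ≈ 800), and the skull shell sits 12 mm off the
brain so cubical mask dilation (which reaches √3× farther diagonally)
cannot reach it.

What the generator does not emulate — and what passing tests therefore
do not show — includes beam hardening and streak artifacts between
nearby metal objects, anisotropic/correlated CT noise, partial-volume
anisotropy from non-isotropic acquisitions, contacts left outside the
brain, cables overlapping grids (approximated only by the marker blob),
and real cortical geometry (the brain is a sphere; the mock sulcus is a
slot). Accuracy numbers on phantoms are therefore analogues of, not
substitutes for, validation on patient images.

`simulate_raters` adds isotropic Gaussian jitter per rater per contact,
emulating independent expert relocalizations.

## Problem sizes used in the validation analogues

The accuracy analogue runs 50 phantoms (alternating 8×8 and 4×5 grids on
an 80 mm cap plus 8–10 contact depth arrays, noise sd 100 HU, 200³
voxels at 1 mm); the robustness and reliability analogues run five
configurations (thresholds 1,200–2,200 HU, mask iterations −1..+1) on
one such phantom. Oracle checks use sizes where exhaustive enumeration
is exact: ≤ 12 voxels for 2-partitions, 2×3 grids for the 720-permutation
assignment optimum, n = 5 for the 2⁵ sign-flip enumeration, and a
subdivision-3 icosphere for the brute-force projection-energy search.

## Known limitations

- The greedy index assignment is not globally optimal in adversarial
  geometries; the permutation refinement recovers the optimum on all
  tested grids but carries no global guarantee.
- The alternating projection scheme is a heuristic for a non-convex
  constrained problem; the discrete polish guarantees a node-feasible
  local optimum only.
- The robustness of coordinates across the full 1,200–2,200 HU threshold
  range measures ~0.11 mm on these phantoms: each threshold selects a
  different shell of noisy voxels into the centroid. Narrower,
  operator-chosen threshold ranges give proportionally smaller spread.
- Strips of 1×N use the depth path; the grid procedure needs rows and
  cols ≥ 2 (the hull of a line is degenerate).
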