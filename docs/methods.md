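# Methods

## Problem and model

A lung 4D-CT study is a sequence of k co-registered 3-D CT volumes
("phases") sampled along the respiratory cycle.  Delineating the gross
tumor volume in every phase is required for motion-aware radiotherapy
planning, but contouring k volumes by hand is slow, and automatic
single-volume segmentation fails exactly where it matters: tumor edges
that are weak or missing in one phase (motion artifact, low contrast) and
tumors adhering to iso-intense structures such as the chest wall.

`contextcut4d` segments all k phases *simultaneously* from object and
background seeds drawn in a single phase.  Each voxel v of each phase i
carries a binary label f_v (1 = tumor, 0 = background), and the labeling
minimizes one global energy

    E_g(f) = sum_i { R_i,v(f_v) + B_i,(v,w)(f_v, f_w) + C_i,(v,v')(f_v, f_v') }

with three cost families:

* **Regional** R_i,v(f_v): negative log-likelihood of the voxel's
  intensity under object/background intensity histograms fitted from the
  seed voxels; R_v(0) = −ln Pr(I_v | B), R_v(1) = −ln Pr(I_v | O).  The
  tumor's intensity distribution is assumed stationary across the
  respiratory cycle, so the single seed-phase model supplies the regional
  term of every phase.  Seeds are hard constraints: an object seed has
  R_v(0) = ∞, a background seed R_v(1) = ∞.
* **Boundary** B_i,(v,w) for 6-neighbors v, w within one phase:
  λ₁ exp(−(I_v − I_w)² / 2σ₁²) / dist(v, w), the classic edge-preserving
  weight — expensive to cut where the image is flat, cheap across strong
  gradients.  dist is the physical spacing (mm) along the connecting axis.
* **Context** C_i,(v,v') for corresponding voxels of *adjacent phases*: a
  two-level Potts penalty on label disagreement, 2λ₂σ₂ when
  |I_{i,v} − I_{i+1,v'}| ≤ τ and λ₂σ₂ otherwise.  Disagreement between
  phases is doubly implausible where the two phases look alike; this is
  the term that lets a sharp phase rescue a weak-edge phase.

All pairwise terms are non-negative Potts penalties, hence submodular:
the exact global optimum over all phases at once is a minimum s-t cut of
a single graph with one node per (phase, voxel), t-links encoding the
regional terms, intra-phase n-links the boundary terms, and inter-phase
arcs the context terms.

## Intensity normalization

Intensities are clipped to a CT display window (default [−1000, 400] HU)
and mapped affinely to [0, 1] before any energy is computed.  σ₁, σ₂ and
τ are therefore dimensionless and independent of scanner calibration.
This choice is deliberate: a Gaussian boundary parameter of σ₁ = 0.5 is
only meaningful on a bounded intensity scale.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| λ₁ | boundary term scale | 1.0 | — |
| σ₁ | boundary Gaussian width | 0.5 | normalized intensity |
| λ₂ | context term scale | 1.0 | — |
| σ₂ | context Potts level | 0.1 | — |
| τ | context similarity threshold | 5/255 ≈ 0.0196 | normalized intensity |
| n_bins | histogram bins on [0, 1] | 64 | — |
| floor | histogram probability floor | 1e-6 | — |
| chain | phase adjacency | linear | — |

λ₁, λ₂, σ₁, σ₂ follow the values that worked best in the parameter study
of the originating clinical work.  τ is not stated there numerically; we
adopt the classic interactive graph-cut Potts default of 5 grey levels on
an 8-bit scale, rescaled to normalized intensities, and expose it in the
configuration.  The histogram floor (each bin probability ≥ 1e-6 after a
convex mix with the uniform distribution, then exact renormalization)
keeps all regional costs finite while perturbing populated bins by less
than one part in 10⁴.

Phase adjacency defaults to a linear chain (phase i ↔ i+1); a cyclic
closure (last ↔ first) is available since respiration is periodic, but
the linear chain is the default as the more conservative reading of the
global-graph construction.  Correspondence between phases is the identity
(z, y, x) index — no registration is performed anywhere, matching the
construction this package implements; this is a known approximation since
the tumor genuinely moves between phases (see Limitations).

## Solver

Minimum cuts are computed exactly by two interchangeable backends behind
one contract (the returned labeling minimizes the energy):

* graphs ≤ 512 nodes: the Boykov–Kolmogorov algorithm (networkx) on
  float capacities; the source side of the cut is the BK residual's
  source search tree.
* larger graphs: scipy's Dinic max-flow on integer capacities.  Per-edge
  capacities must stay below 2³¹, so float weights are scaled by
  ⌊(2³¹−1)/max-weight⌋ and rounded.  To keep that scale fine, seed nodes
  (whose forbidden-label t-link carries the hard weight) are first
  *contracted into the terminals*: their pair edges are rerouted to s or
  t, which realizes R = ∞ exactly, with no huge capacity in the graph.
  The residual quantization is ~10⁻⁸ per weight; the reported energy is
  always re-evaluated from the unscaled float weights of the returned
  labeling.

The hard weight itself is instance-derived: 1 + the sum of every finite
t-link, n-link and context weight, which no finite cut can prefer to
violate.  The t-link encoding is the standard zero-offset one
(to_source = R_v(0), to_sink = R_v(1)), so the cut value equals the
global energy exactly — verified in the tests by evaluating the energy
independently and by exhaustive enumeration on small graphs (an
`2^n`-labeling brute-force oracle, ties broken by the lexicographically
smallest labeling).

When several minimum cuts exist, any is acceptable; determinism comes
from fixed node ordering and deterministic solvers, so reruns are
bit-identical.

## Synthetic phantom

`phantom.generate_phantom` builds studies with exact ground truth: a
bright ellipsoidal tumor (intensity 0.65) inside darker lung parenchyma
(0.25), moving sinusoidally in z (amplitude 6 mm over the cycle,
(A/2)(1−cos 2πi/k), i.e. end-exhale at phase 0); a chest-wall slab on the
+x side; additive Gaussian noise (σ = 0.03); and optionally a *weak-edge*
phase in which the tumor boundary is Gaussian-blurred within an angular
sector of a shell around the boundary (the blurred edge of that phase
stays sharp in its neighbours).  Truth masks are the exact per-phase
ellipsoid voxel sets, fixed before noise and blur.  The default grid is
48×64×64 at 1 mm isotropic with k = 6 phases — large enough for a
realistic tumor-to-boundary ratio, small enough that a full 6-phase
global solve takes seconds on one CPU.

Two design choices deserve explanation:

* **Wall intensity 0.55, not 0.65.**  With a histogram regional model, a
  bulky structure whose intensity *equals* the tumor's is always labelled
  tumor: Pr(I|B) at that intensity can never exceed Pr(I|O) enough, and
  the regional gain scales with the structure's volume while the
  competing boundary cost scales with its surface.  A default phantom
  with an exactly iso-intense wall therefore cannot be segmented
  correctly by this energy — by construction, not by implementation
  accident.  The default wall sits at 0.55 (≈ 3 noise standard deviations
  below the tumor): still a low-contrast confusable neighbour, but
  separable once the background seeds cover it.  Exact iso-intensity
  remains configurable for studying the adhesion failure mode itself.
* **Annotation emulation.**  `seeds_from_truth` mimics generous 2-D brush
  strokes: object seeds sampled inside the eroded tumor, background seeds
  across the whole surround of the tumor on the slices it occupies —
  lung, gap and chest wall alike (defaults 300 / 2000 voxels).  Covering
  nearby confusable structures is what real annotators do and is
  essential: any intensity that occurs outside the tumor but has no mass
  in the background histogram is systematically mislabelled.

The weak-edge experiment (`phantom.weak_edge_params`) blurs one mid-cycle
phase over half the boundary circumference (radius 4.5 mm, ~¾ of the
smallest tumor semi-axis) and omits the wall.  The omission isolates the
failure mode under study: the blur ramp's intensities coincide with the
wall's histogram bins, so with a wall present the regional term dominates
the context arcs (≤ 2λ₂σ₂ per voxel pair) in exactly the region the
context term is supposed to arbitrate, and the two failure modes
confound each other.

What the phantom does *not* emulate: CT physics (beam hardening,
reconstruction and 4D sorting artifacts), deformable motion (the tumor
translates rigidly), textured parenchyma, vasculature, and multi-lesion
anatomy.  Passing phantom tests therefore demonstrates the correctness
and the qualitative behaviour of the energy and solver — not clinical
accuracy, which in the originating work required expert-contoured
patient data.

## Evaluation metrics

DSC = 2|A∩G| / (|A|+|G|) and the average symmetric surface distance

    ASSD = ( Σ_{a∈S_A} min_b d(a,b) + Σ_{b∈S_G} min_a d(a,b) ) / (N_A + N_G)

over border voxels (mask voxels with a 6-neighbor outside the mask;
grid-boundary voxels count as border), with voxel-center positions in mm.
Both are computed in 3-D per phase; the 4-D aggregate is the mean over
phases.  ASSD is standardized on mm.  Nearest distances use a k-d tree
and are verified against an all-pairs computation in the tests.

## Problem sizes used by the test suite

Solver-level checks run on randomly-weighted graphs of ≤ 12 nodes
(against exhaustive enumeration), seed-consistency and decomposition
checks on 20 phantoms of 20×24×24×3 and 12×16×16×3 voxels, and the
weak-edge and single-annotation experiments on the full default phantom
(48×64×64 × 6 phases, 20 and 1 replicates respectively).  These sizes
were chosen to keep the complete suite in the minutes range on a single
CPU while still exercising the large-graph solver path.

## Known limitations

* Identity correspondence between phases ignores tumor motion; context
  arcs near a fast-moving boundary couple anatomically different voxels.
  Deformable registration before coupling is out of scope.
* The histogram regional model cannot separate iso-intense adherent
  structures (see above); the method relies on the user's background
  seeds and the boundary/context terms there.
* With λ₂ large, inter-phase coupling can propagate an error from one
  phase into its neighbours; λ₂σ₂ = 0.1 keeps the coupling weaker than
  typical regional evidence.
* The whole grid is segmented; there is no ROI cropping, so runtime and
  memory scale with k·|grid| (≈ 1.2 M nodes, ~7 M arcs, a few seconds
  per solve at the default phantom size).
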