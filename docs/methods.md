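# Methods

This note records the scientific and numerical choices behind
`sriselect`: what each stage computes, where the design was genuinely
open and what was decided, and what the synthetic test surface does and
does not establish about real data.

## The invariant coordinate system (ICS)

The frame is built from C-alpha geometry only: origin at the centroid,
*z* toward the farthest C-alpha, *x* toward the in-plane projection of
the farthest C-alpha within a lamellar slab of half-width 2 Å around
the *xy*-plane, *y* = *z* × *x*. Decisions taken where the construction
is under-determined:

* **Tie-breaking.** Both argmax selections break exact ties by earliest
  file order. When the two leading distances differ by less than 1e-6 Å
  the frame is numerically unstable and a warning is logged; nothing is
  regularized, because any smoothing would trade determinism on clean
  inputs for opaque behaviour on pathological ones.
* **Empty slab.** If no atom lies within the 2 Å half-width, the
  half-width doubles (2 → 4 → 8 …) until the slab is populated, with a
  warning and the half-width recorded in the frame. Treating this as an
  error would reject thin, elongated clouds that are otherwise fine.
* **Handedness.** *y* = *z* × *x* fixes a right-handed frame. Some
  orientation convention is mandatory — octant indices and cross-
  structure RMSD are meaningless if mirror frames are allowed — and
  right-handed is the field default.

Rigid-motion invariance of ICS coordinates is exact up to floating
point (observed ≤ 1e-13 Å on 1600-point clouds) *provided* the two
extreme-point selections are unique.

## The SRI statistic

Component *k* is the **population** standard deviation (divide by *n*)
of surface-point distances from the origin in octant *k*; octants with
fewer than two surface points contribute exactly 0.0. Population rather
than sample SD keeps the degenerate-octant limit continuous (one point
→ 0 rather than undefined) and matches tables of published SRI values
in which exact 0.00 entries appear.

* **Octant convention.** index = 1 + [x<0] + 2·[y<0] + 4·[z<0], with
  boundary coordinates counting as non-negative.
* **Frame atoms excluded.** The two frame-defining residues lie exactly
  on octant boundary planes by construction; their azimuth in the frame
  is floating-point noise, so including them makes surface binning and
  octant assignment representation-dependent. They are excluded from
  surface detection and the dispersion statistics. For real structures
  this removes 2 of typically 100+ surface points; for the statistic's
  invariance it is essential.
* **Surface detection.** The published protocol defers the surface rule
  to earlier work that does not restate it, so two explicit methods are
  provided and recorded in every result: `angular_shell` (default;
  radially outermost C-alpha per bin of an 18 × 9 longitude/latitude
  grid) and `convex_hull` (hull vertices). Consequently *absolute*
  agreement with any externally published SRI table is not claimed —
  only the statistic's invariance, equivariance and recovery properties,
  and the model selections derived from published vectors, which enter
  as data.

**What the synthetic recovery shows.** Star-shaped clouds with planted
per-octant radial dispersions (200 points/octant, radial mean 20 Å,
dispersions ~1 Å) are recovered with mean absolute component error of
about 4–5% of the mean dispersion (the acceptance script prints the
measured value), using a 72 × 36 angular grid so every octant retains
at least 50 surface points. Real proteins are not star-shaped; pockets
and concavities make "surface" genuinely method-dependent, which is
exactly why the method choice is recorded rather than hidden.

The generator pins the invariant frame by appending two anchor
residues (one far on +*z*, one in-slab on +*x*, both strictly beyond
the 4σ-truncated radius distribution); without them the data-driven
frame would be arbitrarily rotated relative to the generation frame and
per-octant comparisons would be meaningless. A zero-dispersion cloud
still shows residual SRI of ~0.4% of the radial mean, because the
origin is the *estimated* centroid; this is inherent to the statistic,
not a defect.

## The ILMFD descriptor

* **Preprocessing.** Luminance conversion (BT.601 weights), then 1/3
  linear downsizing by 3 × 3 block averaging (deterministic and
  alias-free; dimensions floor-divided, edge remainders cropped).
* **Bands.** 10 equal-width intensity bands over [0, 255], band *k* =
  [25.5·(k−1), 25.5·k) with 255 in the last band. The precise band rule
  of the original imaging work is not public; equal-width bands are the
  simplest fixed-range reading, and the edges are stored in every
  descriptor so alternative rules remain expressible.
* **Box counting.** Box sides 2, 4, …, 2^m with m = floor(log2(min(H,
  W)/2)); grid anchored top-left, partial edge boxes counting when they
  contain a true pixel; dimension = least-squares slope of log N(s) vs
  log(1/s). For nested grids N(s) ≥ N(2s) ≥ N(s)/4, so the slope is
  intrinsically in [0, 2]. A base-3 mode exists because exact
  self-similar fixtures (the depth-5 Sierpinski carpet, dimension
  log 8/log 3 ≈ 1.8928) live on powers of 3. With edge boxes counted,
  a filled image of non-power-of-two size measures slightly below 2.0;
  only power-of-two sizes give exactly 2.0.
* **Segmentation.** Masks are supplied as images (nonzero = aggregate);
  an Otsu threshold helper replaces interactive manual segmentation.

## The predictor

Architecture: 10 inputs → one hidden layer (default width 20, sigmoid)
with Elman recurrence run for 3 internal settling steps from a zero
state → 8 sigmoid outputs; targets min-max normalized per component to
[0, 1] (constant components flagged degenerate, restored exactly on
denormalization). This is the smallest recurrent architecture
consistent with a multi-input/multi-output recurrent backpropagation
regressor; width, settling steps and all training hyperparameters are
serialized with the model.

Training is full-batch gradient descent with momentum 0.9
(learning rate 0.5, 3000 epochs by default), backpropagating through
the settling steps, seeded and bit-reproducible. Momentum was adopted
because plain first-order descent at stable learning rates needs
several-fold more epochs on the sigmoid-saturated output layer for the
same held-out error; with it, the noise-free affine recovery task
(200 samples, seeded 70/30 split) reaches a held-out RMSE of ~2–3% of
the per-component target range in under two seconds. Non-finite loss
raises a divergence error naming the epoch.

**Consensus.** Candidate predictions (one per test image) pass through
two tiers of average-linkage agglomerative clustering (Euclidean), each
tier cut at 0.5 of its maximum merge height; the consensus is the
component-wise mean of the most populous tier-1 cluster inside the most
populous tier-2 super-cluster, population ties falling to the cluster
with the lowest within-cluster variance, then to the lowest label. The
"optimal cluster" of the published workflow is not defined there;
population-then-variance is this package's reading, chosen because the
ensemble's purpose is outlier rejection.

## The end-to-end experiment

A replicate generates 50 synthetic micrographs (90 × 90 noise images
whose intensity-band occupancies jitter around a per-protein profile),
computes their ILMFDs, defines per-image true SRIs through a known
affine map, trains on 35, predicts 15 candidates, forms the consensus
SRI_P, and ranks five model SRIs: the planted best sits 0.2 Å from the
true SRI, the four decoys 2.5 Å away along distinct coordinate axes,
so the minimum inter-model distance (2.5 Å) and the selection margin
(1.25 Å) are known by construction. Across 20 seeded replicates the
planted model is recovered 20/20 with median consensus error ≈ 0.04 Å.
Problem sizes (50 images of 90 × 90, 5 models, 20 replicates) keep a
full experiment under half a minute while leaving the margin two
orders of magnitude above the observed consensus error.

**Limits of the synthetic surface.** The micrograph generator produces
iid pixel noise with controlled band occupancy — no aggregate
morphology, optics, or spatial correlation — and the ILMFD → SRI map is
affine by construction, whereas the real mapping is unknown and
plausibly nonlinear. Passing therefore establishes that the pipeline's
statistics, training and consensus machinery are correct and
deterministic, not that micrographs of real aggregates predict real
SRIs; that claim rests on the benchmark table, where selections made
with the image-predicted SRI match those made with the
reference-structure SRI for all six proteins.

## Model selection and RMSD

DC_MOD/DP_MOD are plain Euclidean distances on the 8-vectors; ranking
ties are broken by label order and logged. RMSD between two structures
is computed after transforming *each* into its own ICS — no optimal
superposition — because the invariant frame is the method's own notion
of canonical placement; a Kabsch mode (centred SVD superposition) is
available for comparison and is never larger than the ICS-frame value.
Pairing is by (chain, residue number, insertion code) intersection by
default, positional pairing as an option. The reported mean ± SD of
RMSD over models uses the population SD.

## Structure I/O

Parsing goes through gemmi with a pre-validation pass that rejects
malformed coordinate fields with the offending line number (gemmi
itself tolerates them silently). One C-alpha per (chain, residue
number, insertion code); the first ALTLOC occurrence wins; HETATM
C-alphas (e.g. calcium) are excluded; the first MODEL block is read
unless another is requested. Oligomers default to *all* chains — the
published workflow is silent on its chain convention, so the choice is
explicit and overridable rather than guessed. Written PDB uses fixed
8.3 coordinate columns, so round trips preserve positions to 1e-3 Å.
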