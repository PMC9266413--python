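# Methods

This note documents the modeling choices, parameters, and numerical details
behind `surfppi`, and what the synthetic benchmark does and does not
demonstrate.

## Surface construction

The molecular surface is the zero isosurface of the probe-inflated signed
distance field `f(x) = min_i (|x − p_i| − r_i) − r_p`, sampled on a regular
grid and triangulated with marching cubes. This is the solvent-accessible
family of surfaces: it is smooth where atoms overlap and inflated by the
probe radius everywhere, but it does not reproduce reentrant
(solvent-excluded) patches. Van der Waals radii are Bondi values
(C 1.70, N 1.55, O 1.52, S 1.80, H 1.10, other 1.80 Å).

Parameters:

* `spacing` (grid step, default **0.7 Å**) — controls mesh fineness; vertex
  positions are accurate to about one spacing, and the single-atom oracle
  bounds vertex radii within 1.5·spacing of the analytic value.
* `probe_radius` (default **1.4 Å**, water).
* Padding is at least `probe + max r_vdw + 2·spacing` so the zero level set
  never touches the grid boundary. A configurable cell budget guards
  against accidentally huge grids.

The exact min-over-atoms field is evaluated by grouping atoms by vdW radius
(six groups at most) and taking the minimum over per-group nearest-neighbor
queries — within a group the nearest center minimizes `|x − p| − r`, so
this is exact, and it is tested against a brute-force evaluation.

Marching cubes is run with face winding oriented along the field gradient,
so vertex normals (normalized sums of incident-face normals) point outward.
Hydrogens are used when present in the input file and never added; waters
are always excluded and other HETATM records are excluded by default.

## Curvature

The shape operator at a vertex is estimated from the `k_geom` nearest mesh
vertices: relative positions and relative normals are projected into the
tangent plane, the 2×2 map `A` minimizing `Σ‖A xⱼ − yⱼ‖²` is solved in
closed form (normal equations with an L2 ridge of 1e-8; near-singular Gram
matrices are flagged degenerate), and the principal curvatures are the
eigenvalues of the symmetrized `S`, ordered k₁ ≤ k₂. The sign convention
makes convex-outward surfaces positively curved (sphere of radius r →
k = +1/r). On icosphere fixtures with analytic normals the estimator is
accurate to well under 1 % of 1/r; accuracy on marching-cubes meshes is
limited by normal estimation rather than by the fit.

The estimator's own default neighborhood is k = 16 (the immediate ~2 Å
ring on a 0.7 Å mesh), which is the right scale for validating against
analytic fixtures. For *featurization* the pipeline deliberately uses a
much larger neighborhood (`ModelConfig.k_geom = 256`, a patch of roughly
4 Å radius): molecular surfaces are rough at the atomic scale, and
curvature measured on the first vertex ring mostly reports atomic
granularity, whereas patch-scale curvature reports the morphology of
binding-site-sized features. On the synthetic generator's shape-marked
interfaces, a two-feature logistic baseline on (k₁, k₂) improves from 0.63
AUROC at k = 16 to 0.94 at k = 256, which is why the larger default was
adopted.

## Chemical features

Per surface point, the k = 16 nearest atoms (`k_atoms`) contribute:

* element one-hot over the fixed palette {C, N, O, S, H, other};
* Fourier distance features `γ(d) = (d, cos(d/2⁰), sin(d/2⁰), …,
  cos(d/2^F), sin(d/2^F))` with **F = 4** (11 values): the dyadic
  denominators expose the distance at length scales from ~1 Å to ~16 Å;
* the Kyte–Doolittle hydropathy of the atom's residue divided by 4.5, so
  ILE → +1 and ARG → −1; unknown residue codes map to 0 with a warning.
  Hydropathy is carried per contributing atom (not patch-averaged): the
  aggregation network learns its own pooling;
* a hydrogen-bond potential at the vertex: `+max(0, 1 − d/cutoff)` for the
  nearest nitrogen (donor class) plus `−max(0, 1 − d/cutoff)` for the
  nearest oxygen (acceptor class), cutoff 3.0 Å, clamped to [−1, 1]. This
  is a deliberately simple geometric surrogate — it has no angular term and
  no per-atom protonation logic — and is labeled as such; it provides a
  donor/acceptor polarity signal, not an energy.

Electrostatic (Poisson–Boltzmann) features are deliberately absent.

## Network

Two streams produce per-point embeddings (default 8 dims each):

* chemistry: record MLP (hidden 16, ReLU) → mean over the k atoms → one
  elementary graph-convolution layer over the point 8-NN graph
  (`h'ᵢ = ReLU(W_self hᵢ + W_neigh · mean_j hⱼ)`);
* geometry: two-layer MLP on (k₁, k₂).

The concatenated 16-dim vector passes through `n_conv_layers = 3` radius
convolutions with `conv_radius = 12 Å` (matching the patch scale customary
for this task). Per layer: `gⱼ = ReLU(pre(fⱼ))`,
`w_ij = kernel(p_j − p_i ⊕ n_j − n_i)` (kernel MLP: 6 → 8 tanh → 1 linear,
output weights initialized small so sums over ~10²-neighbor balls do not
saturate the heads at initialization), `outᵢ = post(Σⱼ w_ij gⱼ)` with the
self edge included, ReLU between layers, final layer linear to the 8-dim
descriptor. Aggregation is a plain weighted sum — the kernel can learn its
own normalization.

The raw-difference kernel is exactly translation-invariant but not
rotation-invariant. An optional mode (`rotation_invariant_kernel`) replaces
the raw differences with six pairwise rotation invariants (offset along the
receiver normal, tangential offset magnitude, offset along the sender
normal, normal alignment, normal-change·offset, distance), making
predictions exactly rigid-motion invariant; the default remains the
raw-difference form.

Heads: site scores are `σ(MLP(e))` per point; interaction scores are
`σ(MLP([e_a + e_b, |e_a − e_b|]))` on the 8-dim embeddings of the two patch
center vertices, a symmetric form so scores cannot depend on protein order.
A patch is a center vertex with its neighborhood ball; the center's
descriptor represents the patch because the convolutions already pool the
neighborhood.

Everything runs on a small NumPy reverse-mode autodiff engine
(`surfppi.autodiff`); neighborhood aggregation uses CSR sparse matmuls with
precomputed sparsity patterns, and every operation's gradient is
finite-difference-checked in the test suite.

## Labeling, sampling, training

* Interface labels: vertex of A is positive iff its nearest vertex of B is
  within **1.4 Å** (vertex-to-vertex; point-to-triangle distance was
  rejected for simplicity and determinism). Labels are computed on the
  full-resolution meshes; the network operates on a seeded subsample of
  `n_points = 256` vertices per protein which inherit their full-mesh
  labels. The subsample is uniform — deliberately so: enriching interface
  vertices would imprint a local point-density signature that the radius
  convolution's weighted sums can read directly, short-circuiting the
  chemo-geometric features. (The single concession: if the uniform draw
  misses a non-empty interface entirely, which can happen for very small
  point budgets, up to four interface vertices replace random picks.)
  Subsampling keeps radius-graph sizes tractable on one CPU while labels
  stay at full surface resolution.
* Balanced sampling: site items are equal numbers of positive/negative
  vertices (drawn with replacement when one class is scarce); pair items
  match each sampled positive vertex of A to its nearest positive vertex of
  B, with negatives drawn uniformly subject to at least one non-interface
  member.
* Training: mean binary cross-entropy, AMSGrad Adam (lr 1e-3), seeded 10 %
  validation split, early stopping when validation loss has not improved
  for `patience` epochs, parameters restored from the best epoch. Library
  defaults are max 300 epochs / patience 10; the benchmark (below) caps at
  24 epochs / patience 6 — held-out AUROC is already far above its
  acceptance margin there, and the cap keeps the five training runs inside
  the benchmark's single-CPU envelope.
  Mini-batches are fixed seeded partitions of the items, merged into
  block-diagonal graphs so each batch is a single forward/backward pass;
  epochs shuffle the batch order. Site and interaction models are separate
  (no shared pre-training).
* AUROC is the Mann–Whitney statistic from average ranks (exact ½ tie
  credit); confusion matrices use a 0.5 threshold.

## Synthetic generator

`synthetic_data` plants a known interface so that recovery can be measured.
Each protein is a "blob": 300 atoms quasi-uniformly covering a sphere of
radius 12 Å (Fibonacci lattice), Gaussian positional jitter σ = 0.1 Å,
elements drawn C:N:O:S = 62:17:20:1, one pseudo-residue per atom. A polar
cap of angular radius 0.7 rad carries (a) a cosine-tapered radial bump of
3 Å on the lock and a matching depression on the key — a curvature signal —
and/or (b) residues drawn from the hydrophobic set {ILE, VAL, LEU, PHE,
ALA, MET} with probability 0.85 versus a uniform background — a hydropathy
signal. The pair is posed bump-into-depression with the *median* facing-cap
envelope separation calibrated to `gap = 1 Å` (a snug, bound-complex-like
contact; the closest approach lands a few tenths of an Å lower, at the
granularity of the atomic envelopes), then given a random rigid motion.
Atoms are serialized as ordinary PDB ATOM records so the full real-data
path (parsing → surfacing → featurization) runs unchanged.

Real interfaces differ in what holds them together — some are dominated by
shape complementarity, others by hydrophobic chemistry — and a model should
exploit both. The generator therefore draws an interface *kind* per pair
(probabilities 1/3 each): `both` (bump + hydrophobic cap), `geometric`
(bump only, no hydrophobic bias), and `chemical` (hydrophobic cap over a
shallow 0.5 Å complementary dome, which keeps the two surfaces conformal —
so contact labels survive — while carrying almost no curvature signal).
This design makes each feature stream *necessary* for about a third of the
pairs rather than merely helpful: a chemistry-only model is near chance on
`geometric` pairs beyond what local atom-distance patterns reveal, and a
geometry-only model is near chance on `chemical` pairs, so ablating either
stream costs a substantial fraction of the achievable AUROC regardless of
how strong the remaining signal is. (A single shared cap carrying both
signals at once turned out not to have this property: with 12 Å
convolutions pooling globally, either signal alone sufficed.)

What the generator does **not** emulate: backbone connectivity and
secondary structure, residue-level atom grouping, reentrant surface
geometry, electrostatics, conformational change, or crystallographic noise.
Passing the benchmark therefore shows the pipeline can recover a planted
chemo-geometric complementarity signal end-to-end; it does not certify
accuracy on real protein complexes.

## Benchmark scale and determinism

The parameter-recovery benchmark (`surfppi.benchmark`) uses 200 training
and 50 held-out test pairs, per-protein point clouds of 256 surface points,
and the training cap above; one full run (both tasks plus the shuffled-label
control and the two ablations) takes on the order of fifteen minutes on a
single CPU. The shuffled-label control is reported as the mean over three
model initializations: with uninformative labels, early stopping keeps a
near-initial model, and a *single* random initialization scores anywhere in
roughly 0.3–0.65 against the true labels (its random head correlates with
the planted structure by chance); the ensemble mean is the meaningful null
statistic. All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawns (dataset, initialization, splits,
sampling, evaluation), so identical seeds reproduce identical training logs
and reports bit-for-bit on one machine.

## Known limitations

* The surface is solvent-accessible-like, not a true solvent-excluded
  surface; deep reentrant pockets are smoothed.
* The h-bond surrogate ignores geometry beyond distance.
* Curvature at marching-cubes vertices inherits normal-estimation noise at
  the atom-granularity scale; the patch-scale default (`k_geom = 256`)
  trades spatial resolution for robustness, so features narrower than a few
  Å are smoothed away.
* The default kernel is translation- but not rotation-invariant (the
  rotation-invariant mode is opt-in).
* Trained weights shipped nowhere: every model is trained from scratch,
  seeded.
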