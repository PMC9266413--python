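# surfppi

Surface-based deep graph representation learning for predicting **protein
binding sites** and **protein–protein interactions (PPIs)** — the screening
problem at the heart of targeted protein degradation, where a protein of
interest and an E3 ligase must form a stable interface for a degrader
molecule to work.

`surfppi` is aimed at computational structural biologists who want a
self-contained, CPU-friendly implementation of the surface-mesh PPI
prediction pipeline: PDB structures in, per-surface-point interaction-site
scores and patch-pair interaction scores out, with a seeded synthetic
benchmark so the whole pipeline can be exercised and validated without any
external datasets.

## The model

1. **Surfacing.** The molecular surface is the zero level set of a
   probe-inflated Euclidean distance field,
   `f(x) = min_i (|x − p_i| − r_vdw,i) − r_probe` (Bondi radii, water probe
   1.4 Å), triangulated by marching cubes on a 0.7 Å grid, with outward
   vertex normals obtained from incident-face normals.
2. **Chemical features.** Each surface point aggregates its *k* = 16
   nearest atoms; every atom record carries an element one-hot over
   {C, N, O, S, H, other}, Fourier distance features
   `γ(d) = (d, cos(d/2⁰), sin(d/2⁰), …, cos(d/2^F), sin(d/2^F))` (F = 4),
   the Kyte–Doolittle hydropathy of its residue rescaled to [−1, 1], and a
   distance-weighted hydrogen-bond donor/acceptor potential. Records are
   embedded by an MLP, mean-pooled, and refined by one graph-convolution
   layer over the point k-NN graph.
3. **Geometric features.** The shape operator `S = −∇N` is estimated at
   each point by a tangent-plane least-squares fit over the 16 nearest mesh
   vertices; its eigenvalues — the principal curvatures k₁ ≤ k₂ (Å⁻¹),
   positive on convex-outward surfaces — feed a shallow MLP.
4. **Radius convolution.** The concatenated chemo-geometric embedding is
   processed by three convolution layers over a 12 Å radius graph: a kernel
   MLP maps each pair's position and normal differences to a scalar weight
   `w_ij`, and `out_i = post(Σ_j w_ij · pre(f_j))`, yielding an 8-dim
   descriptor per point.
5. **Heads.** A logistic site head scores each point as binding/non-binding;
   a symmetric interaction head scores patch pairs from two proteins via
   `MLP([e_a + e_b, |e_a − e_b|])`, so the protein order cannot matter.

Training minimizes binary cross-entropy with the AMSGrad variant of Adam on
balanced samples (interface vertices are those within 1.4 Å of the partner
surface), with a seeded 10 % validation split and early stopping. Evaluation
uses AUROC computed as the Mann–Whitney rank statistic (ties credited ½).

The networks are implemented in NumPy with a compact reverse-mode
autodifferentiation core (`surfppi.autodiff`) — no GPU or deep-learning
framework required.

## Worked example

```bash
# 1. simulate a lock-and-key dataset (PDB files + manifest, 48 train / 12 test)
surfppi simulate --n-pairs 60 --seed 7 --out data/synth

# 2. train an interaction model on the training split (a few minutes on one CPU)
surfppi train --data data/synth --task interaction --seed 7 --out runs/ppi

# 3. evaluate on the held-out pairs
surfppi eval --data data/synth --model runs/ppi/model.npz --seed 7 --out runs/eval
```

which prints:

```
wrote 60 pairs to data/synth
trained interaction model: stopped at epoch 58, best val loss 0.2638
mean interaction AUROC over 12 entries: 0.9706
```

i.e. across the 12 held-out pairs, a sampled interacting patch pair
outscores a sampled non-interacting one about 97 % of the time.
`runs/eval/eval_report.json` holds the per-pair AUROCs and 0.5-threshold
confusion counts. `surfppi predict-sites` and `surfppi predict-interaction`
apply a trained model to arbitrary PDB files, and `surfppi surface` exports
meshes (PLY/OFF) for inspection.

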