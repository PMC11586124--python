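# spatialcci

Reconstruction of cell–cell interaction (CCI) networks from single-cell and
spatial transcriptomics data with a variational graph autoencoder (VGAE),
plus registration of serial tissue sections into a common 3D frame via
Gromov–Wasserstein (GW) matching and Procrustes analysis.

## Who this is for

Spatial transcriptomics measurements (seqFISH, MERFISH, Visium and kin) give
per-cell expression together with spatial coordinates, but the interaction
networks derived from them are noisy and incomplete: edges are missed, the
expression features carry platform noise, and each section is only a 2D cut
of a 3D tissue. `spatialcci` addresses three linked tasks:

1. **Network reconstruction / link prediction.** Cells (or genes) are nodes;
   the observed graph — a spatial k-nearest-neighbor graph of the cell
   coordinates, or a gene graph induced by a curated ligand–receptor (L-R)
   database — is treated as a partial observation. A VGAE denoises it,
   reconstructs existing edges and recovers deleted ones.
2. **L-R database handling.** Ingest, merge and deduplicate TSV ligand–receptor
   tables (with multi-subunit complexes), and turn them into gene-level
   adjacency matrices.
3. **3D alignment.** Register consecutive slices with entropic GW optimal
   transport (invariant to each slice's unknown rigid motion), recover the
   rigid transforms by weighted Procrustes, and stack slices into labeled 3D
   coordinates, from which cross-layer interaction graphs are built.

## The model

The encoder is a three-layer graph convolutional network over the normalized
adjacency Â = D̃^{-1/2}(A + I)D̃^{-1/2}:

    H⁽¹⁾ = ReLU(Â X W⁽⁰⁾),   H⁽ˡ⁾ = ReLU(Â H⁽ˡ⁻¹⁾ W⁽ˡ⁻¹⁾)
    μ = Â H W_μ,   log σ = Â H W_logσ,   Z = μ + exp(log σ) ⊙ ε,  ε ~ N(0, I)

with the inner-product decoder A′ = sigmoid(Z Zᵀ) and the loss

    L = L_recon + β·L_KL (+ λ_adv · L_gen)

where L_recon is positively-weighted binary cross-entropy of A′ against A
(diagonal excluded), L_KL is the Gaussian KL to N(0, I), and an optional
adversarial regularizer trains a small MLP discriminator to tell encoder
latents from prior draws. Slice matching minimizes the entropic GW objective
GW(C, P) = Σ (D_X(i,j) − D_Y(k,l))² P(i,k) P(j,l) by Sinkhorn-Knopp
projections with an annealed regularization schedule.

Everything is dense numpy with hand-derived gradients — the graphs this
package targets (10² – 10³ nodes) train full-batch in seconds on one CPU.

## Worked example

```python
from spatialcci import VGAE, generate_tissue, standardize, sample_negative_edges
from spatialcci.evaluation import remove_edges, score_heldout, roc_auc, accuracy

tissue = generate_tissue(n_cells=200, n_genes=50, n_communities=4, seed=0)
X = standardize(tissue.expression)
A_train, held_out = remove_edges(tissue.true_adjacency, fraction=0.5, seed=0)

result = VGAE(X, A_train).fit(epochs=30, seed=0)
print(result.summary())

negatives = sample_negative_edges(tissue.true_adjacency, len(held_out), seed=0)
scores = score_heldout(result.predict_proba(), held_out, negatives)
print(f"held-out AUROC: {roc_auc(scores):.3f}")
print(f"held-out ACC:   {accuracy(scores):.3f}")
```

prints

```
Variational Graph Autoencoder Results
==============================================
nodes    200   features     50
edges    385   latent       16
hidden dims    (64, 64, 32)
epochs    30   lr 0.01     beta 1
adv_weight 1      pos_weight 50.688
seed 0
----------------------------------------------
final recon loss     2.8586
final KL loss        0.3323
final total          3.8595
==============================================
held-out AUROC: 0.814
held-out ACC:   0.758
```

Half of the 385 ground-truth edges were deleted before training; scoring the
deleted edges against an equal-size sample of non-edges, the model ranks a
true-but-unseen interaction above a non-interaction 81% of the time and
calls 76% of the pairs correctly at the 0.5 probability threshold.

A command-line interface mirrors the pipeline
(`spatialcci preprocess / graph / train / align / network3d /
benchmark-noise / benchmark-removal / fixtures make / db build`); run
`spatialcci --help`.

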