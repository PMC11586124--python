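# Methods

This note documents the models and procedures implemented in `spatialcci`,
the defaults and why they were chosen, what the synthetic data emulates, and
the known limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Graph construction

**Cell level.** The interaction graph over cells is the symmetrized
k-nearest-neighbor graph of the Euclidean distance matrix of the spatial
coordinates: j is a directed neighbor of i if D(i,j) is among the k smallest
off-diagonal entries of row i, and the final matrix is the OR of that
relation and its transpose. The default `n_neighbors = 6` encodes the
assumption that a cell in solid tissue physically contacts a handful of
neighbors in a 2D section; it is exposed everywhere as a parameter. A cell
is never its own neighbor, and ties at the k-th distance break by node index
(stable argsort), so regular grids are deterministic.

**Gene level.** Given a ligand–receptor database, genes i and j are adjacent
iff some pair places them on opposite sides, in either direction. Pairs with
multi-subunit complexes contribute an edge between every ligand-side subunit
and every receptor-side subunit, because the adjacency is per-gene while the
curation is per-complex; within-side subunit pairs are *not* connected.
Database deduplication uses the canonical key (species, sorted uppercase
ligand subunits, sorted uppercase receptor subunits): case, surrounding
whitespace and subunit order are redundancy, but the ligand→receptor
direction is not — an A→B entry and a B→A entry are distinct records, even
though both induce the same undirected gene edge.

**Normalization.** All GCN propagation uses Â = D̃^{-1/2}(A + I)D̃^{-1/2}
with self-loops, so an isolated node has degree 1 and the normalization is
always finite.

## Preprocessing

Cells and genes with all-zero rows/columns are dropped, then each gene is
z-scored with the population standard deviation. Zero-variance genes map to
all-zero columns instead of raising, so constant synthetic inputs survive.
Per-gene (rather than per-cell) scaling was chosen because the encoder
consumes genes as feature channels and the GCN mixes cells; either axis is
defensible and the choice is isolated in one function. Gaussian noise for
robustness experiments is injected *after* standardization — noise standard
deviations of order 1–7 are only meaningful on a unit-scale matrix — with a
flag to apply it beforehand instead.

## The variational graph autoencoder

Three ReLU GCN layers (default widths 64, 64, 32) form a shared trunk;
separate linear GCN heads produce μ and log σ (default latent dimension 16).
The sample Z = μ + exp(log σ)⊙ε feeds the inner-product decoder
A′ = sigmoid(ZZᵀ). Per-node log σ is clipped to ±10 (gradient masked where
active) as a numerical guard; the clip is inactive in normal training.

**Loss.** Reconstruction is mean binary cross-entropy over off-diagonal
entries with a positive-class weight defaulting to the non-edge/edge ratio —
without it, a sparse graph's optimum is the empty prediction. The diagonal
is excluded from the loss and from all evaluation: a self-edge is
meaningless here, and the inner-product decoder is structurally biased
toward it. The KL term is the standard Gaussian KL to N(0, I), summed over
latent dimensions and averaged over nodes, weighted by β (default 1). Hidden
widths, latent size, learning rate (Adam, 0.01), and epochs (30) are
full-batch defaults sized for graphs of a few hundred to a few thousand
nodes.

**Adversarial regularizer.** A 2-layer MLP discriminator (default width 64)
is trained with the logistic loss to separate prior draws (real) from
encoder samples (fake); the generator term pushes encoder output toward the
prior, weighted by `adv_weight` (default 1). The schedule is one
discriminator step then one encoder/decoder step per epoch. The adversarial
stream draws from an RNG stream independent of the model stream, so
`adv_weight=0` reproduces a plain VGAE trajectory bit for bit. The
architecture and loss family are deliberately minimal — a stronger critic
(spectral normalization, Wasserstein loss) is unnecessary at these scales.

**Gradients.** All gradients are derived by hand (dense matrix calculus) and
checked against central finite differences in the test suite to ~1e-6
relative error. One seed controls weight initialization and the per-epoch ε
draws, making loss histories bitwise reproducible on a single device.

**Read-out.** Evaluation decodes μ (the posterior mean) rather than the
stochastic sample: it is the conventional deterministic read-out and removes
sampling variance from scores.

## Slice alignment

Two slices are compared through their intra-slice Euclidean distance
matrices with the quadratic Gromov–Wasserstein objective; the transport plan
has uniform marginals (1/n, 1/m) since no per-cell weights are available.
The solver is mirror descent: each outer iteration linearizes the objective
(gradient c_const − 2 D_X P D_Y) and projects with log-domain
Sinkhorn-Knopp.

Numerical choices, found necessary in practice:

- **Annealed regularization.** A single sharp ε cold-started from the
  uniform plan falls into poor local optima, while a blurry ε cannot drive
  the plan near a permutation (the plan's entropy floor leaves a large
  residual cost). The solve therefore anneals ε down a geometric schedule
  (default 1e-2 → 1e-5, 6 stages, scaled by the mean squared intra-slice
  distance so the setting is unit-free), warm-starting both the plan and the
  Sinkhorn potentials at each stage.
- **Stagnation handling.** With dropout, some points have no true
  counterpart, and at sharp ε the plan can cycle rather than converge; the
  final stage tracks the best-cost iterate and stops after a patience of
  non-improving iterations, returning that iterate with a warning.
- **Marginal polish.** After the outer loop, one high-precision Sinkhorn
  projection is applied so the returned plan satisfies its marginals to
  ~1e-12 regardless of the looser inner tolerances used during the solve.

The rigid transform is recovered by weighted Procrustes under the soft plan
(closed form via SVD of the weighted cross-covariance). Reflections are
excluded by default (det R = +1) — serial sections should not be mirrored —
and an isotropic scale factor is available but off by default: the
registration formula is rotation + translation, and allowing scale on real
sections would absorb sectioning artifacts into geometry. A fused cost
mixing a squared expression-feature distance into the GW linearization is
available behind a weight α (default 0, purely spatial), for data where
expression should inform the matching. Stacking places slice s at
z = s × layer_spacing after mapping all slices into the first slice's frame.

## Evaluation

AUROC, average precision and accuracy delegate to scikit-learn;
independently written brute-force oracles (pair counting with half-weight
ties, an explicit threshold sweep, confusion counts) pin their behavior to
1e-12 in the tests. Held-out scoring treats removed edges as positives
against an equal-size seeded sample of non-edges; accuracy uses a 0.5
probability threshold. The two benchmark experiments are (a) edge removal:
delete a fraction of edges, train on the remainder, score the deleted edges;
and (b) feature noise: perturb expression with N(0, sd²), mask a fixed 10%
of edges, train, score the masked edges. Both replicate over seeds and
report per-seed rows plus per-condition arithmetic means, displayed at 3
decimals with full precision retained.

## Synthetic data

`generate_tissue` draws equally sized cell communities as Gaussian blobs
(sd 2) centered at evenly spaced angles but strongly unequal radii
(8 → 15.5 for the default four). The radius spread is deliberate: it gives
the blob constellation a unique best rigid registration. An evenly spaced
equal-radius layout is rotationally near-symmetric at the community level,
which makes the planted rotation of a slice pair unidentifiable for a
matcher that is — by design — invariant to rigid motions; real tissue
morphology does not have that degeneracy. Expression is a rank-k model:
a community-specific loading vector (scaled by `signal_strength`, default 2)
plus i.i.d. N(0, noise_sd²) per-cell noise (default 1), so community
membership is statistically recoverable from features — the property the
autoencoder exploits. The default benchmark fixture is 200 cells, 50 genes,
4 communities, 6 neighbors.

What this generator does **not** model: count statistics (negative binomial
noise, zero inflation, library-size variation), within-community expression
gradients, doublets, segmentation errors, or platform-specific spatial
artifacts. Passing benchmarks on these fixtures therefore demonstrates that
the machinery is correct and that recovery works when features carry
community-level signal; it does not certify performance on any particular
real platform.

`generate_multislice` applies cumulative planted rigid transforms (default
20° and a fixed translation per step) with positional jitter (default sd
0.01) and seeded cell dropout (default 5%), returning the planted transforms
and the surviving counterpart map as ground truth. `generate_toy_lr_db` and
`generate_reference_lr_tables` produce ligand–receptor tables; the latter
writes synthetic stand-ins for the curated human/mouse reference database
files, planting exactly the published unique-pair counts (5786 human, 4806
mouse) beneath ~15% redundant rows (verbatim duplicates, case/whitespace
variants, reordered complex subunits) so that the dedup logic is genuinely
exercised. These files are synthetic: gene symbols are generated, and the
planted counts verify the dedup contract, not the biological curation.

## Problem sizes and benchmarks

The shipped benchmarks use the 200-cell fixture for model recovery (50% edge
deletion; noise sd 0 and 7; seeds 0–4; 30 epochs) and 100-cell slices for
alignment (3 slices, 20° planted rotations, jitter sd 0.01, 5% dropout,
seeds 0–4). These sizes keep a full benchmark run to minutes on one CPU
while leaving the statistical questions non-trivial; all of them scale up
through parameters.

## Known limitations

- Dense O(n²) matrices throughout: practical to a few thousand nodes, not
  to 10⁵-cell atlases (no minibatch or neighbor-sampling training).
- The GW matcher assumes comparable geometry between slices; it has no
  partial-overlap handling beyond tolerating a small dropout fraction.
- Accuracy at the fixed 0.5 threshold depends on decoder calibration, which
  the positive-class weighting shifts; rank metrics (AUROC/AP) are the more
  stable summaries.
- Gene-level evaluation against an L-R database needs a defined negative
  universe; the balanced seeded sample used here is one convention among
  several, and is configurable.
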