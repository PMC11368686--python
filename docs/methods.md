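# Methods

## Model and training

The encoder maps a log-normalized expression vector to a spatial
representation; the projection head maps that representation to the space
where the contrastive loss is computed and is discarded after training.
Both are MLPs: the encoder applies, per layer, a dense transform, batch
normalization and leaky ReLU (slope 0.01), with default widths
(1024, 512); the projector has widths (256, 128) with a ReLU after its
first layer only. For gene panels narrower than 1024 genes the first
encoder layer is capped at 4× the panel width (logged), keeping the
parameter count proportionate to the input.

Batches are built from the reference's spatial k-nearest-neighbor graph
(Euclidean, self excluded, distance ties broken toward the lower index).
An epoch partitions the cells into anchor groups of batch_size/2 without
replacement, so every cell anchors exactly once per epoch; each anchor
draws one positive uniformly from its k spatial neighbors. A positive may
coincide with another anchor — excluding such collisions would bias the
positive distribution, so they are allowed. Projections are L2-normalized
so dot products are cosine similarities, consistent with the small default
temperature τ = 0.05.

The per-sample infoNCE loss treats every in-batch cell as a query with its
pair partner as the positive. Two denominator conventions are
implemented: `with_positive` (default) sums over all other in-batch
projections — the conventional softmax cross-entropy form, bounded below
by 0 — while `negatives_only` sums over the N−2 negatives alone and can
go negative once the positive dominates. Both are exposed because the
second corresponds to a literal reading of the loss as sometimes printed;
the default is the standard, numerically well-behaved form.

Optimization is SGD with momentum 0.9 and L2 weight decay 5e-4, learning
rate cosine-decayed from 0.1 over the configured epochs (default 3000;
the test suite and the acceptance script train 300 epochs on an
800-cell synthetic tissue, which this scale reaches convergence-like
behavior on). Forward/backward passes, batch normalization and the
optimizer are implemented directly in numpy with explicit gradients; the
backward pass is validated against central finite differences in the test
suite. Batch-normalization inference uses running statistics frozen at
training time, so encoding is deterministic. All randomness (weight
initialization, anchor order, positive sampling) flows from the single
config seed; run-level reproducibility on one machine is guaranteed,
cross-platform bit-identity is not promised.

## Normalization

Expression input is per-cell library-size scaled to a common target (the
median library by default) followed by log1p. This is a deliberate,
documented stand-in for pooled-size-factor normalization, which the
pipeline treats as an upstream given: pre-normalized input is accepted by
flagging `is_lognorm`, and re-normalizing a flagged profile is an error
rather than a silent re-application. Normalization is applied per dataset
(reference and query separately). Highly variable genes are ranked by the
variance of log-transformed values.

## Spatial inference

* **Neighbors**: top-k cosine similarity among query representations,
  self excluded, ties to the lower index.
* **Pseudo-space**: metric MDS (SMACOF stress majorization, one seeded
  random initialization) on the dissimilarity 1 − cosine similarity.
* **SC→ST assignment**: the weighted similarity
  s_{i,j} = cos(R_i,R_j) + (1/K)·Σ_k exp(−(1−cos(R_i,R_k))²)·cos(R_k,R_j)
  smooths the query-to-reference similarity over the query cell's K most
  similar peers; the cell itself ranks first in its own neighbor list, so
  K=1 reduces to twice the plain cosine and leaves the argmax unchanged.
  Each cell is assigned the reference location of its row maximum (ties
  to the lower index). Multiple cells may share a location ("clumping");
  no repulsion or transport-based de-clumping is applied.
* **Confidence**: per cell, up to n_top = 20 candidate locations are
  selected greedily in descending similarity under mutual exclusion on
  the reference's spatial m-NN graph (m = 80), so candidates represent
  distinct spatial modes rather than one tight cluster. Softmax over the
  selected similarities gives probabilities whose Shannon entropy H
  (natural log) is normalized across the query batch:
  C = 1 − H / max(H). If every cell has zero entropy all confidences are
  1; a cell with fewer than two selectable candidates is flagged NaN.
  Because the normalizer is the batch's own entropy maximum, C is a
  relative score: at least one cell always scores 0.
* **Gene contribution**: C_{i,j} = ‖f(X_i + ε e_j) − f(X_i)‖₂ / ε with
  ε = 0.01, i.e., a finite-difference sensitivity of the representation
  to each gene; for a linear encoder this equals the weight-matrix column
  norm exactly.

## Evaluation

Neighbor hit counts |predicted top-k ∩ true top-k| per cell (true
neighbors by Euclidean distance on held-out coordinates, self excluded)
and averages over cells for k = 20, 40, …, 200; the analytic expectation
under uniformly random prediction is k²/(n−1). Neighborhood JSD compares
cell-type proportion vectors of the predicted and true k = 20
neighborhoods with the Jensen–Shannon distance (natural log, range
[0, √ln 2]; a base-2 option rescales to [0, 1]); per-type summaries group
by the focal cell's type. Global structure is scored per cell by the
Spearman correlation between predicted and true distance vectors to all
other cells; cells with constant distance vectors (fully clumped
predictions) are excluded and counted. The shuffled-location null reruns
any coordinate-dependent metric under seeded random permutations of the
true coordinates and reports mean, sd and quantiles.

## Synthetic tissue generator

The generator produces the data regime the method assumes, at desk scale:
cells uniform in the unit square; discrete zones as Voronoi regions of
seeded random centers, giving cell-type labels and zone-specific
expression programs; continuous spatial gradients as random Fourier
features approximating a Gaussian-process field with length-scale
`smoothness` (default 0.3). Only 25% of genes carry the zone/gradient
signal (amplitude 0.8 on the log scale over a baseline of N(1, 0.5²));
the rest are housekeeping-like. All genes are additionally modulated by
three shared per-cell "cell-state" factors — emulating cell size, stress
and cycle-like variation — and by iid measurement noise (Gaussian sd,
Poisson, or gamma-Poisson negative binomial), both scaled by
`dispersion` (default 1.0).

The correlated cell-state component is the load-bearing design choice: it
dominates naive expression-space distances, so nearest-neighbor search on
raw profiles (or on an untrained random encoder, which quasi-preserves
input geometry) recovers few true spatial neighbors — matching real
single-cell data, where most expression variance is not spatial. The
contrastive objective cancels it, because positives share location but
not cell state. Under the defaults (800 cells, 100 genes, 5 zones, seed
7, 300 epochs) the trained encoder recovers ~10.7 of 20 true neighbors
versus 2.35 untrained and 0.50 expected at random. With `dispersion → 0`
both nuisance sources vanish and expression identifies zones perfectly.

The latent tissue is a pure function of the config seed, so
`make_query` can draw an independent measurement replicate of the same
tissue — new cell states and noise, optional coordinate jitter and
per-entry dropout — with truth coordinates withheld for evaluation. Spot
binning pools cells on a regular grid of side round(√(n_cells/spot_bin)),
summing counts, labeling by majority type and dropping empty bins.

What the generator does **not** emulate: platform-specific capture
chemistry, segmentation errors, spatially varying cell density, batch
effects between reference and query beyond fresh noise draws, or
realistic zero-inflation profiles. Passing tests therefore demonstrate
the correctness and internal consistency of the pipeline under its own
assumptions, not performance on any particular real platform.

## Numerical choices and edge cases

Distance and similarity ties everywhere resolve to the lower index via
stable sorts, making outputs deterministic. Cosine similarities are
clipped to [−1, 1] against floating-point drift. Zero-norm representation
rows, zero-count cells, non-finite losses, duplicate gene ids and
gene-order mismatches between encoder and query are hard errors, never
silent repairs. The infoNCE implementation is vectorized over the
similarity matrix with log-sum-exp stabilization and is checked against a
naive per-sample double loop to 1e-6. Checkpoints store layer weights,
batch-norm statistics, the input gene list, the config and the loss
trajectory in one `.npz` file.

## Problem sizes

Default test and acceptance runs use 800 cells × 100 genes with 300
training epochs, chosen as the smallest scale at which the end-to-end
contrast between trained, untrained and null baselines is unambiguous;
the package itself has no size-specific logic beyond the first-layer cap
described above.
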