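# Methods

## The model

Given an n×m data matrix A (rows = samples, columns = features), the method
seeks a 2-D **linear** projection of the data that retains more information
than the top-2 PCA projection.  It does so by embedding the projection inside
a multilayer perceptron:

    input (m) → bottleneck (2, linear, no bias, no activation)
              → hidden (d, tanh) → hidden (d, tanh) → output (m, identity)

The first layer is the projection under study; the remaining layers are a
nonlinear decoder.  Training minimises the L2 reconstruction error

    E = ½ · mean over all n·m entries of (y − x)²

by mini-batch stochastic gradient descent.  The encoder is initialised at the
top-2 PCA loadings (right singular vectors of the centered, standardized
matrix), so optimisation starts exactly at the PCA solution.  After training
the decoder is discarded: the deliverable is the m×2 projection matrix, and
the embedding is strictly linear in the data.

The comparison baseline is the *frozen-encoder* network: identical
architecture and training, but the first-layer weights are never updated and
remain the PCA loadings.  Because the free network can always represent the
frozen one, a lower final loss for the free encoder indicates that a
projection other than the top-variance one allows the decoder to retain more
of the data.

**Variance captured.**  On per-feature standardized data the total per-entry
mean square is exactly 1, so `(1 − 2E)·100` is the percentage of total
variance retained by the reconstruction.  With a purely linear decoder set to
the transpose of an orthonormal rank-2 encoder this reduces to
100·(λ₁+λ₂)/Σλ, the usual PCA explained-variance ratio — a closed form the
test suite verifies to 1e-6.  E is always computed with the per-entry-mean
convention; without it, "1 − 2E" would not be a fraction.

## Assumptions and conventions

- Features are standardized to zero mean and unit **population** variance
  before training (constant features are rejected with the feature named).
  The zero predictor then has E = 0.5 ↔ 0% variance captured.
- The bottleneck width is fixed at 2; this is deliberately a 2-component
  method and the public API does not expose a general k.
- Principal-direction signs follow a deterministic convention: the
  largest-magnitude entry of each loading column is positive.
- The decoder activation is tanh by default (bounded, smooth, zero-centered
  — appropriate for standardized targets and clean for gradient checks);
  sigmoid and relu are selectable.  The output layer is always linear.
- Decoder weights are initialised from the uniform
  (−√(6/(fan_in+fan_out)), +√(6/(fan_in+fan_out))) scheme with zero biases,
  seeded; identical (data, configuration, seed) triples reproduce
  bit-identical results because all randomness flows through one
  `numpy.random.default_rng` per concern.

## Training parameters

| parameter      | default | meaning                                            |
|----------------|---------|----------------------------------------------------|
| learning_rate  | 0.01    | SGD step size                                      |
| epochs         | 2000    | epoch cap                                          |
| batch_size     | 32      | mini-batch size (clamped to n; `"full"` allowed)   |
| patience       | 50      | epochs without > min_delta improvement before stop |
| min_delta      | 1e-7    | improvement threshold for early stopping           |
| hidden_width d | 32      | width of both decoder hidden layers                |

"Training until the loss reaches its minimum" is operationalised as the
patience rule; the epoch cap bounds runtime.  The cap was sized so that
the loss on the synthetic benchmarks is close to its attainable minimum:
with a much smaller cap (a few hundred epochs) runs stop well above the
minimum and the free-vs-frozen comparison is dominated by optimisation
noise rather than by the representational difference between the two
networks.  Loss history records
the full-data E after every epoch; divergence (non-finite E) raises an error
suggesting a smaller learning rate.  With `freeze_encoder` the encoder bytes
are asserted unchanged after training.

## Single-cell preprocessing

The pipeline applies, in order: (1) drop genes with nonzero counts in fewer
than 3 cells; (2) drop cells expressing fewer than 200 genes; (3) drop cells
expressing more than 2,500 genes; (4) drop cells whose mitochondrial read
fraction exceeds 0.95.  All boundaries are strict inequalities.  The 0.95
mitochondrial default is unusually permissive compared with common practice
(0.05–0.20) but is this pipeline's documented default and is configurable.
Because removing cells can push genes back below the prevalence threshold
(and removing genes can push cells below the complexity threshold), the
gene/cell filters are iterated to a fixed point; this makes the pipeline
idempotent, and the QC report accumulates per-rule removal counts over
passes (a cell violating several rules counts under the first in rule
order).

Retained cells are scaled to 10,000 total counts and transformed by
log10(x + 1).  Highly variable genes are ranked by var/mean dispersion of
the log-normalized values, z-scored within 20 equal-width mean bins;
singleton or zero-spread bins fall back to the global z-score so that
extreme-mean outlier genes can still rank.  Ties break deterministically by
gene name, and the retained genes keep their original column order.

## Clustering evaluation

k-means (Lloyd's algorithm, k-means++ seeding, 10 restarts, seed-fixed) is
delegated to scikit-learn — standard machinery, not part of the method under
study.  The evaluation statistics are implemented from their definitions:

- **Silhouette** SH(i) = (b−a)/max(a,b) with a = mean Euclidean distance to
  the other members of i's cluster and b = smallest mean distance to another
  cluster; singleton clusters score 0 (the common convention).
- **Adjusted Rand index** in the Hubert–Arabie contingency-table form.  A
  pair-count expression occasionally quoted in the literature is exposed as
  `ari_pair_expression` for cross-checking only; it does not reduce to the
  Hubert–Arabie form in general and is not used for evaluation.
- **Pair counts** (a, b, c, d over unordered sample pairs) are computed via
  contingency-table algebra, equivalent to O(n²) enumeration (tested against
  it).

Both statistics agree with the scikit-learn reference implementations to
1e-10 in the test suite; the silhouette comparison feeds both sides one
exact `scipy.spatial.distance.cdist` distance matrix so the check isolates
the aggregation formula rather than floating-point differences in distance
kernels.

## Synthetic data

**Manifold generator** (`make_manifold`): a 2-D latent uniform on [−1,1]²
mapped through fixed smooth feature functions (quadratic by default; also
sinusoidal, a swiss-roll-like curl, and a purely linear control) with
independent Gaussian noise (default sd 0.1 against roughly unit-scale
features, i.e. ~10% noise).  Random map coefficients are drawn per feature,
except that the coefficients of the *linear* latent terms get a magnitude
floor (|c| ∈ [0.7, 1.5]): if a latent coordinate is only weakly expressed in
the features, no 2-D projection could recover it and latent-recovery
experiments would measure the generator, not the method.  Default size
n=500, m=10 — large enough for stable training, small enough that the full
paired comparison over 10 seeds runs in well under a minute.

On this generator the free encoder's advantage over the frozen one is
consistent once training is run near to convergence — final losses differ
by a few tenths of a percent to a few percent of total variance in the free
encoder's favour.  The purely linear control map shows no advantage, as
expected: there the top-variance projection already carries all the
structure.

**Count generator** (`make_counts`): 3 cell types over 3,000 genes share a
log-normal baseline expression profile; each type upregulates a random 10%
of genes 4-fold; cells get log-normal library-size factors (sd 0.4); counts
are negative binomial with shape r = 0.5 (var = μ + μ²/r, strongly
overdispersed).  The last 50 genes are named `MT-*` and flagged
mitochondrial.  Optional planted QC violators are constructed strictly
beyond each threshold: 150 expressed genes (< 200), 2,600 expressed genes
(> 2,500), and ~97.5% mitochondrial reads with a normal gene count.  Normal
cells land comfortably inside all QC windows (roughly 600–1,700 expressed
genes, < 4% mitochondrial), so on default parameters the pipeline removes
exactly the planted cells.

What the generators do **not** emulate: real gene-level count distributions,
batch effects, ambient RNA, doublets, dropout beyond what the NB gives, or
any particular tissue's cluster geometry.  Passing tests therefore show the
machinery is correct and the claimed qualitative effects hold in a
controlled regime — not that the method wins on any particular real dataset.

## Numerical choices

- Gradient correctness is established against central finite differences
  (h = 1e-5, relative error < 1e-5) across all weights and biases; for relu
  the tolerance is 1e-4 and pre-activations are kept away from the kink,
  where the derivative is discontinuous and differencing is meaningless.
- PCA uses `numpy.linalg.svd` of the centered matrix; explained fractions
  are ratios of squared singular values, so they are convention-free.
- k-means inherits scikit-learn's empty-cluster handling and restarts.
- The benchmark harness standardizes each (possibly HVG-subset) matrix
  independently before reduction.

## Known limitations

- SGD with a fixed learning rate typically runs to the epoch cap (the
  patience rule rarely fires at min_delta = 1e-7 because mini-batch noise
  keeps producing tiny improvements); the final loss sits slightly above
  the attainable minimum.
- The frozen-encoder run re-uses the free run's architecture and seed;
  no learning-rate schedules or optimizers beyond plain SGD are provided.
- `select_hvg` requires at least 2 genes to remain (a 1-column matrix is not
  a valid data matrix here).
- MDS in the benchmark harness is O(n²) and intended for the synthetic
  scale, not full-size atlases.
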