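# Methods

This note documents the models implemented in `odormetric`, their
assumptions, the numerical choices behind the optimizers, what the synthetic
benchmark generator does and does not emulate, and the problem sizes used by
the test suite and `scripts/acceptance.py`.

## Supervision: triplet constraints

All learners are supervised by relative similarity comparisons
(i, j, k) meaning "molecule i smells more like j than k". Because human
similarity ratings are subjective and poorly calibrated in absolute terms,
only the *orderings* of pairwise dissimilarities are treated as signal.
Triplets are derived from per-molecule descriptor profiles:

- continuous profiles (mean over subjects of 0–100 analog ratings per
  descriptor) are compared with the cosine dissimilarity
  `d_ij = 1 − y_i·y_j / (‖y_i‖‖y_j‖)`, which for nonnegative rating vectors
  lies in [0, 1];
- binary profiles (a descriptor is present when at least a fraction —
  default 25% — of subjects rated it above zero) are compared with the
  Jaccard distance; two empty descriptor sets get distance 0, since both
  molecules are odorless under the vocabulary and fabricating dissimilarity
  would fabricate constraints.

The exhaustive constraint set {(i, j, k) : d_ik − d_ij > τ} has
n·C(n−1, 2) elements when all dissimilarities are distinct and is O(n³);
a seeded uniform subsample (default cap 500,000) keeps training sets
manageable. The tie tolerance τ defaults to 1e−9: float-equal
dissimilarities are ties, not constraints, and are never emitted.

Train/validation/test splits come in two units. Splitting *triplets* is
appropriate for the transductive MDS evaluation; splitting *molecules*
(keeping a triplet only when all three members share a partition) is the
honest out-of-sample protocol for the parametric learners. Both are
provided; the repeated-splits evaluator reports mean and population variance
of TGA across splits.

## Ordinal MDS

`OrdinalMDS` implements Kruskal-style non-metric MDS. The stress of an
embedding X̂ is

    S = Σ_{i<j} (t_ij − d_E(x̂_i, x̂_j))² / Σ_{i<j} t_ij²

with each unordered pair counted once. In ordinal mode the targets t_ij are
disparities: the isotonic regression (scikit-learn's implementation) of the
current embedding distances onto the dissimilarity order. In metric mode
t_ij are the raw dissimilarities.

Numerics: initialization is the classical (Torgerson) solution — eigenvectors
of the doubly centered squared-dissimilarity matrix — falling back to seeded
Gaussian coordinates when no positive eigenvalue exists; coincident points
are jittered so gradients are defined. Each iteration takes a gradient step
on the coordinates with the disparities held fixed, then re-fits disparities;
a step is accepted only if the full stress decreased (step halving up to 40
times, mild growth by 1.2 after acceptance), so the stress trace is monotone
non-increasing by construction. Convergence is declared when an accepted
iteration improves stress by less than `tol` (default 1e−7); hitting
`max_iter` (default 300) is not an error — the best embedding found is
returned and flagged via `converged_`.

The default output dimension is 25, mirroring the parametric embedders; a
`dimension_sweep` helper reports stress and TGA per dimension (stress
decreases and TGA increases with dimension on embeddable data). MDS is
deliberately transductive — no out-of-sample extension is provided; that gap
is what motivates the parametric learners.

## Mahalanobis triplet metric

`MahalanobisTripletMetric` learns `W` (d̂ × d) with distance
`d_M(x_i, x_j) = ‖W x_i − W x_j‖²`, i.e. the quadratic form in
`M = WᵀW`, which is symmetric PSD by construction. Training minimizes the
exponential margin loss `Σ exp(−(d_M(x_i,x_k) − d_M(x_i,x_j)))` — the same
family as the deep learner with the identity embedder, so the two learners
differ only in the embedding function — by seeded mini-batch Adam
(lr 0.001, batch 200 by default). `W` is initialized at the identity-padded
matrix, so training starts from the squared-Euclidean baseline and can only
be judged against a meaningful start. The exponent is clipped at ±500 to
keep the loss finite on extreme margins.

The loss operates on raw squared distances, so the margin scale matters:
`rescale_features` scales a feature matrix to a median squared pairwise
distance of ~1 and should be applied (or z-scoring used) before fitting
either parametric learner.

## Deep triplet embedder

`DeepTripletEmbedder` is a shared-weight three-branch (triplet/siamese)
network: fully connected layers with rectifier nonlinearities except the last
layer, which is linear with a bias pinned at zero. The last linear layer
realizes the metric — absorbing `M = WᵀW` into it is mathematically
equivalent to learning a separate PSD metric on the penultimate features and
avoids a redundant parameter — so the perceptual distance is plain squared
Euclidean in the output space: `d_P(x_i, x_j) = ‖φ(x_i) − φ(x_j)‖²`.

Defaults: hidden widths (256, 128) tapering a 379-dim input to a 25-dim
output, Adam with lr 0.001, batch size 200, 1000 epochs, exponential triplet
loss `exp(−(‖a−n‖² − ‖a−p‖²))` summed over the batch. A hinge alternative
`max(0, m + ‖a−p‖² − ‖a−n‖²)` is available behind `loss="margin"`. Weight
decay is exposed and defaults to 0 (no regularization). When a validation
triplet set is supplied, per-epoch validation loss and TGA are traced and the
weights with the best validation TGA are retained (`best_epoch_`); otherwise
the final weights are kept. A fixed `random_state` makes initialization,
batch order and hence the loss traces bitwise reproducible. Non-finite
training loss aborts with a diagnostic rather than returning garbage.

The network and its backward pass are implemented directly on numpy arrays;
at the problem sizes this package targets (hundreds of molecules, ≤ a few
hundred feature dimensions) CPU matmuls are entirely sufficient.

## Evaluation protocols

- **TGA**: 100 × fraction of triplets with d(i, j) < d(i, k). Model-side
  exact ties count as failures by default (conservative); `tie_credit=0.5`
  grants half credit. TGA is a rank statistic — invariant under strictly
  increasing transforms of the distance.
- **Pairwise report**: full distance matrix min–max normalized over
  off-diagonal entries, diagonal forced to 0; idempotent. Degenerate case
  (all off-diagonal distances equal): zeros if that value is 0, ones
  otherwise, with a warning.
- **Retrieval**: k nearest non-query molecules, ascending distance, ties
  broken lexicographically by id for reproducibility.
- **Expert alignment**: expert triplets are built with the Jaccard distance
  on binary expert profiles restricted to the vocabulary shared with the
  non-expert data; the learned metric's TGA against them is reported together
  with a table of discordant triplets (molecule keys and descriptor sets).
- **Concentration contrast**: both concentration variants of each molecule
  are embedded with one model; a molecule is flagged when its two
  concentrations are farther apart than its median distance to other
  molecules ("same molecule, different smell").

Variance across splits is reported as population variance (and standard
deviation alongside), since the convention behind "mean and variance" report
surfaces is ambiguous.

## Synthetic benchmark generator

`SyntheticSpec`/`generate` plant known perceptual structure:

- latent coordinates z ∈ ℝ^q are standard Gaussian with the first (hedonic)
  axis scaled by `hedonic_weight` (default 3): pleasantness is treated as the
  dominant dimension of odor perception. Ground-truth dissimilarity is
  Euclidean in this latent space.
- structural features are an orthonormal linear map of the latent
  coordinates (an isometry) plus Gaussian noise, or a fixed random tanh
  network ("nonlinear-lift") when nonlinear structure is wanted.
- descriptor means are softplus readouts `softplus(c + gain·Bz)` rescaled
  into [0, 100]. The baseline offsets c make a few descriptors common and
  most rare (right-skewed usage); the linearized loading matrix
  diag(softplus′(c))·B has orthonormal columns orthogonal to the baseline
  profile, so in the small-gain limit the cosine dissimilarity between
  noise-free profiles is a monotone function of latent distance and
  profile-derived triplets agree with the planted orderings. At the default
  gain (0.3, chosen so ratings vary over tens of points) softplus curvature
  flips a few percent of near-tie triplets — the regime-dependence is tested
  explicitly. The hedonic axis loads primarily on the "pleasant" descriptor.
- subject ratings: with `subject_noise_sd > 0` (default 15 on the 0–100
  scale) a subject *uses* a descriptor with probability
  sigmoid((mean − 25)/10) — a detection model, without which additive noise
  alone would make every subject rate every descriptor above zero and
  25%-of-subjects binarization degenerate — and, when used, reports the mean
  plus Gaussian noise clipped to [1, 100]. With zero noise all subjects
  report the exact means.
- the low-concentration variant shifts each molecule's latent point by a
  random vector of expected norm `concentration_shift` (default 0.75) before
  both the feature map and the readout, so "same molecule, different smell"
  cases arise by construction.
- defaults mirror the descriptor-rating study the package targets: 480
  molecules, 55 subjects, 20 descriptors plus "pleasant", 379-dim features,
  two concentrations. The latent dimension (6) and the noise magnitudes are
  the package's own choices of a realistic regime.
- `expert_relabeling` builds a synthetic stand-in for a binary
  expert-descriptor table: an idealized annotator thresholds the noise-free
  means at the intensity where the detection probability reaches the
  binarization fraction, then a share of each molecule's present descriptors
  is relabeled to an absent one (dialect mismatch that preserves set sizes).

What the generator does **not** emulate: real physicochemical descriptor
marginals (Mordred/Dragon-like distributions), descriptor-vocabulary
semantics, subject-specific biases or anchoring effects, and panel-size
imbalance. Passing tests therefore demonstrate that the learners recover the
structure they are designed for under a controlled noise model — not that
any particular accuracy will be attained on a specific human dataset.

## Planted-recovery scenarios and problem sizes

The scenarios in `odormetric.recovery` are the package's end-to-end
self-tests; their sizes were chosen once so that the whole suite runs in a
few minutes on one CPU:

- **MDS recovery**: n = 100 molecules, noise-free distances from a planted
  3-D configuration, fit at d̂ = 3 (stress < 0.05, TGA ≥ 95%, Procrustes
  residual < 1e−2; dimension sweep over 1–3).
- **Mahalanobis recovery**: planted metric diag(10, 1, …, 1) in d = 10,
  n = 200, 20,000 training and 5,000 held-out triplets, 200 epochs
  (TGA ≥ 90% and ≥ 10 points over the Euclidean baseline).
- **Deep vs linear**: 2-D latent space lifted by a fixed random tanh network
  (hidden width 8, scale 4) into 20 features, n = 160, 15,000/3,000/4,000
  train/val/test triplets, 120 deep epochs vs 150 linear epochs (the deep
  metric exceeds the linear one by ≥ 5 TGA points on average over seeds,
  and both exceed the raw Euclidean/cosine baselines).
- **Label-randomization null**: training on coin-flip triplet orientations;
  validation TGA stays at the 50% chance level (5,000 validation triplets).
- **Hedonic ablation**: n = 120, 60 features, default rating noise; triplets
  built from profiles with and without the "pleasant" descriptor; every
  learner's TGA drops without it, because the ablated orderings depend on
  weaker, noisier latent axes.
- **Expert alignment**: n = 100; deep metric trained on 25%-binarized,
  Jaccard-derived non-expert triplets over 16 shared descriptors, scored
  against synthetic expert triplets with 20% descriptor relabeling, plus the
  noise-free ceiling.

`scripts/acceptance.py` runs these scenarios (stochastic ones over three
seeds derived from `--seed`) and writes each measured quantity as
`{"value": ..., "n": ...}` JSON.

## Known limitations

- Ordinal MDS has no out-of-sample extension by design.
- The exponential loss is sensitive to the raw distance scale; features must
  be brought to an O(1) distance scale first (`rescale_features`).
- Exhaustive triplet construction materializes per-anchor boolean planes
  (O(n²) memory per anchor); for n in the thousands use the sampling cap.
- The Jaccard dissimilarity on small descriptor sets is coarse and tie-rich;
  triplet sets built from it are sparser and noisier than cosine-derived
  ones, which bounds attainable alignment scores.
- The deep embedder is a plain MLP without GPU paths or hyperparameter
  search; both are out of scope.
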