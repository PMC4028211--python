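# Methods

`gcselect` implements a hybrid wrapper method for selecting small predictive
gene subsets from labelled expression matrices (bulk microarray-style data:
a few thousand genes, tens of samples, 2–5 classes). The method chains four
ideas: a univariate filter to cut the search space, a neural-network
sensitivity score that measures how strongly each gene drives the class
outputs, K-means clustering to expose redundancy among co-expressed genes,
and a discrete particle swarm that searches subsets of the surviving genes,
scored by cross-validated classifier accuracy with a size penalty.

## Data model and preprocessing

Expression matrices are genes × samples on disk and in memory; classifier
code transposes at its boundary. Class labels are mapped to integer codes in
first-appearance order of the labels file. Every class must have at least two
samples (per-class standard deviations and stratified folds need them);
missing values are rejected rather than imputed.

Samples are split once into training and test parts (stratified, default
60% train). All scores below are computed on the training part only. By
default each gene is standardized to zero mean and unit variance on the
training split (parameters then applied to the test split). This matters for
two reasons: logistic hidden units saturate on raw expression scales, and
unstandardized sensitivities are dominated by gene scale rather than class
association. The switch is exposed (`standardize`) for data that is already
normalized.

## Extreme learning machine (ELM)

The classifier throughout is a single-hidden-layer feedforward network
trained as an ELM: input weights `Wh` and biases `b` are drawn once from
Uniform(−1, 1) and never updated; the hidden layer is the logistic sigmoid
`h = σ(X Whᵀ + b)`; the output layer is linear with weights solved
analytically as the minimum-norm least-squares solution `Wo = H⁺ T` against
one-hot targets, via SVD pseudo-inverse with a relative singular-value
cutoff of 1e-10 (hidden matrices are routinely rank-deficient in
genes ≫ samples settings). With as many hidden units as distinct training
samples the network interpolates the training set exactly; prediction is the
argmax score with ties resolved to the lowest class index.

Two distinct hidden-size defaults are used deliberately:

- classifier fits (`elm.train`, `kfold_cv_accuracy` when unset):
  `min(n_train, 50)`;
- sensitivity profiling (`gcs_profile` when unset):
  `max(2, min(20, n_train // 2))`.

The profiling default is smaller because an interpolating hidden layer makes
`H` square and near-singular, the pseudo-inverse output weights explode, and
the resulting derivatives are dominated by rectified random-projection noise
rather than class structure; at roughly half the sample count the fitted
surface is smooth enough that sensitivities track the planted signal. For
wrapper evaluation on very small subsets the pipeline configuration used in
the shipped studies likewise sets the evaluator to ~n/3 hidden units
(`n_hidden: 10` at 30 samples/class), since an interpolating evaluator
systematically underestimates the accuracy of good small subsets.

## Gene-to-class sensitivity (GCS)

For a trained network the derivative of output `j` with respect to input `i`
at a sample is `Σ_k wo_kj · h_k(1−h_k) · wh_ki`. `S_ij` is the mean absolute
derivative over training samples. Because a single random hidden layer gives
a noisy estimate, `S` is averaged over repeated independently-seeded ELM
trainings — 50 by default, the point where the profile is stable in our
variance checks. The per-gene score collapses classes by the mean over
outputs and is normalized to mean 1 over the profiled pool:

    GCS(k) = (Σ_j S_kj / N_O) / ( (1/N_gn1) Σ_k' Σ_j S_k'j / N_O )

so GCS = 2 reads "twice the average sensitivity of the pool", independent of
data scale. If every sensitivity is exactly zero (a degenerate all-zero
target), the profile falls back to all-ones.

## Two-level gene pooling

**First level (IIC filter).** Genes are ranked by a multi-class information
index built from per-class means and standard deviations,

    d(g) = Σ_{j<k} |μ_j(g) − μ_k(g)| / (σ_j(g) + σ_k(g)),

summed over unordered class pairs (sample standard deviations, ddof 1).
A pair with zero pooled deviation contributes +∞ when the means differ (a
perfect separator ranks first) and 0 when they agree. The top `pool_size`
genes form the first-level pool; ties break to the lower gene index. The
default is 300, in the conventional 200–400 band for data with thousands of
genes; for small (e.g. synthetic) matrices a proportionally smaller pool is
appropriate and the CLI warns rather than forbids.

**Second level (clustering + GCS filters).** Pooled genes are clustered by
K-means on their standardized training profiles (Lloyd's algorithm,
k-means++ seeding, 10 restarts, 300 iterations max, seeded). The cluster
count can be fixed per dataset, chosen by the elbow rule on the
between-group/total variance ratio (return the last count before the ratio
gain drops below 0.05), or chosen by cross-validation: run a reduced-budget
selection per candidate and keep the count with the best CV accuracy.
Two filters then apply:

1. a cluster is dropped when its maximum GCS is below `theta_c` (default
   0.5) times the best cluster's maximum — the best cluster is always kept;
2. within each kept cluster, genes strictly below the cluster-mean GCS are
   dropped (a constant-GCS cluster keeps everything, so every kept cluster
   contributes at least its top gene).

The survivors form the second-level pool of size N_gn2.

## GCS-biased binary particle swarm

Particles are bit vectors over the second-level pool. Initialization sets
each bit with probability 0.5 and then forces the highest-GCS gene of any
uncovered kept cluster on, so every particle starts with full cluster
coverage. Velocities follow the standard rule

    v ← w(t)·v + c1·r1·(p − x) + c2·r2·(p_g − x),   clamped to ±v_max,

with `c1 = c2 = 1.6`, inertia linearly annealed from 1.2 to 0.4, and
`v_max = 4` (the sigmoid is effectively saturated beyond ±4). The position
update encodes gene importance: each velocity component is modulated by the
relative GCS factor `f_j = GCS(j)·N_gn2 / Σ_k GCS(k)` — multiplied by `f_j`
when the velocity pushes toward selection (v ≥ 0), divided by it when it
pushes away — then with probability `a = 0.5` the bit is resampled as 1 with
probability `σ(v′)`, and otherwise copied from the particle's own best or
the global best with equal probability. The sign-aware modulation makes the
probability of switching a bit on non-decreasing in GCS at fixed dynamics
and reduces exactly to the unmodulated rule when GCS is uniform; a plain
multiplicative modulation would invert the bias wherever the velocity is
negative. An all-zero position is repaired by switching on the highest-GCS
gene.

Fitness of a subset is

    w_acc · CVacc(x) − w_size · |x| / N_gn2

with `w_acc = 1`, `w_size = 0.1`: strictly increasing in 5-fold stratified
cross-validated ELM accuracy at fixed size, strictly decreasing in size at
fixed accuracy, and calibrated so dropping one gene can never outweigh one
misclassified CV sample on pools of ≥ 10 genes. Identical subsets are
memoized (fitness is deterministic given the CV seed). Default budgets are
swarm size 50 and 40 iterations; an optional fitness threshold can stop
early but is disabled by default. All randomness comes from counter-style
streams keyed by (master seed, iteration, particle), so runs are
reproducible and independent of evaluation order.

## Pipeline, frequency analysis, reproducibility

`run_pipeline` chains split → standardize → IIC pool → GCS profile →
K-means → cluster/gene filters → swarm, derives each stage's seed from the
master seed, and writes every intermediate table plus a JSON manifest that
reproduces the run bit-for-bit. Gene sets shrink monotonically across
stages.

`frequency_analysis` re-runs only the swarm (fresh swarm and CV seeds per
run) over one fixed second-level pool and counts how often each pooled gene
appears in the returned subset; genes are ranked by that frequency (ties to
pool order). Two analyses with different selection seeds are independent
repetitions over the same pool; their agreement is summarized by the
Spearman rank correlation of the frequency vectors (average ranks for
ties).

## Synthetic data and what it does not show

The generator plants three gene populations: informative genes, each
assigned one "up" class round-robin with mean shift `effect_size · noise_sd`
there and 0 elsewhere; redundant genes that are a source informative gene
plus independent Gaussian copy noise (correlated probes that co-cluster);
and pure-noise genes. Defaults: two classes of 30 samples, 5 informative
genes at effect size 3, 5 copies each (copy noise sd 0.3), 250 noise genes,
unit noise sd. Per-class counts may be unbalanced. The generator does not
model probe-level effects, batch effects, or heavy-tailed noise, so passing
tests demonstrate the machinery recovers planted structure — not performance
on real microarrays.

One structural property of this construction is worth stating plainly: with
two classes, every informative group carries the same class contrast, so
groups are mutually redundant for classification. Small subsets drawn from
two or three distinct groups already reach CV accuracy 1.0 at these sample
sizes, and the size-penalized fitness then prefers dropping further groups.
The selector therefore typically returns 2–3 genes from 2–3 different
groups — redundancy within groups is collapsed, but full coverage of all
planted groups is not an optimum of the stated objective and is not
observed.

## Study configurations shipped with the package

Tests and the acceptance script run the planted construction with a
proportionate first-level pool (40 of 280 genes, matching the 3–15% of genes
that a 200–400 pool represents on real data), a fixed cluster count of 6
(5 planted groups + 1 noise blob; the cluster count is a per-dataset
configuration in this method), a 10-hidden-unit evaluator, and the default
swarm budgets. Frequency analyses use 50 runs — enough for a stable ranking
check at desk scale; larger counts simply shrink the binomial noise.

## Known limitations

- Sensitivities and the IIC both assume roughly Gaussian within-class
  expression; heavy-tailed data should be transformed first.
- The wrapper stage can overfit the CV estimate at very small sample sizes
  (dozens of samples): an occasional noise gene rides along in the selected
  subset because it fixes the last one or two CV predictions by chance.
- Exact reproducibility requires the same BLAS/library stack; the package
  fixes all seeds but floating-point reduction order is library-dependent.
- Rank correlations between repeated frequency analyses fluctuate around
  their expectation at 50 runs; stable gene rankings need hundreds of runs.
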