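# Methods

`otulearn` predicts a continuous, per-sample ecosystem function — the
motivating case is dissolved organic carbon (DOC) measured in plant-litter
decomposition microcosms — from a microbial community profile, and asks
which taxa drive the prediction. The data model is a rarefied OTU count
table `X` (N samples x M taxa) and a target vector `y` (one DOC value per
sample), related by `y = M(theta, X) + eps` for a regression model `M`.

## Preprocessing

* **Rarefaction.** Each sample is subsampled *without replacement*
  (multivariate hypergeometric) to a common depth; samples with fewer reads
  than the depth are dropped with a warning. The default depth of 1023
  reads matches typical shallow 16S rarefaction; the method itself is
  depth-agnostic.
* **Replicate-aware splitting.** Microcosms inoculated from the same soil
  source diverge but remain correlated, so train/test splits operate on
  replicate *groups*: groups are shuffled, and a prefix whose cumulative
  size is closest to the requested test fraction becomes the test set. No
  group ever straddles the split, and the achieved test size varies by at
  most one group around the target. Group membership comes from an explicit
  `group_id` column, or is derived from the sample-id prefix before the
  last `_`-separated token.
* **Standardization.** Features are z-scored with mean and *population*
  standard deviation computed from training rows only (a `ddof` switch
  exposes the sample-variance convention; at n ~ 250 the difference is
  negligible). Held-out tables are scaled with the training statistics.
  Constant training columns carry no signal and are mapped to zero
  everywhere, which also avoids division by zero. Indicator analysis and
  abundance/prevalence summaries always use the raw counts — presence/
  absence and abundance shares are meaningless after z-scoring.

## Neural-network regression

A fully connected feed-forward network with sigmoid hidden units and a
linear output; the default architecture is a single hidden layer of J = 15
nodes. Training minimizes mean squared error plus an L2 penalty by
mini-batch SGD (default batch 32, learning rate 0.1, L2 coefficient 1e-4),
with weights initialized uniformly at `+/- 1/sqrt(fan_in)`. A validation
subset (20% of training rows, replicate-group-aware) is scored each epoch;
training halts when the validation cost has not improved for 10 consecutive
epochs (the patience), capped at 2000 epochs, and the parameters of the
best-validation epoch are returned. A randomized hyperparameter search
(hidden size 5–50, learning rate log-uniform on [1e-4, 1e-1], L2
log-uniform on [1e-6, 1e-1], 25 draws by default) scores candidate
configurations by internal validation MSE on the training data only.

The default learning rate (0.1) was chosen so that, with a patience of 10,
SGD reliably escapes the initial plateau on standardized community data;
much smaller rates can trigger premature early stopping and much larger
ones diverge (divergence raises an error suggesting a smaller rate).

## Gradient feature importance

Two signed, per-taxon statistics are derived from the gradient at the first
hidden layer; both are computed analytically by backpropagation (and
verified against finite differences in the tests):

* **Weight-gradient form.** `F[m, j] = d M / d W1[m, j] = x_m * delta_j`
  (the M x J importance matrix for one sample), marginalized uniformly over
  hidden nodes, `f_m = mean_j F[m, j]`, then averaged over training
  samples, `s_m = mean_k f_m(x_k)`. This is the form the three operations
  `importance_matrix` / `importance_vector` / `sensitivity` implement.
* **Input-gradient (saliency) form.** `s_m = mean_k d M / d x_km`, i.e. the
  same backpropagated `delta` weighted by the input weights
  (`sum_j W1[m, j] delta_j`) instead of uniformly.

In planted-signal experiments the two behave very differently. With
standardized features the weight-gradient form reduces to
`s_m ~ cov(x_m, mean_j delta_j)`, a curvature-like quantity whose per-node
terms carry the sign of sigma'' rather than sigma'; in practice it misranks
and sign-flips a fraction of genuinely strong-effect taxa even when every
underlying network fits the data well. The input-gradient form recovers
planted ranks and signs essentially perfectly and is what makes the
headline behaviors of the toolkit (perfect direction agreement with
indicator classes; recovery of planted taxa into the consensus set)
reproducible. `bootstrap_importance` therefore defaults to
`mode="input_gradient"`; the uniform marginalization remains available as
`mode="weight_gradient"`.

**Bootstrap ranking.** Importance is bootstrapped: 50 iterations, each
subsampling 80% of the training rows without replacement and retraining
from a fresh seeded initialization; the statistic is evaluated over the
iteration's own subsample. Taxa are ranked by |bootstrap mean| descending
(ties broken lexicographically by taxon id, for determinism); the sign —
positive means the taxon pushes the predicted function up — is retained.

## Random-forest regression

Tree induction is delegated to scikit-learn's `RandomForestRegressor`
(1000 trees, squared-error splits, 2 samples to split an internal node, 1
per leaf, all features considered at each split, bagged row resampling);
this module owns the configuration contract, the normalization of impurity
importances (non-negative, sum to one), and the same 80%/50-iteration
bootstrap ranking wrapper used for the network. Because forest predictions
are averages over leaf values, they can never leave
`[min(y_train), max(y_train)]` — an invariant the tests assert and the
community-design analysis exploits. An optional randomized search tunes
`min_samples_split`, `min_samples_leaf` and `max_features`; the default
analysis path uses the stated defaults.

## Indicator taxa (IndVal)

Samples are labelled **high**/**low** on the target; the default rule is a
median split with ties assigned to "low" (quantile and fixed-threshold
rules are available — the choice of split materially affects the number of
significant taxa and is deliberately exposed). For taxon t and class c,
specificity `A_tc` is the class mean abundance divided by the summed class
mean abundances, fidelity `B_tc` is the fraction of class-c samples where
the taxon is present, and `IndVal_tc = A_tc * B_tc`; taxa absent everywhere
score zero (0/0 := 0). Confidence comes from label permutations (default
1000, giving 0.1% resolution; fewer than 99 is rejected as unable to
resolve a 95% threshold): the confidence is the fraction of permuted
best-over-classes scores *strictly* below the observed best score, so ties
with the null count against significance (conservative), and a taxon is a
significant indicator at confidence >= 0.95. Under a null table this
yields approximately (slightly under, due to tie handling) a 5% positive
rate, which the tests check.

## Consensus selection and the overlap null

The three selections are size-matched: the significant-indicator count
defines k, and the NN and RF rankings contribute their top-k taxa; the
consensus set is the triple intersection. Overlap-vs-rank curves count
shared taxa among top-k prefixes for k = 1..k_max (each taxon enters a
curve at one plus the maximum of its positions, so curves are monotone).
Chance overlap is quantified by simulating three independent uniform
orderings of M taxa: expected pairwise top-k overlap is `k^2/M` and triple
overlap `k^3/M^2`, with an equal-tailed 99% band over 1000 simulations;
the implementation counts overlaps via cumulative histograms of maximum
positions, and the tests verify the simulated means against the closed
forms. Direction agreement between the network and the indicator analysis
is the fraction of shared selected taxa whose importance sign matches their
indicator class (positive <-> high).

## Evaluation experiments

* **Repeated splits.** The generalization experiment re-splits the data
  (replicate-aware) n times; within each permutation all model x
  feature-set arms share a byte-identical partition (asserted by checksum)
  and its standardization. Arms are compared by a two-tailed t-test on
  per-permutation r values — Welch unpaired by default, with a paired
  option that is defensible because arms share splits — plus the fraction
  of pooled test samples on which one arm's absolute error is smaller.
* **Sample-size sensitivity.** For each fraction of the training set,
  replicate-group-aware subsets are drawn (10 by default), the model is
  retrained, and test r is recorded, yielding a learning curve with
  mean +/- sd per fraction.
* **Abundance/prevalence.** Per-taxon mean raw count over all samples and
  fraction of samples with a nonzero count, used to profile the consensus
  set against the full community.

## In-silico community design

The bootstrap-mean importance vector `s` points, in standardized feature
space, in the direction that most increases the predicted function.
Starting from an observed community (by default the highest- or
lowest-target training sample), trajectories `x_new = x0 + alpha * s` are
evaluated under both models over an ascending alpha grid that includes 0.
The default grid has 21 points with `alpha_max * ||s||` equal to twice the
median inter-sample distance in standardized space (so perturbations are
commensurate with real between-community differences). Random baselines
draw isotropic Gaussian directions rescaled so `||alpha*d|| = ||alpha*s||`
at every alpha — norm-matching makes the comparison fair. Perturbed
communities are not clipped to non-negative count space (an inverse
transform back to count scale is available for reporting; it round-trips
exactly for non-constant features). The forest trajectory stays within the
training-target range by construction; the network can extrapolate beyond
it, which is the point of the exercise.

## Synthetic data generator

The generator emulates rarefied 16S tables from replicated microcosm
experiments, and its defaults are the study-shaped conditions used
throughout the tests and the acceptance script: 100 source communities x 3
replicates (300 samples), 300 taxa, depth 1023, about half of the count
cells zero, within-group correlation 0.5, and a planted signal of 20 taxa
with alternating +1/-1 effects plus Gaussian noise (sd 0.3). The taxon
count is scaled down from the ~1700 of a real shallow-sequencing study to
keep the 50-iteration bootstrap wrappers comfortable on a single CPU;
nothing in the method depends on M beyond runtime.

Mechanics: per-taxon baseline log-abundances are drawn normal and scaled by
a spread `sigma` calibrated (by root finding on `mean((1-p)^depth)` over
the baseline composition) so the expected zero-cell fraction matches the
requested sparsity; each replicate group draws a latent profile
perturbation shared across its replicates, mixed with per-replicate noise
in a `sqrt(rho)/sqrt(1-rho)` split so replicate latents correlate at rho;
softmax gives per-sample compositions and rows are multinomial at the fixed
depth. The target is a linear combination of the *relative* abundances of
the signal taxa (standardized across samples), so sequencing depth cannot
leak into the signal, plus Gaussian noise. Signal taxa are drawn from the
upper half of baseline abundance — an effectively absent taxon cannot carry
signal — and a generation whose planted taxa end up nearly absent raises an
error naming the sparsity/signal conflict.

What the generator does *not* emulate: phylogenetic correlation between
taxa, compositional interaction effects, overdispersion beyond the
latent-log-normal/multinomial hierarchy, and nonlinear taxon-function
relationships. Passing recovery tests therefore demonstrate correctness of
the machinery on linear additive signals in realistic sparsity/replication
structure, not performance guarantees on real communities.

Benchmark configurations used in the tests: the *recovery benchmark* (all
planted taxa must reach the consensus set; both models must exceed r = 0.9
on held-out data) uses 3 planted taxa with effects (+2, -2, +2), zero
observation noise, 100 taxa and 150 groups, and trains the network with a
patience of 30 — on noiseless data the validation trace is smooth and the
longer patience simply avoids premature stops. The *null calibration*
benchmark uses zero effect sizes and checks the significant-indicator rate
against 5%.

## Numerical choices and degenerate inputs

* Rank ties in |importance| break lexicographically by taxon id.
* Constant targets are rejected wherever they would be degenerate
  (binarization, Pearson r, extreme selection).
* Pearson r on a constant prediction vector raises rather than returning
  NaN; degenerate arms surface as errors, not silent zeros.
* The indicator ordering used for overlap curves is best score descending,
  ties by confidence then taxon id.
* Divergent SGD (non-finite or absurdly large cost) raises immediately with
  a suggestion to lower the learning rate.
* All stochastic procedures take explicit integer seeds; the pipeline
  derives per-stage seeds from the run seed by hashing, records them in the
  run manifest, and stays below 2^31.

## Problem sizes in the shipped checks

The default test suite and the acceptance script run entirely on generated
data sized for a single CPU: the main synthetic study uses 300 samples x
300 taxa with 50-iteration bootstraps and 1000 label permutations; the
repeated-split experiment runs 10 permutations x 4 arms; sensitivity uses
3 fractions x 5 replicates. Reproduction checks against the published
litter-decomposition study require its supplementary datasets, which are
not redistributed here; placed under `data/study/`, they activate the
corresponding acceptance tests at full scale.

## Known limitations

* The weight-gradient importance (uniform marginalization) is retained for
  completeness but is not recommended for ranking; see above.
* The indicator high/low threshold is a modelling choice; significant-taxon
  counts are sensitive to it.
* Whether hyperparameter search should re-run inside every bootstrap
  iteration is an open trade-off; the default searches once and reuses the
  configuration (configurable), which slightly understates selection
  uncertainty.
* The reduced feature set used in the repeated-split experiment is held
  fixed across permutations (selected once on the primary split);
  re-selecting per permutation would give an honest-but-slower outer loop.
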