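# Methods

## The model

`repdim` asks how many latent feature dimensions underlie the activity
patterns a neural population produces across `K` experimental conditions.
The generative model assumes each condition `k` has a feature vector
`f_k ∈ R^D`, each feature dimension `d` has a spatial pattern component
`u_d ∈ R^P` (one entry per voxel / neuron / electrode), and a measured
trial pattern is

    y_{k,n} = Σ_d u_d f_k^(d) + ε_{k,n},

with `ε` iid Gaussian noise.  `D` — the number of pattern components needed
to describe the condition means — is the dimensionality of the
representation.  A region that merely scales one activity pattern with a
single latent variable (e.g. effort) has `D = 1`; a region that assigns
every condition its own independent pattern has the full `D = K − 1`.

## The estimator

Because estimated between-class covariance matrices always have `K − 1`
non-zero eigenvalues under noise, `D` cannot be read off a spectrum.
Instead a family of Gaussian linear classifiers is compared by
leave-one-run-out cross-validation:

1. On the training runs, estimate class means `μ̂_k` and the pooled
   within-class covariance `Σ̂_W` (scatter divided by `Σ_k (N_k − 1)`),
   regularized by adding 1% of the mean diagonal element to the diagonal.
2. Pre-whiten with the symmetric inverse square root `Σ̂_W^(−1/2)`
   (symmetric eigendecomposition; eigenvalues below `1e−10 ×` the mean
   eigenvalue are clipped to that floor).
3. Form the between-class covariance of the whitened means,
   `Σ̂_B* = (1/K) Σ_k (μ*_k − μ̄*)(μ*_k − μ̄*)^T`; its eigenvectors, ordered
   by decreasing eigenvalue, are the discriminative directions.
4. The `d`-dimensional classifier projects whitened patterns and means onto
   the top-`d` eigenvectors and assigns the class with the largest linear
   discriminant `g_k(y) = h_k y − ½ h_k μ̂_k`; in whitened coordinates this
   is the nearest projected class mean.  At `d = K − 1` it reproduces the
   full Gaussian linear classifier (LDA) exactly.

The cross-validated accuracy as a function of `d` (the *accuracy curve*)
peaks at the true dimensionality given enough data: smaller `d` discards
discriminative signal, larger `d` over-fits noise in the estimated
directions.  `argmax_d` with ties resolved to the smallest `d` is the
dimensionality estimate.

Numerical conventions (all deterministic): classification ties go to the
lowest class label; eigenvectors are flipped so their largest-magnitude
component is positive; eigenvalues tied within a relative 1e−9 are ordered
by the axis index of the eigenvector's largest component; an identically
zero within-class scatter receives an absolute diagonal floor of 1e−8 with
a warning.  Accuracies are stored as exact counts out of the pooled test
trials, so "equal accuracy" means equal counts and the matching tolerance
(half the resolution `1/n_test`) is well defined.

## Feature-space projection and alignment

Condition means are visualized by `f̂_k = W^(d)T Σ̂_W^(−1/2) μ̂_k`.  In this
space Euclidean distances among the projected means equal Mahalanobis
distances among the original means, and the per-dimension variance of the
projected means (with `1/K` normalization) equals the eigenvalues of
`Σ̂_B*`.  Because eigenvector sign and any rotation within tied eigenvalues
are arbitrary, configurations from different subjects are compared after
similarity alignment (translation, isotropic scale, rotation *with
reflections allowed*): ordinary Procrustes for a pair, and generalized
Procrustes (iterative alignment to a unit-norm consensus, initialized from
the first configuration, tolerance 1e−9, at most 100 iterations) for a
group.  Per-condition covariances of the aligned coordinates summarize
between-subject dispersion.

## The simulator

`simulate` draws `u_d ~ N(0, σ_a² I_P)` and `ε ~ N(0, I_P)`; with noise
variance fixed at 1, `σ_a²` is the signal-to-noise ratio.  Defaults mirror
a typical fMRI design: `K = 4` conditions, one pattern estimate per
condition per run (a GLM beta), `M = 8` runs, and `P = 80` units for
sweep-style runs (80 is also the subspace size used throughout); regions of
interest for the subspace experiments use `P = 400`.  The simulator does
*not* model spatial covariance among units, temporal autocorrelation, or
run-to-run mean shifts; passing tests therefore demonstrate correctness of
the estimator under iid-unit Gaussian conditions, not robustness to the
spatial structure of real fMRI noise (see "Known limitations").

Feature spacings:

* `random` — rows of `F` iid standard normal.  Four conditions placed at
  random in 3-D are nearly coplanar on average, which is why higher
  dimensions carry little variance.
* `even` — the `K × K` indicator matrix is row-centered (giving `1 − 1/K`
  on the diagonal, `−1/K` elsewhere) and its rows are projected onto `D` of
  its equal-eigenvalue eigenvectors.  This guarantees every feature
  dimension carries identical between-condition variance (an exactly flat
  spectrum) for any `D ≤ K − 1`; at `D = K − 1` the conditions form a
  regular simplex.  For `D < K − 1` the conditions are *not* equidistant —
  equidistance is geometrically impossible there — and some conditions can
  coincide along individual dimensions.
* recruitment — condition `k` activates the first `c_k` units at a fixed
  amplitude (`c_1 < … < c_K`, default equal steps up to `P`).  Although
  driven by one physical variable, this coding yields a full-rank
  between-class spectrum, which is what makes it empirically testable
  against graded-intensity coding.

### True spectra

`true_eigen_spectrum` reports the large-`P` limit eigenvalues of the
between-class covariance implied by the feature vectors, normalized per
draw by the largest eigenvalue.  The features are centered at the *true*
mean of their generating distribution (the origin) rather than the sample
mean of the `K` draws; the Monte-Carlo means for `K = 4` are then
`[1, 0.29, 0]` for 2-D and `[1, 0.39, 0.09]` for 3-D random placements.
(Sample-mean centering — which the estimator itself uses, as it must —
would give `[1, 0.23, 0]` and `[1, 0.33, 0.045]`.)

### Signal-variance sweep

Monte-Carlo experiments vary `σ_a²` over a uniform grid from 0 up to "the
level where classification becomes perfect".  That level is defined as the
smallest `σ_a²` at which at least 5% of pilot simulations are classified
perfectly by the full classifier (60 pilot runs per probe; doubling search
plus bisection).  The mean accuracy is deliberately *not* used: with random
feature placement there are always draws whose conditions nearly coincide,
so the mean approaches 1 only at extreme signal variances and a sweep
calibrated that way would consist almost entirely of saturated runs (where
all classifiers tie at 100% and the tie rule, not the data, decides).  At
the default sizes the calibrated tops are roughly `σ_a² ≈ 0.9` for 1-D,
`0.15` for 2-D and `0.09` for 3-D random feature spaces; identification
runs cycle deterministically through 21 grid levels.

### Matching and the random-subspace experiment

To compare an observed curve with simulation, library runs whose
full-classifier accuracy matches the observation within half the accuracy
resolution are averaged (the tolerance doubles, with a warning, if no run
matches).  The region-of-interest experiment generates 400-unit datasets
with true `D ∈ {1, 2, 3}`, calibrating `σ_a²` per `D` (bisection on pilot
mean accuracy) so the 400-unit full classifier averages ≈ 0.70 regardless
of `D`, then scores each dataset by the full-region accuracy curve and by
the curve averaged over random 80-unit subsets (sampled without
replacement within a draw, independently across draws).

Problem sizes used by `scripts/acceptance.py`: 10,000 spectrum draws;
5,000 sweep runs for the 1-D identification and 2,500 each for 2-D/3-D;
90 regions per dimensionality with 100 subspace draws each.  The subspace
identification rate was checked to be flat in the number of draws beyond
~50, so draw count far below the 2,000 used historically does not bias the
rate; the dataset count dominates the Monte-Carlo error (≈ 3 percentage
points at 270 regions).

## Unit selection

Per-unit informativeness is the one-way across-condition ANOVA F statistic.
Selecting the top fraction on the *whole* dataset before cross-validation
(`select_biased`, opt-in, loudly warned) is statistically invalid: among
the selected units many owe their score to noise, and since such units
separate conditions along random, mutually different directions, the
selected region mimics a full-dimensional representation whatever the
truth — on pure noise it even yields above-chance "accuracy".  The valid
variant (`select_nested`) recomputes scores inside each cross-validation
fold on the training runs only; it leaves chance-level data at chance and
preserves the location of the accuracy-curve peak.  Score ties are broken
by unit index; units with zero within-condition variance but distinct
means get `+inf` and rank first, with a warning.

## Design choices that were genuinely open

* Multiple trials per condition per run are classified individually, not
  averaged, matching the one-estimate-per-run structure of GLM betas.
* The even-spacing eigenvector basis is whatever the symmetric
  eigendecomposition returns under the canonical tie/sign rules; any
  orthonormal basis of the space orthogonal to the all-ones vector is
  equally valid, and none makes `D < K − 1` conditions equidistant.
* Group Procrustes aligns to a consensus rather than to a designated
  reference subject.
* Per-draw spectrum normalization (divide by that draw's largest
  eigenvalue, then average across draws).
* Library matching uses ± half the accuracy resolution as its tolerance so
  that "same accuracy" is exact on the count scale.

## Known limitations

* No spatial covariance among units; real fMRI voxels are smoothed and
  vascularly correlated, which changes how much signal a random subset of
  a region retains.  Under iid units an 80-of-400 subset carries exactly
  1/5 of the squared Mahalanobis signal, so the subspace classifier's
  absolute accuracy drops more steeply here than it would on spatially
  correlated data; the identification-rate comparisons are robust to this,
  the absolute subset accuracy is not.
* The sweep calibration's 5%-perfect-runs threshold is an
  operationalization; identification fractions shift by a few percentage
  points if the sweep top moves by a factor of ~2 in either direction.
* Accuracy ties at the resolution of the test-trial count bias the
  arg-max estimate toward small `d` near ceiling; use more runs or trials
  per run when the expected accuracy is high.
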