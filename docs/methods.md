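# Methods

## The normalization model

All three normalizations are instances of one scheme: per group *j*
(default grouping strain × stage × stimulus; technical-repeat trials are
pooled, and batch is never a grouping factor because it is the predictor
of the batch model), fit a linear model `y_ij = x_ijᵀ β_j + ε_ij` to the
observed activity and keep the residuals, shifted by a non-negative offset.
The observation unit is one larva × second of Burst Duration inside the
configured fitting window (the full −30…30 s trace by default). Per-second
sampling is the default because the output must remain a per-second time
series and the subtracted quantity is constant along each larva's trace
either way; `fit_on="larva_mean"` switches to one per-larva mean
observation for users who prefer the coarser unit.

**Light.** `activity ~ β0 + β1·intensity`, OLS per group, intensity joined
from the larva's well. Standard errors and two-sided p-values use the t
distribution with n − 2 degrees of freedom. A group whose wells all share
one intensity leaves the slope unidentifiable: the standalone estimator
refuses (`DegeneratePredictorError`) rather than silently fitting, while
the integrated chain falls back to an intercept-only fit with slope 0 —
there a constant light map makes the step vacuous, and the refusal would
block the two remaining, still-meaningful steps.

**Batch.** One-way layout under sum-to-zero (effects) coding. The model is
saturated, so the fitted value for an observation is its batch's sample
mean; the intercept is therefore the *unweighted* mean of batch means and
each effect is (batch mean − intercept). With unequal batch sizes a
weighted alternative exists (intercept = pooled grand mean); the
unweighted convention is used because the estimand of interest is the
deviation of each replicate from a typical replicate, not from the pooled
observation mean. The zero-sum identity is enforced exactly against float
drift. Standard errors come from the pooled residual variance with N − K
degrees of freedom; the last level's SE uses the contrast −Σ others.

**Baseline.** Intercept-only model on the baseline window (default the
last 30 pre-change seconds, t ∈ [−29, 0]): factor = group baseline mean −
target, subtracted from the whole trace. The target defaults to the grand
mean of all baseline records across groups, weighted by group size (it is
a plain mean over records). The step is a per-group constant shift, so it
changes within-group variance by exactly zero and leaves every group's
baseline mean at target + offset — both asserted to 1e-12 in the tests as
exact arithmetic properties.

**Offset.** Residuals can be negative; activity cannot. A fixed offset
(default 0.06) or an auto-resolved one is added after subtraction. The
auto rule requires μ ≥ |min over all records of the pre-offset normalized
value| whenever that minimum is negative (else μ = 0), rounded *up* to 4
decimal places for reporting stability — the bound is on the residuals,
not on the fitted values, because non-negativity of the output is the
point of the offset. Estimators resolve the auto offset at fit time from
the training table (scikit-learn semantics: statistics are learned in
`fit`), so `transform` on new data reuses the resolved value.

**Integration.** light → batch → baseline, each step fitted on the
previous step's residuals. Steps 1–2 use zero offset (negative
intermediate values are expected and permitted); the single offset is
applied at step 3. The chain's default baseline target is computed from
the *raw* input table, so the normalized traces sit at the familiar raw
activity level (baseline ≈ raw grand mean + 0.06) rather than at the
residual scale; any explicit target overrides this. No clipping is ever
applied; raw tables are validated to [0, 1], normalized tables only to
being finite (and ≥ 0 after the offset when auto mode is used).

## Hotelling's T²

The multivariate unit is one larva × trial (configurable to per-larva
trial means): its vector of per-second activities over a short window.
T² = (n_a n_b/(n_a+n_b)) d̄ᵀ S⁻¹ d̄ with the pooled unbiased covariance;
the p-value uses the exact-under-normality F transform with (p,
n_a+n_b−p−1) degrees of freedom, not the chi-square limit. Larvae missing
any second of the window are excluded and counted in the result. Singular
or ill-conditioned (cond > 1e12) pooled covariances raise with advice to
shorten the window — no silent regularization, since the intended windows
are short (p = 3) relative to typical group sizes. Reported p-values can
underflow to 0.0 in double precision for very large statistics; a printed
0 means "below ~5e-324", not literally zero.

## Evaluation embeddings

Each larva contributes its window trace (default t ∈ {−1…3}, i.e. two
pre-change and three post-change one-second bins under the convention that
the light change falls between t = 0 and t = 1; a config option widens to
{−2…3}), trials averaged. PCA runs on the column-centered, un-scaled
matrix — all columns share Burst Duration units — and reports
variance-explained fractions from the covariance eigenvalues; percent
variance is rounded to 2 decimals in CSV output. t-SNE delegates to
scikit-learn's implementation with `init="pca"`, a fixed `random_state`
and one worker thread; only determinism-given-seed, the perplexity bound
(perplexity < (n−1)/3) and parameter pass-through are contractual, because
t-SNE geometry is not reproducible across implementations. The
cluster-separation statistic used by the tests (mean between-centroid
distance over mean within-cluster spread) is a test-side diagnostic, not
part of the library surface.

## Synthetic data generator

Per larva × second the noiseless mean is

    baseline_g + slope·I_well + shift_batch + peak_g·exp(−decay_g·(t−1))·1[t ≥ 1]

to which Gaussian noise is added; the sum is clamped to [0, 1] and then
zeroed with probability `zero_inflation`. Defaults follow the magnitudes
of real recordings: baselines 0.008–0.015, slope −2×10⁻⁴ per W/m², batch
shifts ±1.6×10⁻³, a radial light map falling linearly with distance from
the plate centre from 30 to 20 W/m², three developmental stages of one
wild-type strain whose response peaks (0.05 / 0.25 / 0.15 at t = 1)
reproduce the qualitative ordering seen in such assays (6 dpf strongest,
3 dpf barely responding), two batches of 48 larvae per group, 61 seconds
around the light change.

Design choices worth noting:

- **Shared plate layout.** All plates (every group × batch) use one
  randomly drawn well-loading pattern, as real experiments fill plates in
  a fixed layout. This keeps batch and group exactly balanced over the
  light gradient, so the generating slope and the centred batch shifts are
  the exact estimands of the fitted models — which is what makes "estimate
  within 3 SE of truth" a calibrated recovery check rather than one biased
  by plate-to-plate intensity imbalance.
- **Default noise sd 5×10⁻⁴, zero-inflation 0.** Under these conditions
  the mean surface stays ≥ ~2.4×10⁻³ (≈ 4.8 σ from the clamp), so the
  linear models are exactly the generating process and recovery tests are
  sharp. Real recordings are harsher — heavier-tailed, strongly
  zero-inflated when larvae sit still — and clamping plus zero-inflation
  are multiplicative distortions a linear model does not undo. Both are
  implemented and exercised (a binomial check of the zero fraction, a
  bounds check under large noise), but they are off in the default
  conditions; consequently, passing recovery tests demonstrate correctness
  of the estimators under the model's own assumptions, not robustness to
  real-data noise.
- The exponential response shape is cosmetic: it gives the traces a
  realistic profile, but only the linear structure (slope, shifts,
  baselines) matters to what the normalization removes, and the time
  profile is orthogonal to all three predictors by design.
- `SimTruth` records clamp and zero counts plus the full noiseless mean
  surface, so tests can verify they are in an unclamped regime before
  asserting recovery.

## Problem sizes and numerics

The test suite and the acceptance script use the default design (17 568
records, 288 larvae) for pipeline checks, 200 replications of a one-group
96-larvae × 60 s design for parameter recovery, and 2000 null replications
(p = 3, 48 + 48) for Hotelling calibration; the whole suite runs in well
under a minute on one core. Exact contracts (residual means, zero-sum
effects, baseline shifts) are asserted at 1e-10–1e-12 absolute; OLS
results are cross-checked against closed-form normal equations at 1e-8,
T² against a brute-force 2×2-inverse oracle at 1e-10 and against an
independent implementation (pingouin) at 1e-9. Ties and degenerate inputs
fail loudly: constant predictors, singular covariances, groups missing
from the baseline window and malformed well addresses all raise with the
offending group or token named.

## Known limitations

- The linear models address additive effects only; multiplicative or
  activity-dependent distortions (and the zero-inflation of real data)
  are outside their reach, as are generalized-linear, nonparametric or
  time-series extensions.
- Light-On and Light-Off periods are normalized separately (stimulus is
  part of the default grouping) and treated symmetrically around their
  respective light change; the package takes no position on whether joint
  normalization would be preferable.
- The auto offset guarantees non-negativity only on the table it was
  resolved on; transforming new data with a previously fitted estimator
  can in principle go negative, which is reported, not clipped.
- T² assumes multivariate normality and equal group covariances; with
  per-second bounded activities this is an approximation that improves
  after normalization and with larger groups.
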