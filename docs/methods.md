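# Methods

## The model

`regsyn` trains a generator for mixed-type tabular cohorts as a
reinforcement-learning policy. A shared-trunk multi-layer perceptron maps a
standard-normal noise vector to per-feature distribution parameters:
Normal(μ, σ²) heads for continuous features (mean plus clamped
log-variance), Bernoulli heads for binary features, and softmax categorical
heads. Sampling from the heads yields a synthetic row together with its
exact log-probability, so the generator is a proper stochastic policy and a
generated row is a single-step episode.

A discriminator MLP scores one-hot-encoded, normalized rows with a logit
D(x); its realism score σ(D(x)) ∈ (0, 1) is the base reward. The
discriminator trains with binary cross-entropy (real = 1, synthetic = 0)
plus the R1 gradient penalty (γ/2)·E_real‖∇ₓD‖², evaluated on real rows
only. Because the generator consumes only scalar scores — never
discriminator gradients — any computable reward can be added without
architectural changes.

The regression-aligned reward exploits exactly that. Before training, a
reference regression f is fitted once on the real training data (logistic
for a binary outcome, OLS for a continuous one; categoricals
reference-coded with the first declared category dropped). Each generated
row x is penalized by

    R_reg(x) = −(q(x) − f(x))²,

where q(x) is the generator's *pre-sampling* conditional outcome: the
outcome head's Bernoulli probability, or the Gaussian outcome head's mean
μ_θ(x) for continuous outcomes. The total per-sample reward at iteration t
is

    r = σ(D(x)) + λ_t · R_reg(x),

with λ_t ramping linearly from 0 at a start iteration t′ to its full
weight λ over a configurable ramp length.

The rationale is a probability-matching argument. The logistic MLE on real
data satisfies the score equation E[(y − f(x)) x̃] = 0 with x̃ = (1, xᵀ)ᵀ.
If the synthetic covariates are non-degenerate (full-rank design,
Condition 1) and the generator's conditional outcome matches the reference
prediction, q(x) = f(x) (Condition 2), then the same score equation holds
under the synthetic distribution, so the strictly convex synthetic
log-likelihood has its unique optimum at exactly the real-data
coefficients — a regression refit on synthetic data recovers (β₀*, β*).
The identical first-order argument covers OLS with q = μ_θ(x). Both
recovery properties are exercised directly in the test suite by drawing
outcomes from a fitted f on fresh full-rank covariates and refitting.

## Training loop

Per iteration: sample a batch of rows and their log-probabilities; score
realism; compute the penalty and λ_t; standardize the total reward within
the batch — (r − mean)/(sd + 1e−8) — to get advantages (episodes are
single-step, so no value network or discounting is needed and the batch
mean is the baseline); run K epochs of the clipped PPO surrogate
−E[min(ρA, clip(ρ, 1−ε, 1+ε)A)] with ρ the probability ratio against the
sampling-time policy; then update the discriminator on fresh generator
samples versus a random real minibatch. With λ = 0, or with no reference
supplied, the loop is exactly the base discriminator-only procedure — the
two code paths produce bit-identical trajectories at λ = 0, which is
asserted in the tests.

All networks, backpropagation, the PPO update, Adam, and the R1
double-backprop are implemented directly in numpy (see `nn.py`); for a
piecewise-linear activation the parameter gradient of ‖∇ₓD‖² reduces to
outer products of a backward and a linearized forward pass. Every analytic
gradient is validated against central finite differences in the tests
(R1 to 1e−3 relative, as is appropriate near activation kinks).

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| λ, t′, ramp | 0 / 0 / 1 | penalty weight and linear anneal; λ = 0 disables the reward. The ramp length defaults in experiments to ~10% of total iterations. |
| clip ε | 0.2 | standard PPO clipping range |
| PPO epochs K | 4 | surrogate epochs per batch (2 in the desk-scale experiments) |
| disc:gen ratio | 1 | discriminator updates per generator iteration |
| R1 γ | 1.0 | gradient-penalty weight (units of squared input-gradient norm) |
| batch | 512 | rows per iteration |
| learning rates | 1e−4 | Adam, both networks (3e−4 in the desk-scale experiments) |
| hidden layers | 3 × 256 | shared-trunk MLPs, leaky-ReLU (slope 0.2) |
| noise dim | 128 | standard-normal input |
| log-variance clamp | [−6, 2] | prevents variance collapse/explosion |
| probability clamp | 1e−6 | keeps Bernoulli log-masses finite |
| discrete log-mass floor | −30 | keeps PPO ratios finite at zero-probability values |

The generator operates entirely on the normalized scale (continuous
features standardized to zero mean, unit *population* standard deviation);
denormalization happens only at export. For continuous outcomes, q and f
are therefore compared on the normalized outcome scale, which keeps the
squared-error penalty scale-stable across datasets.

## Reference regression

Logistic fits use Newton/IRLS via statsmodels with the score-equation
residual max|x̃ᵀ(y − p)|/n < 1e−8 as the authoritative optimality check
(the optimizer's own flag can trip on its stricter internal tolerance even
when the MLE is found); perfect separation and rank-deficient designs are
hard errors. OLS is closed form. Fitted standard errors are retained and
drive the 2-standard-error recovery assertions.

## The cohort simulator

The simulator draws covariates from a fully specified distribution —
multivariate-normal continuous block, independent Bernoulli binaries,
independent categoricals — and the outcome from a known logistic or linear
model over the one-hot-encoded covariate row, making coefficient recovery
exactly testable (the reference-coded ground truth is available in closed
form). Two presets fix documented coefficients:

- `icu_like`: 8 standardized vitals/labs with pairwise correlation 0.3,
  3 intervention flags, a 3-level insurance class, and logistic in-hospital
  mortality with marginal prevalence ≈ 14% (Monte-Carlo over 10⁶ draws),
  inside the 5–25% band typical of ICU cohorts.
- `survey_like`: standardized age and schooling, sex and disability flags,
  a 5-level race variable, and a linear assistance amount whose large
  disability effect on a 15% subgroup makes the outcome right-skewed
  (sample skewness ≈ 0.76 at n = 20,000).

What the simulator deliberately does **not** emulate: missingness (missing
cells are a hard error; imputation belongs upstream), cross-block covariate
dependence (blocks are mutually independent so the recovery oracle stays
analytic), heavy-tailed or multimodal continuous marginals, and any
marginal statistics of restricted real cohorts. Passing tests therefore
demonstrate correctness of the machinery and the recovery mechanism under
a well-specified data-generating process, not performance on real clinical
data.

## Evaluation metrics

- **DWD** (dimension-wise difference): absolute prevalence difference for
  binary features; mean absolute per-category prevalence difference for
  categoricals; 1-D Wasserstein-1 for continuous features after min–max
  rescaling over the *pooled* real ∪ synthetic values (this pins every term
  into [0, 1]); unweighted mean over features.
- **CWC** (column-wise correlation difference): mean absolute difference of
  Pearson correlation matrices of the one-hot-encoded tables over the
  off-diagonal upper triangle, so categorical structure contributes.
- **Membership-inference AUC**: each known real record is scored by the
  negative Euclidean distance from its encoded (pooled-standardized +
  one-hot) representation to its nearest released row; AUC by the
  rank-sum identity with average ranks for ties. Released-copies-of-members
  gives AUC 1; a release independent of membership gives 0.5 in
  expectation. Both calibration points are recomputed by
  `scripts/acceptance.py`.
- **Utility**: Pearson correlation of slope vectors between the real-data
  and synthetic-data fits of the same regression (intercepts excluded —
  the intercept is a calibration term, not an association; a flag is not
  provided because the coefficient vectors are exposed and any alternative
  convention is one `np.corrcoef` away), plus held-out performance of the
  synthetic-fit model on real test data (rank-based AUC or RMSE) against
  the real-fit baseline.

## Desk-scale experiment

The directional claim — that the regression reward raises the coefficient
correlation over base adversarial training at no catastrophic fidelity
cost — is tested at desk scale: an `icu_like` cohort of n = 5,000
(80/20 train/test), 3,000 training iterations, batch 512, three seeds per
variant, networks of 2 × 64 units with noise dimension 64 and K = 2 PPO
epochs so the six runs stay tractable on a single CPU. The penalty weight
λ = 1 with t′ = 300 and a 300-iteration ramp was selected by a coarse
search over λ ∈ {0, 1, 5, 10} balancing coefficient recovery against
fidelity, mirroring how the weight is meant to be chosen in practice. The
test asserts a strict ordering of mean coefficient correlation
(reward > base) and that DWD falls from initialization for both variants;
it does not assert absolute values, which at this scale are noisy.

## Numerical choices and edge cases

- Population (ddof = 0) standard deviation in normalization makes the
  unit-variance postcondition exact; constant continuous columns are hard
  errors naming the offending feature.
- `split_cohort` shuffles with a seeded generator and cuts a prefix of
  round-half-up(fraction · n) rows.
- CSV serialization writes numerics at 17 significant digits (exact double
  round trips) and categoricals as labels; unknown labels and empty cells
  error with row/column locations.
- Advantage standardization guards the degenerate one-row batch (advantage
  0) and the all-equal-reward batch (no preference signal).
- Checkpoints store a schema fingerprint and refuse to load against a
  mismatched schema.

## Known limitations

- Single-CPU numpy training: suitable for cohorts of 10³–10⁵ rows and the
  desk-scale experiments here, not for tens of thousands of iterations on
  wide cohorts.
- One population-level reference regression; subgroup-specific rewards and
  non-regression objectives are natural extensions of the same reward
  interface but are not implemented.
- The attack model is membership inference only; attribute-inference and
  re-identification analyses are out of scope.
- Hyperparameter search is manual/config-driven; there is no automated
  Bayesian tuner.
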