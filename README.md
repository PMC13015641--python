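# regsyn

**Reward-guided synthetic tabular cohorts that preserve regression
structure.**

Synthetic data is an increasingly common vehicle for sharing biomedical
cohorts under privacy constraints and for augmenting small datasets. Most
generators, however, optimize generic distributional fidelity and give the
analyst no way to enforce the statistical properties their downstream
analysis actually depends on — typically, that a regression fitted on the
synthetic cohort reproduces the coefficients and predictions of the
real-data regression.

`regsyn` addresses this for mixed-type tabular cohorts (continuous vitals
and labs, binary flags, categorical demographics, one designated outcome).
A generator MLP maps noise to per-feature distribution parameters —
Normal heads for continuous features, Bernoulli for binary, categorical
softmax — and is trained as a reinforcement-learning policy with Proximal
Policy Optimization (PPO) against a per-sample reward

    r = σ(D(x)) + λ_t · R_reg(x),        R_reg(x) = −(q(x) − f(x))²

where σ(D(x)) is a discriminator's realism score (trained with binary
cross-entropy plus an R1 gradient penalty), f is a *reference regression*
fitted once on the real training data (logistic or OLS), q(x) is the
generator's pre-sampling conditional outcome — its Bernoulli outcome-head
probability, or the Gaussian outcome-head mean — and λ_t ramps linearly
from 0 to its full weight λ starting at iteration t′.

The reward targets a probability-matching condition: when the synthetic
covariates are full rank and q(x) = f(x), the real-data score equation
E[(y − f(x)) x̃] = 0 transfers to the synthetic distribution, so a
regression refit on synthetic data recovers the real coefficients
(β₀*, β*) exactly — for both logistic and linear outcomes. Because PPO
treats the reward as a black-box scalar, the penalty plugs in without any
architectural change, and λ = 0 reduces the loop to plain adversarial
training.

The package is fully self-contained: a cohort simulator generates
ICU-style (binary mortality) and survey-style (right-skewed continuous
outcome) cohorts with *known* generating coefficients, so training, the
reward, coefficient recovery, and all evaluation metrics are testable
without any external or access-restricted data. Evaluation covers three
axes: fidelity (dimension-wise difference, column-wise correlation
difference), privacy (nearest-neighbor membership-inference AUC), and
scientific utility (coefficient correlation, held-out AUC/RMSE), plus a
training-fraction sensitivity sweep. See `docs/methods.md` for the model,
assumptions, and numerical choices.

## Worked example

Train on a simulated ICU-style cohort with the regression reward and
evaluate all three axes:

```python
from regsyn import (preset_cohorts, split_cohort, TrainingConfig, RewardSchedule,
                    utility_report, fidelity_report, membership_inference_auc)
from regsyn.train import run_pipeline

real = preset_cohorts("icu_like", n=4000, seed=7)
train_ds, test_ds = split_cohort(real, 0.8, seed=7)
covs = [f.name for f in real.schema.covariates]

config = TrainingConfig(
    iterations=2000, batch_size=512,
    gen_hidden=(64, 64), disc_hidden=(64, 64), noise_dim=64,
    ppo_epochs=2, gen_lr=3e-4, disc_lr=3e-4,
    schedule=RewardSchedule(lam=1.0, t_start=200, ramp_len=200),
    seed=0,
)
synth, result, reference = run_pipeline(train_ds, config, covs, use_reward=True)

fid = fidelity_report(train_ds, synth)
priv = membership_inference_auc(train_ds.subset(range(1000)),
                                test_ds.subset(range(800)), synth)
util = utility_report(train_ds, test_ds, synth, covs)
print(f"DWD        : {fid.dwd:.4f}")
print(f"CWC        : {fid.cwc:.4f}")
print(f"MIA AUC    : {priv.auc:.3f}")
print(f"coef r     : {util.coefficient_r:.3f}")
print(f"synth AUC  : {util.synth_model_performance:.3f}")
print(f"real AUC   : {util.real_model_performance:.3f}")
```

Output (about two minutes on one CPU):

```
DWD        : 0.0257
CWC        : 0.0349
MIA AUC    : 0.503
coef r     : 0.967
synth AUC  : 0.771
real AUC   : 0.784
```

Reading the numbers: the synthetic cohort's univariate marginals sit close
to the training data (DWD, CWC near zero), the membership attack is near
random chance (AUC ≈ 0.5, i.e. the release does not reveal who was
trained on), the refit logistic coefficients correlate strongly with the
real-data fit, and the synthetic-fit mortality model scores held-out real
patients nearly as well as the real-data baseline. Training with
`use_reward=False` (equivalently λ = 0) typically lands at a visibly lower
coefficient correlation — that contrast, averaged over seeds, is asserted
by the end-to-end test in `tests/test_acceptance.py`.

The same pipeline is available from the shell:

```bash
regsyn simulate --preset icu_like --n 5000 --seed 1 --out cohort.csv --schema-out schema.yml
regsyn train    --data train.csv --schema schema.yml --config train.yml \
                --reference-covariates heart_rate,map,gcs --out run/
regsyn generate --checkpoint run/checkpoint.npz --n 10000 --seed 7 --out synth.csv
regsyn evaluate --real-train train.csv --real-test test.csv --synth synth.csv \
                --schema schema.yml --out report.json
```

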