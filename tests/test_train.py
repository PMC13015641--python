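"""PPO trainer: advantages, surrogate loss, loop behavior, checkpoints."""

import numpy as np
import pytest

from regsyn import (
    RewardSchedule,
    TrainingConfig,
    compute_advantages,
    fit_reference_regression,
    generate,
    load_checkpoint,
    normalize,
    ppo_generator_loss,
    preset_cohorts,
    save_checkpoint,
    train,
)
from regsyn.schema import SchemaViolationError
from regsyn.train import _ppo_objective


@pytest.fixture(scope="module")
def toy_cohort():
    """Small mixed cohort for loop tests (3 continuous, 1 binary outcome)."""
    from regsyn import CohortSimConfig, simulate_cohort

    cfg = CohortSimConfig(
        n=600,
        cont_names=["a", "b", "c"],
        cont_cov=np.eye(3),
        outcome_kind="logistic",
        beta0=-0.5,
        beta=np.array([0.8, -0.5, 0.0]),
        seed=17,
    )
    return simulate_cohort(cfg)


def small_config(**overrides):
    base = dict(
        iterations=30,
        batch_size=64,
        gen_hidden=(24, 24),
        disc_hidden=(24, 24),
        noise_dim=12,
        ppo_epochs=2,
        gen_lr=3e-4,
        disc_lr=3e-4,
        seed=0,
    )
    base.update(overrides)
    return TrainingConfig(**base)


class TestComputeAdvantages:
    def test_equal_rewards_give_zero_signal(self):
        np.testing.assert_allclose(compute_advantages(np.full(8, 0.3)), 0.0)

    def test_two_point_standardization(self):
        np.testing.assert_allclose(
            compute_advantages(np.array([0.0, 1.0])), [-1.0, 1.0], atol=1e-6
        )

    def test_single_row_batch_guard(self):
        np.testing.assert_allclose(compute_advantages(np.array([0.7])), 0.0)


class TestPpoLoss:
    def test_clip_arithmetic(self):
        # rho=2, A=1, eps=0.2 -> min(2, 1.2) = 1.2
        assert _ppo_objective(np.array([2.0]), np.array([1.0]), 0.2)[0] == 1.2
        # negative advantage: min picks the unclipped, more pessimistic term
        assert _ppo_objective(np.array([2.0]), np.array([-1.0]), 0.2)[0] == -2.0

    def test_null_advantages_zero_loss(self):
        obj = _ppo_objective(np.array([0.3, 1.0, 4.0]), np.zeros(3), 0.2)
        np.testing.assert_array_equal(obj, 0.0)

    def test_unchanged_parameters_loss_is_minus_mean_advantage(self, mixed_schema):
        from regsyn import GeneratorPolicy

        gen = GeneratorPolicy(mixed_schema, noise_dim=8, hidden=(16,), seed=2)
        noise = np.random.default_rng(0).standard_normal((40, 8))
        po = gen.forward_policy(noise)
        batch = gen.sample_batch(po, np.random.default_rng(1))
        adv = compute_advantages(np.random.default_rng(2).normal(size=40))
        loss = ppo_generator_loss(batch.rows, batch.log_probs, adv, po, 0.2)
        assert loss == pytest.approx(-float(adv.mean()), abs=1e-12)
        assert loss == pytest.approx(0.0, abs=1e-9)  # standardized advantages


class TestTrainingLoop:
    def test_smoke_run_finite_logs_and_checkpoint(self, toy_cohort, tmp_path):
        norm_train, norm = normalize(toy_cohort)
        res = train(norm_train, small_config())
        df = res.log.to_frame()
        assert len(df) == 30
        assert np.all(np.isfinite(df.to_numpy()))
        p = tmp_path / "ckpt.npz"
        save_checkpoint(p, res.generator, res.discriminator, norm)
        gen, disc, norm2 = load_checkpoint(p, schema=toy_cohort.schema)
        noise = np.random.default_rng(0).standard_normal((5, 12))
        np.testing.assert_allclose(
            gen.forward_policy(noise).means, res.generator.forward_policy(noise).means
        )

    def test_checkpoint_refuses_schema_mismatch(self, toy_cohort, mixed_schema,
                                                tmp_path):
        norm_train, norm = normalize(toy_cohort)
        res = train(norm_train, small_config(iterations=2))
        p = tmp_path / "ckpt.npz"
        save_checkpoint(p, res.generator)
        with pytest.raises(SchemaViolationError):
            load_checkpoint(p, schema=mixed_schema)

    def test_identical_seed_identical_trajectory(self, toy_cohort):
        norm_train, _ = normalize(toy_cohort)
        log1 = train(norm_train, small_config()).log.to_frame()
        log2 = train(norm_train, small_config()).log.to_frame()
        assert log1.equals(log2)

    def test_zero_weight_reference_matches_base_trajectory(self, toy_cohort):
        # with lam = 0 the penalty path multiplies by zero: trajectories match
        norm_train, _ = normalize(toy_cohort)
        covs = [f.name for f in toy_cohort.schema.covariates]
        ref = fit_reference_regression(norm_train, covs, "logistic")
        base = train(norm_train, small_config()).log.to_frame()
        reg = train(norm_train, small_config(), ref).log.to_frame()
        assert base.drop(columns="mean_penalty").equals(
            reg.drop(columns="mean_penalty")
        )

    def test_logged_components_reconstruct_reward(self, toy_cohort):
        norm_train, _ = normalize(toy_cohort)
        covs = [f.name for f in toy_cohort.schema.covariates]
        ref = fit_reference_regression(norm_train, covs, "logistic")
        cfg = small_config(schedule=RewardSchedule(lam=2.0, t_start=5, ramp_len=10))
        df = train(norm_train, cfg, ref).log.to_frame()
        np.testing.assert_allclose(
            df["mean_reward"],
            df["mean_realism"] + df["lam_t"] * df["mean_penalty"],
            atol=1e-12,
        )
        # anneal actually engaged during this run
        assert df["lam_t"].iloc[-1] == pytest.approx(2.0)
        assert df["lam_t"].iloc[0] == 0.0

    def test_generator_update_reads_only_scalar_scores(self, toy_cohort,
                                                       monkeypatch):
        """The generator must treat the critic as a black box: its update
        consumes realism scores only, never discriminator internals."""
        import importlib

        train_mod = importlib.import_module("regsyn.train")
        norm_train, _ = normalize(toy_cohort)
        calls = []
        orig = train_mod.Discriminator.score_rows

        def spy(self, rows):
            out = orig(self, rows)
            calls.append(out.scores)
            return out

        monkeypatch.setattr(train_mod.Discriminator, "score_rows", spy)
        cfg = small_config(iterations=3, disc_updates_per_gen=1)
        res = train(norm_train, cfg)
        assert len(calls) == 3  # one scoring pass per generator iteration
        assert all(isinstance(c, np.ndarray) for c in calls)

    def test_generated_output_is_denormalized(self, toy_cohort):
        norm_train, norm = normalize(toy_cohort)
        res = train(norm_train, small_config(iterations=5))
        synth = generate(res.generator, 200, seed=3, normalizer=norm)
        assert synth.schema == toy_cohort.schema
        assert synth.n == 200
        # outcome column remains valid binary after denormalization
        assert set(np.unique(synth.column("y"))) <= {0, 1}


class TestFidelityImprovement:
    def test_dimension_wise_difference_drops_during_training(self, toy_cohort):
        """Adversarial training must pull the generated marginals toward the
        training data, across independent seeds."""
        from regsyn import GeneratorPolicy, dimension_wise_difference
        from regsyn.train import generate as gen_rows

        norm_train, _ = normalize(toy_cohort)
        cfg_base = small_config(iterations=500, batch_size=128)
        for seed in (0, 1, 2):
            cfg = TrainingConfig(**{**cfg_base.__dict__, "seed": seed})
            ss = np.random.SeedSequence(seed)
            gseed = int(ss.spawn(3)[0].generate_state(1)[0] % 2**31)
            gen0 = GeneratorPolicy(norm_train.schema, cfg.noise_dim,
                                   cfg.gen_hidden, gseed)
            synth0 = gen_rows(gen0, 600, seed=99)
            dwd0, _ = dimension_wise_difference(norm_train, synth0)
            res = train(norm_train, cfg)
            synthT = gen_rows(res.generator, 600, seed=99)
            dwdT, _ = dimension_wise_difference(norm_train, synthT)
            assert dwdT < dwd0
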