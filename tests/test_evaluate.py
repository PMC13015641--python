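"""Fidelity, privacy, and utility metrics against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from regsyn import (
    CohortSchema,
    CohortSimConfig,
    DegenerateFeatureError,
    FeatureSpec,
    TabularDataset,
    coefficient_correlation,
    column_wise_correlation_diff,
    dimension_wise_difference,
    membership_inference_auc,
    simulate_cohort,
    split_cohort,
    utility_report,
)
from conftest import make_continuous_dataset


def _binary_table(values):
    schema = CohortSchema(
        (
            FeatureSpec("b", "binary"),
            FeatureSpec("y", "binary", role="outcome"),
        )
    )
    return TabularDataset(
        schema, pd.DataFrame({"b": values, "y": np.zeros(len(values), int)})
    )


class TestDimensionWiseDifference:
    def test_identical_tables_give_zero(self, mixed_dataset):
        dwd, per = dimension_wise_difference(mixed_dataset, mixed_dataset.copy())
        assert dwd == 0.0
        assert all(v == 0.0 for v in per.values())

    def test_binary_prevalence_difference(self):
        real = _binary_table([1] * 30 + [0] * 70)   # prevalence 0.30
        synth = _binary_table([1] * 25 + [0] * 75)  # prevalence 0.25
        dwd, per = dimension_wise_difference(real, synth)
        assert per["b"] == pytest.approx(0.05)
        assert per["y"] == 0.0
        assert dwd == pytest.approx(0.025)

    def test_maximally_separated_continuous_masses(self):
        real = make_continuous_dataset({"x": [0.0] * 5, "y": [0, 1, 2, 3, 4]})
        synth = make_continuous_dataset({"x": [1.0] * 5, "y": [0, 1, 2, 3, 4]})
        _, per = dimension_wise_difference(real, synth)
        assert per["x"] == pytest.approx(1.0)

    def test_matches_brute_force_on_ten_row_toy(self, mixed_dataset):
        real = mixed_dataset.subset(range(10))
        synth = mixed_dataset.subset(range(10, 20))
        dwd, per = dimension_wise_difference(real, synth)
        # brute force, feature by feature
        exp = {}
        exp["b1"] = abs(real.column("b1").mean() - synth.column("b1").mean())
        exp["y"] = abs(real.column("y").mean() - synth.column("y").mean())
        exp["ins"] = np.mean(
            [
                abs((real.column("ins") == k).mean() - (synth.column("ins") == k).mean())
                for k in range(3)
            ]
        )
        xr, xs = real.column("x1"), synth.column("x1")
        lo, hi = min(xr.min(), xs.min()), max(xr.max(), xs.max())
        a = np.sort((xr - lo) / (hi - lo))
        b = np.sort((xs - lo) / (hi - lo))
        exp["x1"] = np.abs(a - b).mean()  # equal-size W1 = mean |order stats|
        for k, v in exp.items():
            assert per[k] == pytest.approx(v, abs=1e-12)
        assert dwd == pytest.approx(np.mean(list(exp.values())), abs=1e-12)
        assert all(0.0 <= v <= 1.0 for v in per.values())


class TestColumnWiseCorrelation:
    def test_identical_tables_give_zero(self, mixed_dataset):
        assert column_wise_correlation_diff(mixed_dataset, mixed_dataset.copy()) == 0.0

    def test_opposite_perfect_correlations(self):
        real = make_continuous_dataset({"x": [0.0, 1, 2, 3], "y": [0.0, 1, 2, 3]})
        synth = make_continuous_dataset({"x": [0.0, 1, 2, 3], "y": [3.0, 2, 1, 0]})
        assert column_wise_correlation_diff(real, synth) == pytest.approx(2.0)

    def test_row_permutation_invariance(self, mixed_dataset):
        perm = mixed_dataset.subset(np.random.default_rng(0).permutation(40))
        a = column_wise_correlation_diff(mixed_dataset, perm)
        b = column_wise_correlation_diff(mixed_dataset, mixed_dataset)
        assert a == pytest.approx(b, abs=1e-12)

    def test_symmetry_in_arguments(self, mixed_dataset):
        other = mixed_dataset.subset(range(20))
        assert column_wise_correlation_diff(
            mixed_dataset, other
        ) == pytest.approx(column_wise_correlation_diff(other, mixed_dataset))

    def test_zero_variance_column_is_error(self):
        real = make_continuous_dataset({"x": [1.0, 1.0, 1.0], "y": [0.0, 1, 2]})
        synth = make_continuous_dataset({"x": [0.0, 1, 2], "y": [0.0, 1, 2]})
        with pytest.raises(DegenerateFeatureError):
            column_wise_correlation_diff(real, synth)

    def test_matches_brute_force_on_ten_row_toy(self, mixed_dataset):
        from regsyn import encode_one_hot

        real = mixed_dataset.subset(range(10))
        synth = mixed_dataset.subset(range(10, 20))
        got = column_wise_correlation_diff(real, synth)
        cr = np.corrcoef(encode_one_hot(real), rowvar=False)
        cs = np.corrcoef(encode_one_hot(synth), rowvar=False)
        acc = []
        for i in range(cr.shape[0]):
            for j in range(i + 1, cr.shape[0]):
                acc.append(abs(cr[i, j] - cs[i, j]))
        assert got == pytest.approx(np.mean(acc), abs=1e-12)


def _continuous_cohort(n, seed, d=3):
    cfg = CohortSimConfig(
        n=n, cont_names=[f"x{i}" for i in range(d)], outcome_kind="linear",
        beta0=0.0, sigma_eps=1.0, seed=seed
    )
    return simulate_cohort(cfg)


class TestMembershipInference:
    def test_exact_copy_of_members_gives_auc_one(self):
        cohort = _continuous_cohort(200, 0)
        members, non_members = split_cohort(cohort, 0.5, seed=1)
        rep = membership_inference_auc(members, non_members, members.copy())
        assert rep.auc == 1.0

    def test_hand_distance_instance_matches_pairwise_count(self):
        # members at distance ~0.1, 0.2 from the released row; non-members
        # at 0.3, 0.4: every member outranks every non-member
        schema = CohortSchema(
            (
                FeatureSpec("x", "continuous"),
                FeatureSpec("y", "continuous", role="outcome"),
            )
        )

        def tbl(xs):
            return TabularDataset(
                schema, pd.DataFrame({"x": xs, "y": np.zeros(len(xs))})
            )

        members = tbl([0.1, 0.2])
        non_members = tbl([0.3, 0.4])
        synth = tbl([0.0])
        rep = membership_inference_auc(members, non_members, synth)
        # brute force over all member/non-member pairs
        wins = sum(
            (m > nm) + 0.5 * (m == nm)
            for m in rep.member_scores
            for nm in rep.non_member_scores
        )
        assert rep.auc == pytest.approx(wins / 4)
        assert rep.auc == 1.0

    def test_exchangeable_scores_average_to_half(self):
        # released data independent of membership: over repeated reshuffles
        # of the member/non-member labels, the mean AUC concentrates at 0.5
        cohort = _continuous_cohort(400, 3)
        released = _continuous_cohort(400, 4)
        rng = np.random.default_rng(5)
        aucs = []
        for _ in range(50):
            perm = rng.permutation(cohort.n)
            rep = membership_inference_auc(
                cohort.subset(perm[:200]), cohort.subset(perm[200:]), released
            )
            aucs.append(rep.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.01

    def test_empty_released_set_is_error(self):
        cohort = _continuous_cohort(10, 6)
        members, non_members = split_cohort(cohort, 0.5, seed=0)
        with pytest.raises(Exception):
            membership_inference_auc(members, non_members, cohort.subset([]))


class TestCoefficientCorrelation:
    def test_identical_vectors(self):
        assert coefficient_correlation([1.0, 2, 3], [1.0, 2, 3]) == pytest.approx(1.0)

    def test_negated_vector(self):
        assert coefficient_correlation([1.0, 2, 3], [-1.0, -2, -3]) == pytest.approx(-1.0)

    def test_brute_force_pearson(self):
        a, b = np.array([1.0, 2, 3]), np.array([1.0, 2, 4])
        expected = (
            np.sum((a - a.mean()) * (b - b.mean()))
            / np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        )
        assert coefficient_correlation(a, b) == pytest.approx(expected)
        assert coefficient_correlation(a, b) == pytest.approx(0.982, abs=5e-4)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError):
            coefficient_correlation([1.0, 1, 1], [1.0, 2, 3])


@pytest.fixture(scope="module")
def cohort():
    cfg = CohortSimConfig(
        n=6000,
        cont_names=["a", "b"],
        bin_names=["t"],
        bin_probs=[0.4],
        outcome_kind="logistic",
        beta0=-0.8,
        beta=np.array([0.9, -0.6, 0.7]),
        seed=12,
    )
    return simulate_cohort(cfg)


class TestUtilityReport:
    def test_identity_synthetic_data(self, cohort):
        train_ds, test_ds = split_cohort(cohort, 0.7, seed=0)
        rep = utility_report(train_ds, test_ds, train_ds.copy(), ["a", "b", "t"])
        assert rep.coefficient_r == pytest.approx(1.0)
        assert rep.synth_model_performance == pytest.approx(
            rep.real_model_performance
        )
        assert rep.metric_kind == "auc"

    def test_permuted_outcome_breaks_association(self, cohort):
        train_ds, test_ds = split_cohort(cohort, 0.7, seed=0)
        df = train_ds.data.copy()
        df["y"] = np.random.default_rng(1).permutation(df["y"].to_numpy())
        broken = TabularDataset(train_ds.schema, df)
        rep = utility_report(train_ds, test_ds, broken, ["a", "b", "t"])
        assert np.all(np.abs(rep.synth_fit.slopes) < 0.1)
        assert abs(rep.synth_model_performance - 0.5) < 0.1

    def test_probability_matched_synthetic_recovers_coefficients(self, cohort):
        # outcomes drawn Bernoulli(f(x)) on fresh covariates: slope r > 0.99
        from regsyn import fit_reference_regression, reference_predict

        covs = ["a", "b", "t"]
        reg = fit_reference_regression(cohort, covs, "logistic")
        fresh = simulate_cohort(
            CohortSimConfig(
                n=50_000,
                cont_names=["a", "b"],
                bin_names=["t"],
                bin_probs=[0.4],
                outcome_kind="logistic",
                beta0=-0.8,
                beta=np.array([0.9, -0.6, 0.7]),
                seed=77,
            )
        )
        f = reference_predict(reg, fresh)
        df = fresh.data.copy()
        df["y"] = (np.random.default_rng(2).random(fresh.n) < f).astype(int)
        synth = TabularDataset(fresh.schema, df)
        train_ds, test_ds = split_cohort(cohort, 0.7, seed=0)
        rep = utility_report(train_ds, test_ds, synth, covs)
        assert rep.coefficient_r > 0.99


class TestSensitivitySweep:
    def test_shape_and_reproducibility(self):
        from regsyn import RewardSchedule, TrainingConfig, sensitivity_sweep

        cohort = simulate_cohort(
            CohortSimConfig(
                n=400,
                cont_names=["a", "b"],
                outcome_kind="logistic",
                beta0=-0.3,
                beta=np.array([0.8, -0.5]),
                seed=2,
            )
        )
        train_ds, test_ds = split_cohort(cohort, 0.75, seed=0)
        cfg = TrainingConfig(
            iterations=15, batch_size=64, gen_hidden=(16,), disc_hidden=(16,),
            noise_dim=8, ppo_epochs=1,
        )
        sched = RewardSchedule(lam=1.0, t_start=0, ramp_len=5)
        kwargs = dict(fractions=[0.5, 1.0], seeds=[0, 1])
        s1 = sensitivity_sweep(train_ds, test_ds, cfg, sched, **kwargs)
        assert len(s1) == 2 * 2 * 2  # fractions x seeds x variants
        assert set(s1["variant"]) == {"base", "regression_reward"}
        s2 = sensitivity_sweep(train_ds, test_ds, cfg, sched, **kwargs)
        pd.testing.assert_frame_equal(s1, s2)
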