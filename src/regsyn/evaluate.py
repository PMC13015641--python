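"""Three-axis evaluation of synthetic cohorts: fidelity, privacy, utility.

Fidelity
    Dimension-Wise Difference (DWD): per-feature univariate discrepancy —
    absolute prevalence difference for binary features, mean absolute
    per-category prevalence difference for categoricals, and 1-D
    Wasserstein-1 distance for continuous features after min-max rescaling
    over the pooled real and synthetic values (guaranteeing a [0, 1]
    value) — averaged over all features.  Column-Wise Correlation (CWC)
    difference: mean absolute difference between the Pearson correlation
    matrices of the one-hot encoded real and synthetic tables, over the
    off-diagonal upper triangle.  Lower is better for both.

Privacy
    A nearest-neighbor membership-inference attack: each known real record
    is scored by the negative Euclidean distance from its encoded
    representation to its nearest released synthetic row, and the attack
    AUC is the rank-based probability that a training member outscores a
    non-member (ties counted half).  Values near 0.5 mean the released
    data does not reveal who was in the training set.

Utility
    The same regression specification is fitted on real training data and
    on the synthetic data; utility is summarized by the Pearson
    correlation of the two slope vectors and by the synthetic-fit model's
    performance on held-out real data (AUC for binary outcomes, RMSE for
    continuous), with the real-fit model as baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .reward import ReferenceRegression, fit_reference_regression, reference_predict
from .schema import (
    DegenerateFeatureError,
    SchemaViolationError,
    TabularDataset,
    encode_one_hot,
    normalize,
)


@dataclass
class FidelityReport:
    dwd: float
    dwd_per_feature: dict[str, float]
    cwc: float


@dataclass
class PrivacyReport:
    auc: float
    member_scores: np.ndarray
    non_member_scores: np.ndarray
    n_members: int
    n_non_members: int
    n_released: int


@dataclass
class UtilityReport:
    real_fit: ReferenceRegression
    synth_fit: ReferenceRegression
    coefficient_r: float
    metric_kind: str            # "auc" or "rmse"
    synth_model_performance: float
    real_model_performance: float


def _check_same_schema(a: TabularDataset, b: TabularDataset) -> None:
    if a.schema != b.schema:
        raise SchemaViolationError("datasets must share a schema")


def dimension_wise_difference(
    real: TabularDataset, synth: TabularDataset
) -> tuple[float, dict[str, float]]:
    """DWD and its per-feature breakdown; every term lies in [0, 1]."""
    _check_same_schema(real, synth)
    if real.n == 0 or synth.n == 0:
        raise ValueError("both tables must be non-empty")
    per: dict[str, float] = {}
    for f in real.schema.features:
        xr, xs = real.column(f.name), synth.column(f.name)
        if f.kind == "binary":
            per[f.name] = abs(float(xr.mean()) - float(xs.mean()))
        elif f.kind == "categorical":
            diffs = [
                abs(float((xr == k).mean()) - float((xs == k).mean()))
                for k in range(f.n_categories)
            ]
            per[f.name] = float(np.mean(diffs))
        else:
            lo = min(xr.min(), xs.min())
            hi = max(xr.max(), xs.max())
            if hi == lo:  # all pooled values identical -> distributions equal
                per[f.name] = 0.0
            else:
                per[f.name] = float(
                    stats.wasserstein_distance(
                        (xr - lo) / (hi - lo), (xs - lo) / (hi - lo)
                    )
                )
    return float(np.mean(list(per.values()))), per


def column_wise_correlation_diff(
    real: TabularDataset, synth: TabularDataset
) -> float:
    """Mean |corr_real - corr_synth| over off-diagonal upper-triangle pairs.

    Correlations are Pearson, computed on the one-hot encoded tables so
    categorical structure contributes.
    """
    _check_same_schema(real, synth)
    enc_r, enc_s = encode_one_hot(real), encode_one_hot(synth)
    if enc_r.shape[1] < 2:
        raise ValueError("need at least 2 encoded columns")
    for name, enc in (("real", enc_r), ("synthetic", enc_s)):
        if np.any(enc.std(axis=0) == 0):
            cols = real.schema.encoded_columns()
            bad = [c for c, s in zip(cols, enc.std(axis=0)) if s == 0]
            raise DegenerateFeatureError(
                f"zero-variance encoded column(s) in {name} table: {bad}"
            )
    cr = np.corrcoef(enc_r, rowvar=False)
    cs = np.corrcoef(enc_s, rowvar=False)
    iu = np.triu_indices_from(cr, k=1)
    return float(np.mean(np.abs(cr[iu] - cs[iu])))


def fidelity_report(real: TabularDataset, synth: TabularDataset) -> FidelityReport:
    dwd, per = dimension_wise_difference(real, synth)
    return FidelityReport(dwd, per, column_wise_correlation_diff(real, synth))


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(pos > neg) with ties counted half, via the rank-sum identity."""
    scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(scores)
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def membership_inference_auc(
    members: TabularDataset,
    non_members: TabularDataset,
    synth: TabularDataset,
) -> PrivacyReport:
    """Nearest-neighbor membership-inference attack AUC.

    All three tables are normalized with statistics pooled over members and
    non-members (the adversary's view of the real data), then one-hot
    encoded; each real record's attack score is the negative Euclidean
    distance to its nearest released row.
    """
    _check_same_schema(members, non_members)
    _check_same_schema(members, synth)
    if synth.n == 0:
        raise ValueError("released synthetic set must be non-empty")
    pooled = pd.concat([members.data, non_members.data], ignore_index=True)
    loc: dict[str, float] = {}
    scale: dict[str, float] = {}
    for f in members.schema.features:
        if f.kind == "continuous":
            x = pooled[f.name].to_numpy(dtype=float)
            loc[f.name] = float(x.mean())
            s = float(x.std())
            scale[f.name] = s if s > 0 else 1.0  # constant feature: no signal

    def _apply(ds: TabularDataset) -> np.ndarray:
        df = ds.data.copy()
        for name, m in loc.items():
            df[name] = (df[name].to_numpy(dtype=float) - m) / scale[name]
        return encode_one_hot(TabularDataset(ds.schema, df))

    enc_m, enc_n, enc_s = _apply(members), _apply(non_members), _apply(synth)
    nn = NearestNeighbors(n_neighbors=1).fit(enc_s)
    d_m = nn.kneighbors(enc_m, return_distance=True)[0][:, 0]
    d_n = nn.kneighbors(enc_n, return_distance=True)[0][:, 0]
    auc = _rank_auc(-d_m, -d_n)
    return PrivacyReport(auc, -d_m, -d_n, members.n, non_members.n, synth.n)


def coefficient_correlation(
    real_coefs: np.ndarray, synth_coefs: np.ndarray
) -> float:
    """Pearson correlation between matched slope vectors."""
    a = np.asarray(real_coefs, dtype=float)
    b = np.asarray(synth_coefs, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("coefficient vectors must match and have length >= 2")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    return float(np.corrcoef(a, b)[0, 1])


def _test_performance(
    reg: ReferenceRegression, test: TabularDataset
) -> tuple[str, float]:
    y = test.column(test.schema.outcome.name).astype(float)
    pred = reference_predict(reg, test)
    if reg.kind == "logistic":
        return "auc", _rank_auc(pred[y == 1], pred[y == 0])
    return "rmse", float(np.sqrt(np.mean((y - pred) ** 2)))


def utility_report(
    real_train: TabularDataset,
    real_test: TabularDataset,
    synth: TabularDataset,
    covariates: list[str],
    kind: str | None = None,
) -> UtilityReport:
    """Fit the same regression on real and synthetic data and compare."""
    _check_same_schema(real_train, real_test)
    _check_same_schema(real_train, synth)
    if kind is None:
        kind = (
            "logistic" if real_train.schema.outcome.kind == "binary" else "linear"
        )
    real_fit = fit_reference_regression(real_train, covariates, kind)
    synth_fit = fit_reference_regression(synth, covariates, kind)
    r = coefficient_correlation(real_fit.slopes, synth_fit.slopes)
    metric, synth_perf = _test_performance(synth_fit, real_test)
    _, real_perf = _test_performance(real_fit, real_test)
    return UtilityReport(real_fit, synth_fit, r, metric, synth_perf, real_perf)


def sensitivity_sweep(
    real_train: TabularDataset,
    real_test: TabularDataset,
    config,
    reg_schedule,
    fractions: list[float],
    seeds: list[int],
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Training-fraction sweep over both model variants.

    For every fraction x seed x variant (base: penalty weight 0;
    regression-reward: ``reg_schedule``), the real training cohort is
    subsampled, a generator is trained end-to-end, and the utility report
    against the fixed held-out test set is recorded.  Returns one row per
    cell plus ``summarize_sweep`` for mean +/- sd aggregation.
    """
    from .reward import RewardSchedule
    from .train import run_pipeline

    if list(fractions) != sorted(fractions):
        raise ValueError("fractions must be sorted ascending")
    if not seeds:
        raise ValueError("need at least one seed")
    if covariates is None:
        covariates = [f.name for f in real_train.schema.covariates]
    rows = []
    for frac in fractions:
        for seed in seeds:
            if frac >= 1.0:
                sub = real_train
            else:
                rng = np.random.default_rng(seed)
                k = max(2, int(np.floor(frac * real_train.n + 0.5)))
                sub = real_train.subset(rng.permutation(real_train.n)[:k])
            for variant, schedule in (
                ("base", RewardSchedule(0.0, 0, 1)),
                ("regression_reward", reg_schedule),
            ):
                cfg = replace(config, seed=seed, schedule=schedule)
                synth, _, _ = run_pipeline(
                    sub, cfg, covariates, use_reward=(variant != "base")
                )
                rep = utility_report(sub, real_test, synth, covariates)
                rows.append(
                    {
                        "fraction": frac,
                        "seed": seed,
                        "variant": variant,
                        "coefficient_r": rep.coefficient_r,
                        "metric": rep.metric_kind,
                        "synth_performance": rep.synth_model_performance,
                        "real_performance": rep.real_model_performance,
                    }
                )
    return pd.DataFrame(rows)


def summarize_sweep(sweep: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd per fraction x variant cell."""
    return (
        sweep.groupby(["fraction", "variant"])
        .agg(
            coefficient_r_mean=("coefficient_r", "mean"),
            coefficient_r_sd=("coefficient_r", "std"),
            synth_performance_mean=("synth_performance", "mean"),
            synth_performance_sd=("synth_performance", "std"),
        )
        .reset_index()
    )


def plot_sweep(sweep: pd.DataFrame, path) -> None:
    """Minimal diagnostic figure for a sensitivity sweep."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = summarize_sweep(sweep)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for variant, grp in summary.groupby("variant"):
        ax.errorbar(
            grp["fraction"],
            grp["coefficient_r_mean"],
            yerr=grp["coefficient_r_sd"].fillna(0.0),
            marker="o",
            capsize=3,
            label=variant,
        )
    ax.set_xlabel("training fraction")
    ax.set_ylabel("coefficient r")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
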