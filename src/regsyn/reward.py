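"""The regression-aligned reward.

Before generator training starts, a fixed reference regression f is fitted
on the real training data: logistic for a binary outcome, ordinary least
squares for a continuous one, over a declared covariate list with
categoricals reference-coded (first declared category dropped).  During
training every generated row x is penalized by how far the generator's
pre-sampling conditional outcome q(x) sits from the reference prediction
f(x)::

    R_reg(x) = -(q(x) - f(x))^2

and the total per-sample reward at iteration t is::

    r = sigma(D(x)) + lambda_t * R_reg(x)

where lambda_t ramps linearly from 0 (before the start iteration t') to its
full weight lambda over a configurable number of iterations.  Driving
q(x) -> f(x) enforces probability matching, which — together with
non-degenerate synthetic covariates — guarantees that a regression refit on
the synthetic data recovers the real-data coefficients; that recovery
property is exercised directly in the tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .schema import (
    CohortSchema,
    ConvergenceError,
    NonDegeneracyError,
    TabularDataset,
)


def build_design(
    dataset: TabularDataset, covariates: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Design matrix over named covariates, categoricals reference-coded.

    Continuous and binary covariates enter as single columns; each
    categorical expands to indicators for every category except the first
    declared one, which serves as the reference level.  The returned column
    names make coefficient vectors comparable across real/synthetic fits.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for nm in covariates:
        f = dataset.schema.feature(nm)
        x = dataset.column(nm).astype(np.float64)
        if f.kind == "categorical":
            for k in range(1, f.n_categories):
                cols.append((dataset.column(nm) == k).astype(np.float64))
                names.append(f"{nm}={f.categories[k]}")
        else:
            cols.append(x)
            names.append(nm)
    X = np.column_stack(cols) if cols else np.zeros((dataset.n, 0))
    return X, names


@dataclass
class ReferenceRegression:
    """The fixed real-data regression f(x) = link(beta0* + x^T beta*)."""

    kind: str                      # "logistic" or "linear"
    covariates: list[str]          # schema feature names, in order
    coef_names: list[str]          # encoded design columns (reference-coded)
    intercept: float
    slopes: np.ndarray
    converged: bool
    n_iter: int
    intercept_se: float = float("nan")
    slope_se: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def to_json(self, path=None) -> str:
        doc = {
            "kind": self.kind,
            "covariates": self.covariates,
            "coef_names": self.coef_names,
            "intercept": self.intercept,
            "slopes": self.slopes.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "intercept_se": self.intercept_se,
            "slope_se": self.slope_se.tolist(),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ReferenceRegression":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(
            kind=doc["kind"],
            covariates=list(doc["covariates"]),
            coef_names=list(doc["coef_names"]),
            intercept=float(doc["intercept"]),
            slopes=np.asarray(doc["slopes"], dtype=float),
            converged=bool(doc["converged"]),
            n_iter=int(doc["n_iter"]),
            intercept_se=float(doc.get("intercept_se", float("nan"))),
            slope_se=np.asarray(doc.get("slope_se", []), dtype=float),
        )


_GRAD_TOL = 1e-8


def fit_reference_regression(
    real_train: TabularDataset, covariates: list[str], kind: str
) -> ReferenceRegression:
    """Fit f on real training data: logistic MLE or closed-form OLS.

    The design must be non-degenerate (no constant column, no exact
    collinearity); for logistic fits the Newton/IRLS solution is accepted
    only when the score-equation residual mean((y - f(x)) x~) is below
    1e-8 in max norm.
    """
    if kind not in ("logistic", "linear"):
        raise ValueError(f"unknown regression kind {kind!r}")
    X, names = build_design(real_train, covariates)
    y = real_train.column(real_train.schema.outcome.name).astype(np.float64)
    Xa = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        raise NonDegeneracyError(
            "design matrix is rank deficient (constant or collinear covariates)"
        )
    if kind == "linear":
        res = sm.OLS(y, Xa).fit()
        converged, n_iter = True, 0
    else:
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        try:
            with warnings.catch_warnings():
                # separation means the MLE does not exist: escalate to error
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = sm.Logit(y, Xa).fit(method="newton", maxiter=100,
                                          tol=1e-12, disp=0,
                                          warn_convergence=False)
        except ConvergenceError:
            raise
        except Exception as exc:
            raise ConvergenceError(f"logistic fit failed: {exc}") from exc
        p = 1.0 / (1.0 + np.exp(-(Xa @ res.params)))
        score = np.abs(Xa.T @ (y - p)) / len(y)
        n_iter = int(res.mle_retvals.get("iterations", 0))
        # the score equation is the authoritative optimality check; the
        # optimizer's own flag can trip on its stricter internal tolerance
        if score.max() > _GRAD_TOL or not np.all(np.isfinite(res.params)):
            raise ConvergenceError(
                f"logistic fit did not reach score tolerance "
                f"(max |score|/n = {score.max():.3e})"
            )
        converged = True
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    return ReferenceRegression(
        kind=kind,
        covariates=list(covariates),
        coef_names=names,
        intercept=float(params[0]),
        slopes=params[1:].copy(),
        converged=converged,
        n_iter=n_iter,
        intercept_se=float(bse[0]),
        slope_se=bse[1:].copy(),
    )


def reference_predict(reg: ReferenceRegression, rows: TabularDataset) -> np.ndarray:
    """Per-row prediction f(x): sigmoid link for logistic, identity for OLS."""
    X, names = build_design(rows, reg.covariates)
    if names != reg.coef_names:
        raise ValueError("rows do not conform to the regression's covariate list")
    lin = reg.intercept + X @ reg.slopes
    if reg.kind == "logistic":
        return 1.0 / (1.0 + np.exp(-lin))
    return lin


def regression_penalty(q: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Per-row penalty -(q - f)^2; zero exactly when q matches f."""
    q = np.asarray(q, dtype=np.float64)
    f = np.asarray(f, dtype=np.float64)
    if q.shape != f.shape:
        raise ValueError("q and f must have the same length")
    return -((q - f) ** 2)


@dataclass(frozen=True)
class RewardSchedule:
    """Linear anneal of the penalty weight: 0 before t', ramping to lambda."""

    lam: float = 0.0
    t_start: int = 0
    ramp_len: int = 1

    def __post_init__(self) -> None:
        if self.lam < 0 or self.t_start < 0 or self.ramp_len < 1:
            raise ValueError("need lam >= 0, t_start >= 0, ramp_len >= 1")


def anneal_weight(t: int, schedule: RewardSchedule) -> float:
    """lambda_t = 0 for t < t', then lambda * min(1, (t - t') / ramp_len)."""
    if t < 0:
        raise ValueError("iteration must be non-negative")
    if t < schedule.t_start:
        return 0.0
    return schedule.lam * min(1.0, (t - schedule.t_start) / schedule.ramp_len)


@dataclass
class RewardBreakdown:
    """Per-row reward components: r = realism + lambda_t * penalty."""

    realism: np.ndarray
    penalty: np.ndarray
    lam_t: float
    total: np.ndarray


def total_reward(
    realism: np.ndarray, penalty: np.ndarray, lam_t: float
) -> RewardBreakdown:
    """Combine realism and penalty; r never exceeds the realism score."""
    realism = np.asarray(realism, dtype=np.float64)
    penalty = np.asarray(penalty, dtype=np.float64)
    if np.any(penalty > 0):
        raise ValueError("penalty must be non-positive")
    if lam_t < 0:
        raise ValueError("lambda_t must be non-negative")
    return RewardBreakdown(realism, penalty, lam_t, realism + lam_t * penalty)
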