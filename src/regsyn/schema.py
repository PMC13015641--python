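"""Typed mixed-column cohort tables.

A cohort is a table whose columns are declared up front as continuous,
binary, or categorical, with exactly one column designated as the outcome
of the downstream regression.  Everything else in the package — the
simulator, the generator policy, the discriminator, the reward, and the
evaluation metrics — speaks this data model.

Continuous columns hold floats, binary columns hold {0, 1}, categorical
columns hold integer category indices; the declared category order is
authoritative and labels are only used at the CSV boundary.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

KINDS = ("continuous", "binary", "categorical")
ROLES = ("covariate", "outcome", "auxiliary")


class CohortError(Exception):
    """Base class for cohort data-model errors."""


class SchemaError(CohortError):
    """Invalid schema declaration."""


class SchemaViolationError(CohortError):
    """Data does not conform to its declared schema."""


class MissingDataError(CohortError):
    """A cell is missing; imputation is deliberately not performed here."""


class DegenerateFeatureError(CohortError):
    """A feature is constant (zero spread) where spread is required."""


class ConvergenceError(CohortError):
    """An iterative fit failed to converge."""


class NonDegeneracyError(CohortError):
    """Design matrix is rank deficient (constant or collinear columns)."""


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of a single column: its name, type, and modelling role."""

    name: str
    kind: str
    role: str = "covariate"
    categories: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"unknown kind {self.kind!r} for feature {self.name!r}")
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for feature {self.name!r}")
        if self.kind == "categorical":
            if self.categories is None or len(self.categories) < 2:
                raise SchemaError(
                    f"categorical feature {self.name!r} needs at least 2 categories"
                )
            if len(set(self.categories)) != len(self.categories):
                raise SchemaError(
                    f"categorical feature {self.name!r} has duplicate category labels"
                )
            object.__setattr__(self, "categories", tuple(self.categories))
        elif self.categories is not None:
            raise SchemaError(
                f"{self.kind} feature {self.name!r} must not declare categories"
            )

    @property
    def n_categories(self) -> int:
        return len(self.categories) if self.categories else 0

    @property
    def encoded_width(self) -> int:
        """Width of this feature in the one-hot encoded matrix."""
        return self.n_categories if self.kind == "categorical" else 1


@dataclass(frozen=True)
class CohortSchema:
    """Ordered list of feature declarations with exactly one outcome."""

    features: tuple[FeatureSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise SchemaError("feature names must be unique")
        outcomes = [f for f in self.features if f.role == "outcome"]
        if len(outcomes) != 1:
            raise SchemaError(f"schema needs exactly one outcome, found {len(outcomes)}")
        if outcomes[0].kind not in ("binary", "continuous"):
            raise SchemaError("outcome must be binary or continuous")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def outcome(self) -> FeatureSpec:
        return next(f for f in self.features if f.role == "outcome")

    @property
    def covariates(self) -> list[FeatureSpec]:
        return [f for f in self.features if f.role == "covariate"]

    def feature(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise SchemaError(f"no feature named {name!r}")

    @property
    def encoded_width(self) -> int:
        return sum(f.encoded_width for f in self.features)

    def encoded_columns(self, features: list[FeatureSpec] | None = None) -> list[str]:
        """Column names of the one-hot encoded matrix, in deterministic order."""
        cols: list[str] = []
        for f in features if features is not None else self.features:
            if f.kind == "categorical":
                cols.extend(f"{f.name}={c}" for c in f.categories)
            else:
                cols.append(f.name)
        return cols

    @property
    def fingerprint(self) -> str:
        """Stable digest used to guard checkpoint/normalizer compatibility."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_dict(self) -> dict:
        out = []
        for f in self.features:
            d: dict = {"name": f.name, "kind": f.kind, "role": f.role}
            if f.categories:
                d["categories"] = list(f.categories)
            out.append(d)
        return {"features": out}

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSchema":
        feats = []
        for fd in d["features"]:
            cats = tuple(fd["categories"]) if "categories" in fd else None
            feats.append(
                FeatureSpec(fd["name"], fd["kind"], fd.get("role", "covariate"), cats)
            )
        return cls(tuple(feats))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "CohortSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class TabularDataset:
    """A validated cohort table bound to its schema.

    ``data`` holds one column per schema feature, in schema order:
    float64 for continuous, integer {0,1} for binary, integer category
    indices for categorical features.
    """

    schema: CohortSchema
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.data.columns) != self.schema.names:
            missing = set(self.schema.names) - set(self.data.columns)
            if missing:
                raise SchemaViolationError(f"missing columns: {sorted(missing)}")
            self.data = self.data[self.schema.names]
        self.data = self.data.reset_index(drop=True)
        for f in self.schema.features:
            col = self.data[f.name]
            if col.isna().any():
                raise MissingDataError(f"missing values in column {f.name!r}")
            if f.kind == "continuous":
                self.data[f.name] = col.astype(np.float64)
            else:
                vals = col.astype(np.int64)
                if f.kind == "binary":
                    bad = ~vals.isin((0, 1))
                else:
                    bad = (vals < 0) | (vals >= f.n_categories)
                if bad.any():
                    row = int(np.flatnonzero(bad.to_numpy())[0])
                    raise SchemaViolationError(
                        f"invalid value {col.iloc[row]!r} in column {f.name!r}, row {row}"
                    )
                self.data[f.name] = vals

    @property
    def n(self) -> int:
        return len(self.data)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def subset(self, idx) -> "TabularDataset":
        return TabularDataset(self.schema, self.data.iloc[np.asarray(idx)].copy())

    def copy(self) -> "TabularDataset":
        return TabularDataset(self.schema, self.data.copy())

    def equals(self, other: "TabularDataset") -> bool:
        return self.schema == other.schema and self.data.equals(other.data)


@dataclass(frozen=True)
class Normalizer:
    """Per-continuous-feature location/scale fitted by :func:`normalize`."""

    location: dict[str, float]
    scale: dict[str, float]
    schema_fingerprint: str

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scale.values()):
            raise SchemaError("normalizer scales must be strictly positive")


def normalize(dataset: TabularDataset) -> tuple[TabularDataset, Normalizer]:
    """Standardize continuous columns to zero mean and unit population sd.

    Binary and categorical columns pass through unchanged.  A constant
    continuous column is a hard error: it carries no information and makes
    unit variance unattainable.
    """
    loc: dict[str, float] = {}
    scale: dict[str, float] = {}
    df = dataset.data.copy()
    for f in dataset.schema.features:
        if f.kind != "continuous":
            continue
        x = df[f.name].to_numpy(dtype=np.float64)
        m = float(np.mean(x))
        s = float(np.std(x))  # population convention (ddof=0)
        if s == 0.0 or not np.isfinite(s):
            raise DegenerateFeatureError(
                f"continuous feature {f.name!r} has zero spread"
            )
        df[f.name] = (x - m) / s
        loc[f.name] = m
        scale[f.name] = s
    norm = Normalizer(loc, scale, dataset.schema.fingerprint)
    return TabularDataset(dataset.schema, df), norm


def denormalize(dataset: TabularDataset, norm: Normalizer) -> TabularDataset:
    """Exact inverse of :func:`normalize` on continuous columns."""
    if norm.schema_fingerprint != dataset.schema.fingerprint:
        raise SchemaViolationError("normalizer was fitted on a different schema")
    df = dataset.data.copy()
    for name, m in norm.location.items():
        df[name] = df[name].to_numpy(dtype=np.float64) * norm.scale[name] + m
    return TabularDataset(dataset.schema, df)


def encode_one_hot(dataset: TabularDataset) -> np.ndarray:
    """One-hot encode a cohort into a dense float matrix.

    Continuous and binary columns pass through; each categorical column
    expands into an indicator block with one column per declared category.
    Column order follows the schema, categories in declared order.
    """
    n = dataset.n
    out = np.empty((n, dataset.schema.encoded_width), dtype=np.float64)
    j = 0
    for f in dataset.schema.features:
        col = dataset.column(f.name)
        if f.kind == "categorical":
            k = f.n_categories
            block = np.zeros((n, k))
            block[np.arange(n), col.astype(int)] = 1.0
            out[:, j : j + k] = block
            j += k
        else:
            out[:, j] = col.astype(np.float64)
            j += 1
    return out


def split_cohort(
    dataset: TabularDataset, fraction: float, seed: int
) -> tuple[TabularDataset, TabularDataset]:
    """Disjoint seeded split; the first part gets round(fraction * n) rows.

    Uses a uniform shuffle followed by a prefix cut, with round-half-up for
    the cut size, so identical seeds give identical partitions.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if dataset.n < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(dataset.n)
    k = int(np.floor(fraction * dataset.n + 0.5))
    return dataset.subset(perm[:k]), dataset.subset(perm[k:])


_FLOAT_FMT = "%.17g"  # exact double-precision round trips


def write_cohort_csv(dataset: TabularDataset, path) -> None:
    """Write a cohort as plain CSV; categoricals serialized as labels."""
    df = dataset.data.copy()
    for f in dataset.schema.features:
        if f.kind == "categorical":
            df[f.name] = [f.categories[i] for i in dataset.column(f.name)]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cohort_csv(path, schema: CohortSchema) -> TabularDataset:
    """Read a cohort CSV previously produced by :func:`write_cohort_csv`.

    Unknown category labels and missing cells are hard errors (imputation
    belongs upstream of this package).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    if list(raw.columns) != schema.names:
        raise SchemaViolationError(
            f"CSV header {list(raw.columns)} does not match schema {schema.names}"
        )
    cols: dict[str, np.ndarray] = {}
    for f in schema.features:
        vals = raw[f.name]
        empty = vals.str.len() == 0
        if empty.any():
            row = int(np.flatnonzero(empty.to_numpy())[0])
            raise MissingDataError(f"missing value at row {row}, column {f.name!r}")
        if f.kind == "continuous":
            cols[f.name] = vals.to_numpy(dtype=np.float64)
        elif f.kind == "binary":
            try:
                cols[f.name] = vals.astype(np.int64).to_numpy()
            except ValueError as exc:
                raise SchemaViolationError(
                    f"non-binary value in column {f.name!r}: {exc}"
                ) from exc
        else:
            lookup = {c: i for i, c in enumerate(f.categories)}
            idx = np.empty(len(vals), dtype=np.int64)
            for i, label in enumerate(vals):
                if label not in lookup:
                    raise SchemaViolationError(
                        f"unknown category label {label!r} at row {i}, "
                        f"column {f.name!r}"
                    )
                idx[i] = lookup[label]
            cols[f.name] = idx
    return TabularDataset(schema, pd.DataFrame(cols, columns=schema.names))
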