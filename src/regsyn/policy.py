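"""The generator as a stochastic policy over mixed-type rows.

A shared-trunk MLP maps a standard-normal noise vector to per-feature
distribution parameters: mean and log-variance for every continuous
feature, a Bernoulli success probability for every binary feature, and a
softmax probability vector for every categorical feature.  Sampling from
those heads produces a synthetic row together with its exact
log-probability, which is what the PPO update needs; the outcome head's
pre-sampling value q(x) — the Bernoulli probability, or the Gaussian mean
for a continuous outcome — is exposed directly for the regression reward.

Everything operates on the normalized scale; denormalization happens only
when a trained generator exports data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nn import MLP
from .schema import CohortSchema, TabularDataset

LOGVAR_CLAMP = (-6.0, 2.0)
PROB_CLAMP = 1e-6
LOGP_FLOOR = -30.0  # finite floor for zero-probability discrete values
_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class PolicyOutput:
    """Per-record head parameters emitted by one forward pass."""

    schema: CohortSchema
    means: np.ndarray        # (n, n_continuous)
    log_vars: np.ndarray     # (n, n_continuous)
    bin_probs: np.ndarray    # (n, n_binary)
    cat_probs: dict[str, np.ndarray]  # name -> (n, n_categories)

    @property
    def n(self) -> int:
        return max(self.means.shape[0], self.bin_probs.shape[0])


@dataclass
class SampledBatch:
    """Rows drawn from a PolicyOutput with their exact log-probabilities."""

    rows: TabularDataset
    log_probs: np.ndarray
    noise: np.ndarray


def _feature_lists(schema: CohortSchema):
    cont = [f.name for f in schema.features if f.kind == "continuous"]
    bins = [f.name for f in schema.features if f.kind == "binary"]
    cats = [f for f in schema.features if f.kind == "categorical"]
    return cont, bins, cats


def log_prob(rows: TabularDataset, policy_out: PolicyOutput) -> np.ndarray:
    """Exact per-row log-probability of ``rows`` under the policy heads.

    The factorized density is the sum over features of the Gaussian
    log-density, Bernoulli log-mass, or categorical log-mass of the stored
    value; discrete log-masses are floored at a finite value so importance
    ratios stay finite.
    """
    cont, bins, cats = _feature_lists(policy_out.schema)
    n = rows.n
    logp = np.zeros(n)
    for j, nm in enumerate(cont):
        x = rows.column(nm)
        mu = policy_out.means[:, j]
        lv = policy_out.log_vars[:, j]
        logp += -_HALF_LOG_2PI - 0.5 * lv - 0.5 * (x - mu) ** 2 * np.exp(-lv)
    for j, nm in enumerate(bins):
        x = rows.column(nm)
        p = policy_out.bin_probs[:, j]
        term = np.where(x == 1, np.log(p), np.log1p(-p))
        logp += np.maximum(term, LOGP_FLOOR)
    for f in cats:
        x = rows.column(f.name)
        p = policy_out.cat_probs[f.name][np.arange(n), x]
        logp += np.maximum(np.log(np.maximum(p, 1e-300)), LOGP_FLOOR)
    return logp


def conditional_outcome(policy_out: PolicyOutput) -> np.ndarray:
    """Pre-sampling conditional outcome q(x) per record.

    Binary outcome: the outcome head's success probability before the
    Bernoulli draw.  Continuous outcome: the mean of the Gaussian outcome
    head before sampling.  Deterministic given the PolicyOutput.
    """
    cont, bins, _ = _feature_lists(policy_out.schema)
    out = policy_out.schema.outcome
    if out.kind == "binary":
        return policy_out.bin_probs[:, bins.index(out.name)].copy()
    return policy_out.means[:, cont.index(out.name)].copy()


class GeneratorPolicy:
    """Noise-to-row policy network with exact per-row log-probabilities."""

    def __init__(
        self,
        schema: CohortSchema,
        noise_dim: int = 128,
        hidden: tuple[int, ...] = (256, 256, 256),
        seed: int = 0,
    ):
        self.schema = schema
        self.noise_dim = noise_dim
        self.hidden = tuple(hidden)
        # deterministic head layout in schema order
        self._cont = [f.name for f in schema.features if f.kind == "continuous"]
        self._bin = [f.name for f in schema.features if f.kind == "binary"]
        self._cat = [f for f in schema.features if f.kind == "categorical"]
        self.raw_dim = 2 * len(self._cont) + len(self._bin) + sum(
            f.n_categories for f in self._cat
        )
        rng = np.random.default_rng(seed)
        self.net = MLP([noise_dim, *hidden, self.raw_dim], rng)

    # -- head decoding ------------------------------------------------------

    def _decode(self, raw: np.ndarray) -> PolicyOutput:
        nc, nb = len(self._cont), len(self._bin)
        means = raw[:, :nc]
        log_vars = np.clip(raw[:, nc : 2 * nc], *LOGVAR_CLAMP)
        logits_b = raw[:, 2 * nc : 2 * nc + nb]
        bin_probs = np.clip(
            1.0 / (1.0 + np.exp(-logits_b)), PROB_CLAMP, 1.0 - PROB_CLAMP
        )
        cat_probs: dict[str, np.ndarray] = {}
        j = 2 * nc + nb
        for f in self._cat:
            k = f.n_categories
            logits = raw[:, j : j + k]
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            cat_probs[f.name] = e / e.sum(axis=1, keepdims=True)
            j += k
        return PolicyOutput(self.schema, means, log_vars, bin_probs, cat_probs)

    def forward_policy(self, noise: np.ndarray) -> PolicyOutput:
        """Map noise rows to per-record head parameters."""
        noise = np.asarray(noise, dtype=np.float64)
        if noise.ndim != 2 or noise.shape[1] != self.noise_dim:
            raise ValueError(
                f"noise must be (n, {self.noise_dim}), got {noise.shape}"
            )
        raw, _ = self.net.forward(noise)
        return self._decode(raw)

    def _forward_with_cache(self, noise: np.ndarray):
        raw, cache = self.net.forward(np.asarray(noise, dtype=np.float64))
        return raw, self._decode(raw), cache

    # -- sampling and log-probabilities --------------------------------------

    def sample_batch(self, policy_out: PolicyOutput, rng: np.random.Generator,
                     noise: np.ndarray | None = None) -> SampledBatch:
        """Draw one row per record from the head distributions."""
        n = policy_out.n
        cols: dict[str, np.ndarray] = {}
        for j, nm in enumerate(self._cont):
            sd = np.exp(0.5 * policy_out.log_vars[:, j])
            cols[nm] = policy_out.means[:, j] + sd * rng.standard_normal(n)
        for j, nm in enumerate(self._bin):
            cols[nm] = (rng.random(n) < policy_out.bin_probs[:, j]).astype(np.int64)
        for f in self._cat:
            p = policy_out.cat_probs[f.name]
            u = rng.random((n, 1))
            cols[f.name] = (p.cumsum(axis=1) < u).sum(axis=1).astype(np.int64)
        rows = TabularDataset(
            self.schema, pd.DataFrame(cols, columns=self.schema.names)
        )
        logp = self.log_prob_of(rows, policy_out)
        if noise is None:
            noise = np.zeros((n, 0))
        return SampledBatch(rows, logp, noise)

    def log_prob_of(self, rows: TabularDataset, policy_out: PolicyOutput) -> np.ndarray:
        """Exact per-row log-probability of ``rows`` under the policy heads."""
        return log_prob(rows, policy_out)

    def log_prob_grad_raw(
        self, rows: TabularDataset, policy_out: PolicyOutput
    ) -> np.ndarray:
        """d log p(row) / d raw-head-outputs, one (raw_dim,) row per record.

        Used by the PPO update: the trainer scales these per-row gradients
        and backpropagates them through the trunk.  Clamped head regions
        (log-variance clamp, probability clamp) get zero gradient, matching
        the clamp used in the forward pass.
        """
        n = rows.n
        nc, nb = len(self._cont), len(self._bin)
        grad = np.zeros((n, self.raw_dim))
        for j, nm in enumerate(self._cont):
            x = rows.column(nm)
            mu = policy_out.means[:, j]
            lv = policy_out.log_vars[:, j]
            inv_var = np.exp(-lv)
            grad[:, j] = (x - mu) * inv_var
            interior = (lv > LOGVAR_CLAMP[0]) & (lv < LOGVAR_CLAMP[1])
            grad[:, nc + j] = (-0.5 + 0.5 * (x - mu) ** 2 * inv_var) * interior
        for j, nm in enumerate(self._bin):
            x = rows.column(nm)
            p = policy_out.bin_probs[:, j]
            interior = (p > PROB_CLAMP) & (p < 1.0 - PROB_CLAMP)
            grad[:, 2 * nc + j] = (x - p) * interior
        j = 2 * nc + nb
        for f in self._cat:
            k = f.n_categories
            p = policy_out.cat_probs[f.name]
            onehot = np.zeros((n, k))
            onehot[np.arange(n), rows.column(f.name)] = 1.0
            grad[:, j : j + k] = onehot - p
            j += k
        return grad

    def conditional_outcome(self, policy_out: PolicyOutput) -> np.ndarray:
        """Pre-sampling conditional outcome q(x) per record (see module fn)."""
        return conditional_outcome(policy_out)

    # -- persistence ---------------------------------------------------------

    def get_state(self):
        return self.net.get_state()

    def set_state(self, state):
        self.net.set_state(state)
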