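"""Alternating PPO training of the generator against the critic reward.

Each training iteration treats one generated row as one single-step
episode: the generator samples a batch, the discriminator scores it, the
regression penalty (when a reference regression is supplied) is added with
its annealed weight, and the generator takes K clipped-surrogate PPO epochs
on the batch.  The discriminator then takes its own update(s) on fresh
generator samples versus a real minibatch.  Because episodes are
single-step there is no value network or discounting; the advantage is the
batch-standardized reward.

The generator only ever sees scalar discriminator scores — never its
gradients — so any computable reward can be swapped in without touching the
architecture.  With the penalty weight at zero the loop is exactly the
base discriminator-only procedure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .critic import Discriminator
from .nn import Adam
from .policy import GeneratorPolicy, PolicyOutput, log_prob
from .reward import (
    ReferenceRegression,
    RewardSchedule,
    anneal_weight,
    fit_reference_regression,
    reference_predict,
    regression_penalty,
    total_reward,
)
from .schema import (
    CohortSchema,
    Normalizer,
    SchemaViolationError,
    TabularDataset,
    denormalize,
    encode_one_hot,
    normalize,
)

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class TrainingConfig:
    """All knobs of one training run; defaults suit small CPU cohorts."""

    iterations: int = 1000
    batch_size: int = 512
    gen_lr: float = 1e-4
    disc_lr: float = 1e-4
    clip_eps: float = 0.2
    ppo_epochs: int = 4
    disc_updates_per_gen: int = 1
    r1_gamma: float = 1.0
    schedule: RewardSchedule = field(default_factory=RewardSchedule)
    gen_hidden: tuple[int, ...] = (256, 256, 256)
    disc_hidden: tuple[int, ...] = (256, 256, 256)
    noise_dim: int = 128
    seed: int = 0
    checkpoint_every: int | None = None  # default: iterations // 20

    def __post_init__(self) -> None:
        if min(self.iterations, self.batch_size, self.ppo_epochs,
               self.disc_updates_per_gen) < 1:
            raise ValueError("iterations, batch size, epochs, ratio must be >= 1")
        if not 0.0 < self.clip_eps < 1.0:
            raise ValueError("clip_eps must lie in (0, 1)")
        if min(self.gen_lr, self.disc_lr) <= 0 or self.r1_gamma < 0:
            raise ValueError("learning rates must be positive, gamma >= 0")


@dataclass
class TrainingLog:
    """Per-iteration scalars; one entry per generator iteration."""

    iteration: list[int] = field(default_factory=list)
    mean_realism: list[float] = field(default_factory=list)
    mean_penalty: list[float] = field(default_factory=list)
    lam_t: list[float] = field(default_factory=list)
    mean_reward: list[float] = field(default_factory=list)
    critic_loss: list[float] = field(default_factory=list)
    surrogate_loss: list[float] = field(default_factory=list)
    checkpoints: list[int] = field(default_factory=list)

    def append(self, t, realism, penalty, lam, reward, closs, sloss) -> None:
        vals = (realism, penalty, lam, reward, closs, sloss)
        if not all(np.isfinite(v) for v in vals):
            raise RuntimeError(
                f"non-finite training statistic at iteration {t}: {vals}"
            )
        self.iteration.append(t)
        self.mean_realism.append(realism)
        self.mean_penalty.append(penalty)
        self.lam_t.append(lam)
        self.mean_reward.append(reward)
        self.critic_loss.append(closs)
        self.surrogate_loss.append(sloss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": self.iteration,
                "mean_realism": self.mean_realism,
                "mean_penalty": self.mean_penalty,
                "lam_t": self.lam_t,
                "mean_reward": self.mean_reward,
                "critic_loss": self.critic_loss,
                "surrogate_loss": self.surrogate_loss,
            }
        )


def compute_advantages(rewards: np.ndarray) -> np.ndarray:
    """Batch-standardized rewards: (r - mean) / (population sd + 1e-8)."""
    r = np.asarray(rewards, dtype=np.float64)
    if r.size == 0:
        raise ValueError("empty reward batch")
    return (r - r.mean()) / (r.std() + 1e-8)


def _ppo_objective(ratios: np.ndarray, advantages: np.ndarray,
                   eps: float) -> np.ndarray:
    """Per-row clipped surrogate min(rho*A, clip(rho, 1-eps, 1+eps)*A)."""
    clipped = np.clip(ratios, 1.0 - eps, 1.0 + eps)
    return np.minimum(ratios * advantages, clipped * advantages)


def ppo_generator_loss(
    rows: TabularDataset,
    old_log_probs: np.ndarray,
    advantages: np.ndarray,
    policy_out: PolicyOutput,
    eps: float,
) -> float:
    """Negative mean clipped surrogate of ``rows`` under ``policy_out``."""
    new_logp = log_prob(rows, policy_out)
    ratios = np.exp(new_logp - np.asarray(old_log_probs))
    if not np.all(np.isfinite(ratios)):
        raise RuntimeError("non-finite PPO probability ratio")
    return float(-np.mean(_ppo_objective(ratios, np.asarray(advantages), eps)))


@dataclass
class TrainResult:
    generator: GeneratorPolicy
    discriminator: Discriminator
    log: TrainingLog
    config: TrainingConfig


def train(
    real_train: TabularDataset,
    config: TrainingConfig,
    reference: ReferenceRegression | None = None,
) -> TrainResult:
    """Run the alternating PPO loop on a (normalized) training cohort.

    ``reference`` switches on the regression-aligned reward; without it the
    loop is the base discriminator-only procedure (identically, the
    lambda_t = 0 path).
    """
    schema = real_train.schema
    ss = np.random.SeedSequence(config.seed)
    gen_seed, disc_seed, loop_seed = (int(s.generate_state(1)[0] % (2**31))
                                      for s in ss.spawn(3))
    gen = GeneratorPolicy(schema, config.noise_dim, config.gen_hidden, gen_seed)
    disc = Discriminator(schema.encoded_width, config.disc_hidden, disc_seed)
    rng = np.random.default_rng(loop_seed)
    gen_opt = Adam(gen.net.param_shapes(), lr=config.gen_lr)
    disc_opt = Adam(disc.net.param_shapes(), lr=config.disc_lr)
    real_enc = encode_one_hot(real_train)
    log = TrainingLog()
    B = config.batch_size
    ckpt_every = config.checkpoint_every or max(1, config.iterations // 20)

    for t in range(config.iterations):
        # --- generator rollout -------------------------------------------
        noise = rng.standard_normal((B, config.noise_dim))
        po = gen.forward_policy(noise)
        batch = gen.sample_batch(po, rng, noise)
        enc = encode_one_hot(batch.rows)
        realism = disc.score_rows(enc).scores
        lam_t = anneal_weight(t, config.schedule)
        if reference is not None:
            q = gen.conditional_outcome(po)
            f = reference_predict(reference, batch.rows)
            penalty = regression_penalty(q, f)
        else:
            penalty = np.zeros(B)
        breakdown = total_reward(realism, penalty, lam_t)
        adv = compute_advantages(breakdown.total)
        old_logp = batch.log_probs

        # --- K PPO epochs on this batch ----------------------------------
        surrogate = float("nan")
        for k in range(config.ppo_epochs):
            raw, po_k, cache = gen._forward_with_cache(noise)
            new_logp = log_prob(batch.rows, po_k)
            ratios = np.exp(new_logp - old_logp)
            if not np.all(np.isfinite(ratios)):
                raise RuntimeError(f"non-finite PPO ratio at iteration {t}")
            if k == 0:
                surrogate = float(
                    -np.mean(_ppo_objective(ratios, adv, config.clip_eps))
                )
            active = (
                (ratios * adv <= np.clip(ratios, 1 - config.clip_eps,
                                         1 + config.clip_eps) * adv)
                | ((ratios >= 1 - config.clip_eps) & (ratios <= 1 + config.clip_eps))
            )
            weight = np.where(active, adv * ratios, 0.0)
            dlogp_raw = gen.log_prob_grad_raw(batch.rows, po_k)
            dloss_raw = -(weight[:, None] * dlogp_raw) / B
            grads, _ = gen.net.backward(cache, dloss_raw)
            gen_opt.step(gen.net.params, grads)

        # --- discriminator updates ---------------------------------------
        closs = float("nan")
        for _ in range(config.disc_updates_per_gen):
            d_noise = rng.standard_normal((B, config.noise_dim))
            d_po = gen.forward_policy(d_noise)
            d_batch = gen.sample_batch(d_po, rng, d_noise)
            synth_enc = encode_one_hot(d_batch.rows)
            idx = rng.integers(0, real_enc.shape[0], size=B)
            closs, dgrads = disc._loss_and_grads(
                real_enc[idx], synth_enc, config.r1_gamma
            )
            disc_opt.step(disc.net.params, dgrads)

        log.append(
            t,
            float(realism.mean()),
            float(penalty.mean()),
            lam_t,
            float(breakdown.total.mean()),
            closs,
            surrogate,
        )
        if (t + 1) % ckpt_every == 0 or t + 1 == config.iterations:
            log.checkpoints.append(t)

    return TrainResult(gen, disc, log, config)


def generate(
    generator: GeneratorPolicy,
    n: int,
    seed: int,
    normalizer: Normalizer | None = None,
    batch: int = 4096,
) -> TabularDataset:
    """Sample n synthetic rows; denormalized when a normalizer is given."""
    rng = np.random.default_rng(seed)
    parts = []
    remaining = n
    while remaining > 0:
        m = min(batch, remaining)
        noise = rng.standard_normal((m, generator.noise_dim))
        po = generator.forward_policy(noise)
        parts.append(generator.sample_batch(po, rng, noise).rows.data)
        remaining -= m
    if parts:
        data = pd.concat(parts, ignore_index=True)
    else:
        data = pd.DataFrame(
            {nm: np.zeros(0) for nm in generator.schema.names},
            columns=generator.schema.names,
        )
    ds = TabularDataset(generator.schema, data)
    if normalizer is not None:
        ds = denormalize(ds, normalizer)
    return ds


# --- checkpointing ----------------------------------------------------------


def save_checkpoint(
    path,
    generator: GeneratorPolicy,
    discriminator: Discriminator | None = None,
    normalizer: Normalizer | None = None,
) -> None:
    """Write a versioned checkpoint (schema fingerprint + shapes + weights)."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "schema": generator.schema.to_dict(),
        "fingerprint": generator.schema.fingerprint,
        "noise_dim": generator.noise_dim,
        "gen_hidden": list(generator.hidden),
        "disc_hidden": list(discriminator.net.sizes[1:-1]) if discriminator else None,
        "normalizer": (
            {
                "location": normalizer.location,
                "scale": normalizer.scale,
                "schema_fingerprint": normalizer.schema_fingerprint,
            }
            if normalizer
            else None
        ),
    }
    arrays = {f"gen_{i}": p for i, p in enumerate(generator.get_state())}
    if discriminator is not None:
        arrays.update(
            {f"disc_{i}": p for i, p in enumerate(discriminator.get_state())}
        )
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path, schema: CohortSchema | None = None):
    """Load a checkpoint; refuses when the schema fingerprint mismatches.

    Returns ``(generator, discriminator_or_None, normalizer_or_None)``.
    """
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise SchemaViolationError(
                f"unsupported checkpoint version {meta.get('version')}"
            )
        ckpt_schema = CohortSchema.from_dict(meta["schema"])
        if schema is not None and schema.fingerprint != meta["fingerprint"]:
            raise SchemaViolationError(
                "checkpoint schema fingerprint does not match the provided schema"
            )
        gen = GeneratorPolicy(
            ckpt_schema, meta["noise_dim"], tuple(meta["gen_hidden"]), seed=0
        )
        gen.set_state([z[f"gen_{i}"] for i in range(len(gen.net.params))])
        disc = None
        if meta["disc_hidden"] is not None:
            disc = Discriminator(
                ckpt_schema.encoded_width, tuple(meta["disc_hidden"]), seed=0
            )
            disc.set_state([z[f"disc_{i}"] for i in range(len(disc.net.params))])
        norm = None
        if meta["normalizer"] is not None:
            nm = meta["normalizer"]
            norm = Normalizer(nm["location"], nm["scale"], nm["schema_fingerprint"])
    return gen, disc, norm


# --- convenience pipeline ---------------------------------------------------


def run_pipeline(
    real_train: TabularDataset,
    config: TrainingConfig,
    covariates: list[str] | None = None,
    use_reward: bool = False,
    n_synth: int | None = None,
):
    """Normalize, (optionally) fit the reference regression, train, export.

    Returns ``(synth, result, reference)`` with ``synth`` on the original
    scale.  This is the end-to-end path the CLI and the sensitivity sweep
    use.
    """
    norm_train, norm = normalize(real_train)
    reference = None
    if use_reward:
        if covariates is None:
            covariates = [f.name for f in real_train.schema.covariates]
        kind = (
            "logistic"
            if real_train.schema.outcome.kind == "binary"
            else "linear"
        )
        reference = fit_reference_regression(norm_train, covariates, kind)
    result = train(norm_train, config, reference)
    n_out = n_synth if n_synth is not None else real_train.n
    synth = generate(result.generator, n_out, seed=config.seed + 1, normalizer=norm)
    return synth, result, reference
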