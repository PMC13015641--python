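"""The discriminator as a critic supplying the realism reward.

A leaky-ReLU MLP scores one-hot-encoded, normalized rows with a scalar
logit D(x); the realism score sigma(D(x)) in (0, 1) is the base reward the
generator receives.  The critic trains with binary cross-entropy (real
labelled 1, synthetic 0) plus the R1 gradient penalty
(gamma/2) * E_real ||d D / d x||^2, which is evaluated on real rows only
and smooths the decision boundary so the reward signal stays stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import MLP


def _sigmoid(t: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-t))


def _softplus(t: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, t)


@dataclass
class CriticScore:
    """Per-row logit and realism score; score = sigmoid(logit) exactly."""

    logits: np.ndarray
    scores: np.ndarray


class Discriminator:
    """Scalar realism critic over the one-hot encoded representation."""

    def __init__(
        self,
        encoded_width: int,
        hidden: tuple[int, ...] = (256, 256, 256),
        seed: int = 0,
        zero_output_init: bool = False,
    ):
        self.encoded_width = encoded_width
        rng = np.random.default_rng(seed)
        self.net = MLP([encoded_width, *hidden, 1], rng,
                       zero_output_init=zero_output_init)

    def _check_width(self, rows: np.ndarray) -> np.ndarray:
        rows = np.asarray(rows, dtype=np.float64)
        if rows.ndim != 2 or rows.shape[1] != self.encoded_width:
            raise ValueError(
                f"encoded rows must be (n, {self.encoded_width}), got {rows.shape}"
            )
        return rows

    def score_rows(self, encoded_rows: np.ndarray) -> CriticScore:
        """Score rows; realism = sigmoid(logit), strictly inside (0, 1)."""
        rows = self._check_width(encoded_rows)
        logits = self.net(rows)[:, 0]
        return CriticScore(logits, _sigmoid(logits))

    def r1_penalty(self, real_rows: np.ndarray, gamma: float) -> float:
        """(gamma/2) * mean over real rows of ||grad_x D(x)||^2."""
        rows = self._check_width(real_rows)
        if rows.shape[0] == 0:
            raise ValueError("r1_penalty needs a non-empty real batch")
        if gamma == 0.0:
            return 0.0
        _, cache = self.net.forward(rows)
        penalty, _ = self.net.r1_grads(cache)
        return 0.5 * gamma * penalty

    def critic_loss(self, real_rows: np.ndarray, synth_rows: np.ndarray,
                    gamma: float) -> float:
        """Mean BCE (real=1, synthetic=0) plus the R1 penalty on real rows."""
        loss, _ = self._loss_and_grads(real_rows, synth_rows, gamma)
        return loss

    def _loss_and_grads(self, real_rows: np.ndarray, synth_rows: np.ndarray,
                        gamma: float):
        """Loss value and parameter gradients for one critic update."""
        real = self._check_width(real_rows)
        synth = self._check_width(synth_rows)
        if real.shape[0] == 0 or synth.shape[0] == 0:
            raise ValueError("critic_loss needs non-empty real and synthetic batches")
        n_r, n_s = real.shape[0], synth.shape[0]
        n = n_r + n_s
        out_r, cache_r = self.net.forward(real)
        out_s, cache_s = self.net.forward(synth)
        # BCE with logits: real -> softplus(-D), synthetic -> softplus(D)
        loss = float(
            (_softplus(-out_r[:, 0]).sum() + _softplus(out_s[:, 0]).sum()) / n
        )
        d_r = (_sigmoid(out_r) - 1.0) / n
        d_s = _sigmoid(out_s) / n
        grads_r, _ = self.net.backward(cache_r, d_r)
        grads_s, _ = self.net.backward(cache_s, d_s)
        grads = [gr + gs for gr, gs in zip(grads_r, grads_s)]
        if gamma > 0.0:
            r1_val, r1_g = self.net.r1_grads(cache_r)
            loss += 0.5 * gamma * r1_val
            grads = [g + 0.5 * gamma * rg for g, rg in zip(grads, r1_g)]
        return loss, grads

    def get_state(self):
        return self.net.get_state()

    def set_state(self, state):
        self.net.set_state(state)
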