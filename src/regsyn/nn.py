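"""Minimal feed-forward network machinery with explicit gradients.

Both networks in this package are small leaky-ReLU multi-layer perceptrons
trained on CPU, so the forward pass, backpropagation, the input gradient,
and the second-order R1 term are written out directly in numpy.  All
gradients here are checked against finite differences in the test suite.

The only non-textbook piece is :meth:`MLP.r1_grads`: the R1 regularizer
penalizes ``mean_rows ||d D / d x||^2`` for a scalar-output network, and its
parameter gradient requires differentiating through the input gradient.
For a piecewise-linear activation the activation slopes are locally
constant, so with ``s_l`` the slope diagonals the input gradient is the
linear map ``g = W_1^T S_1 W_2^T S_2 ... w_out`` and the gradient of
``||g||^2`` with respect to ``W_l`` is the outer product ``2 u_l s~_{l-1}^T``
of a backward vector ``u_l = S_l W_{l+1}^T u_{l+1}`` and a forward
re-propagation ``s~_l = S_l W_l s~_{l-1}`` seeded with ``s~_0 = g``.
Bias gradients vanish almost everywhere, exactly as under automatic
differentiation.
"""

from __future__ import annotations

import numpy as np


class NumericalFailure(RuntimeError):
    """Non-finite values encountered in a network computation."""


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, shapes, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class MLP:
    """Leaky-ReLU multi-layer perceptron with a linear output layer.

    ``sizes = [d_in, h_1, ..., h_L, d_out]``; ``L`` may be zero, giving a
    pure linear map.  Weights use He initialization; ``zero_output_init``
    starts the output layer at zero (an untrained critic then scores
    everything identically).
    """

    def __init__(self, sizes, rng: np.random.Generator, leaky_slope: float = 0.2,
                 zero_output_init: bool = False):
        self.sizes = list(sizes)
        self.slope = leaky_slope
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for d_in, d_out in zip(sizes[:-1], sizes[1:]):
            w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_out, d_in))
            self.weights.append(w)
            self.biases.append(np.zeros(d_out))
        if zero_output_init:
            self.weights[-1][:] = 0.0

    # -- parameter plumbing -------------------------------------------------

    @property
    def params(self) -> list[np.ndarray]:
        out = []
        for w, b in zip(self.weights, self.biases):
            out.extend((w, b))
        return out

    def param_shapes(self):
        return [p.shape for p in self.params]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[:] = s

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray):
        """Return (output, cache); cache feeds backward() and r1_grads()."""
        h = np.asarray(x, dtype=np.float64)
        acts = [h]
        slopes = []
        n_hidden = len(self.weights) - 1
        for l in range(n_hidden):
            pre = h @ self.weights[l].T + self.biases[l]
            s = np.where(pre > 0.0, 1.0, self.slope)
            h = np.where(pre > 0.0, pre, self.slope * pre)
            slopes.append(s)
            acts.append(h)
        out = h @ self.weights[-1].T + self.biases[-1]
        if not np.all(np.isfinite(out)):
            raise NumericalFailure("non-finite network output")
        return out, {"acts": acts, "slopes": slopes}

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(self, cache, dout: np.ndarray):
        """Backpropagate ``dout`` (n, d_out); return (param grads, dx)."""
        acts, slopes = cache["acts"], cache["slopes"]
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        delta = np.asarray(dout, dtype=np.float64)
        grads_w[-1] = delta.T @ acts[-1]
        grads_b[-1] = delta.sum(axis=0)
        dh = delta @ self.weights[-1]
        for l in range(len(slopes) - 1, -1, -1):
            dpre = dh * slopes[l]
            grads_w[l] = dpre.T @ acts[l]
            grads_b[l] = dpre.sum(axis=0)
            dh = dpre @ self.weights[l]
        flat = []
        for gw, gb in zip(grads_w, grads_b):
            flat.extend((gw, gb))
        return flat, dh

    def input_gradient(self, cache) -> np.ndarray:
        """Per-row gradient of the scalar output with respect to the input."""
        if self.sizes[-1] != 1:
            raise ValueError("input_gradient requires a scalar-output network")
        slopes = cache["slopes"]
        v = np.broadcast_to(self.weights[-1][0], (cache["acts"][0].shape[0],
                                                  self.sizes[-2])).copy()
        for l in range(len(slopes) - 1, -1, -1):
            u = slopes[l] * v
            v = u @ self.weights[l]
        return v

    def r1_grads(self, cache):
        """Value and parameter gradient of ``mean_rows ||dD/dx||^2``.

        Returns ``(penalty_mean, grads)`` with grads aligned to ``params``.
        """
        if self.sizes[-1] != 1:
            raise ValueError("r1_grads requires a scalar-output network")
        slopes = cache["slopes"]
        n = cache["acts"][0].shape[0]
        # backward pass: u_l for every layer, input gradient g
        v = np.broadcast_to(self.weights[-1][0], (n, self.sizes[-2])).copy()
        us: list[np.ndarray] = [None] * len(slopes)
        for l in range(len(slopes) - 1, -1, -1):
            us[l] = slopes[l] * v
            v = us[l] @ self.weights[l]
        g = v
        penalty = float(np.mean(np.sum(g * g, axis=1)))
        # forward re-propagation of g through the linearized network
        stils = [g]
        for l in range(len(slopes)):
            stils.append(slopes[l] * (stils[-1] @ self.weights[l].T))
        grads = []
        for l in range(len(slopes)):
            gw = (2.0 / n) * (us[l].T @ stils[l])
            grads.extend((gw, np.zeros_like(self.biases[l])))
        gw_out = (2.0 / n) * stils[-1].sum(axis=0)[None, :]
        grads.extend((gw_out, np.zeros_like(self.biases[-1])))
        return penalty, grads
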