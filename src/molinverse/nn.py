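"""Minimal dense-network machinery: MLPs with explicit gradients and Adam.

The encoder, decoder and property encoder of the inverse-mapping model are
small multilayer perceptrons, so this module implements exactly what they
need and nothing more: batched forward passes, reverse-mode backprop
(vector-Jacobian products for training and for the geodesic optimizer),
forward-mode Jacobians (for attribution maps), and the Adam update rule.
Everything is plain float64 NumPy and fully deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np


def tanh(x):
    return np.tanh(x)


def tanh_deriv(activation):
    # derivative expressed through the activation value: 1 - tanh(x)^2
    return 1.0 - activation ** 2


class MLP:
    """Fully connected network with tanh hidden layers and a linear output.

    Parameters are stored as ``weights``/``biases`` lists. Initialization is
    Glorot-style normal, drawn from the supplied Generator so that model
    construction is reproducible.
    """

    def __init__(self, sizes, rng: np.random.Generator):
        if len(sizes) < 2:
            raise ValueError("need at least input and output sizes")
        self.sizes = tuple(int(s) for s in sizes)
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(self.sizes[:-1], self.sizes[1:]):
            scale = np.sqrt(2.0 / (fan_in + fan_out))
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self):
        return self.weights + self.biases

    def set_params(self, params):
        n = len(self.weights)
        self.weights = [np.asarray(p, dtype=float) for p in params[:n]]
        self.biases = [np.asarray(p, dtype=float) for p in params[n:]]

    # -- forward / backward -------------------------------------------------
    def forward(self, x, want_cache=False):
        """Batched forward pass. x: (batch, in). Returns output (+ cache)."""
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim == 1
        if squeeze:
            x = x[None, :]
        if np.any(~np.isfinite(x)):
            raise ValueError("non-finite network input")
        activations = [x]
        h = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i != last:
                h = tanh(h)
            activations.append(h)
        out = h[0] if squeeze else h
        if want_cache:
            return out, activations
        return out

    def backward(self, cache, grad_out):
        """Reverse-mode pass.

        ``cache`` is the activations list from ``forward(..., want_cache=True)``
        and ``grad_out`` the loss gradient at the output (batch, out). Returns
        ``(grad_input, grads)`` where ``grads`` matches ``self.params`` and sums
        over the batch.
        """
        grad = np.asarray(grad_out, dtype=float)
        if grad.ndim == 1:
            grad = grad[None, :]
        w_grads = [None] * len(self.weights)
        b_grads = [None] * len(self.biases)
        last = len(self.weights) - 1
        for i in range(last, -1, -1):
            if i != last:
                grad = grad * tanh_deriv(cache[i + 1])
            w_grads[i] = cache[i].T @ grad
            b_grads[i] = grad.sum(axis=0)
            grad = grad @ self.weights[i].T
        return grad, w_grads + b_grads

    def jacobian(self, x):
        """Forward-mode Jacobian d out / d x at a single input. Shape (out, in)."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 1:
            raise ValueError("jacobian expects a single input vector")
        jac = np.eye(x.size)
        h = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            pre = h @ w + b
            jac = jac @ w
            if i != last:
                h = tanh(pre)
                jac = jac * tanh_deriv(h)[None, :]
            else:
                h = pre
        return jac.T


class Adam:
    """Adam optimizer over a flat list of parameter arrays (in-place updates)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
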