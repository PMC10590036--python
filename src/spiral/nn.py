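"""Minimal dense-network primitives: activations, initialisation, Adam, GRL.

The integration model is small (two graph layers, two dense heads), so its
forward and backward passes are written directly against these primitives
rather than through an autodiff framework.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sigmoid",
    "log_sigmoid",
    "relu",
    "softmax",
    "glorot_uniform",
    "Adam",
    "GradientReversal",
    "gradient_reversal",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # evaluated via exp of log-sigmoid for overflow safety on both tails
    return np.exp(log_sigmoid(x))


def log_sigmoid(x: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -np.asarray(x, dtype=float))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    shifted = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class GradientReversal:
    """Identity in the forward pass; negates the gradient in the backward pass.

    Placing this in front of the batch discriminator turns its minimisation
    into adversarial training of the encoder: the encoder receives the
    negated discriminator gradient, pushing the biology embedding toward
    batch indistinguishability.
    """

    def forward(self, v: np.ndarray) -> np.ndarray:
        return v

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return -grad

    def __call__(self, v: np.ndarray) -> np.ndarray:
        return self.forward(v)


def gradient_reversal(v: np.ndarray) -> np.ndarray:
    """Forward pass of the GRL (identity). See :class:`GradientReversal`."""
    return GradientReversal().forward(v)


class Adam:
    """Adam with (coupled) L2 weight decay added to the gradient."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 weight_decay: float = 0.0, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, g in grads.items():
            p = self.params[key]
            if self.weight_decay:
                g = g + self.weight_decay * p
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1**self.t)
            vhat = self.v[key] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
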