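"""Loss and optimizer for fine-tuning the backbones."""

from __future__ import annotations

import numpy as np

from .layers import Param


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9) -> None:
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
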