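"""Elementwise activations and the softmax cross-entropy loss.

These are the scalar building blocks of the network: the rectified linear
activation f(u) = max{0, u}, the softmax output y_k = e^{u_k} / sum_j e^{u_j}
giving class probabilities, and the cross-entropy E = -sum_n sum_k t_{n,k}
log y_{n,k} minimised during training.
"""

from __future__ import annotations

import numpy as np

__all__ = ["relu", "softmax", "cross_entropy"]

_LOG_EPS = 1e-12


def relu(u):
    """Rectified linear unit, max{0, u}, elementwise."""
    return np.maximum(0.0, np.asarray(u, dtype=float))


def softmax(u: np.ndarray, axis: int = -1) -> np.ndarray:
    """Softmax class probabilities along ``axis``.

    Computed with max-subtraction so arbitrarily large logits do not
    overflow; the result is invariant under adding a constant to all logits.
    """
    u = np.asarray(u, dtype=float)
    shifted = u - np.max(u, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=axis, keepdims=True)


def cross_entropy(
    y: np.ndarray, t: np.ndarray, reduction: str = "sum"
) -> float:
    """Cross entropy between predicted probabilities and one-hot targets.

    ``reduction="sum"`` gives the summed-over-instances form
    E = -sum_n sum_k t_{n,k} log y_{n,k}; ``"mean"`` divides by the number
    of instances (the per-instance variant used in training history
    records). Logs are clamped at a small epsilon.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    t = np.atleast_2d(np.asarray(t, dtype=float))
    if y.shape != t.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs t {t.shape}")
    total = -float(np.sum(t * np.log(np.clip(y, _LOG_EPS, None))))
    if reduction == "sum":
        return total
    if reduction == "mean":
        return total / y.shape[0]
    raise ValueError(f"unknown reduction {reduction!r}")
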