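"""The LeNet-style layer stack and its training machinery.

Architecture (fixed order):

    conv 5x5 x 20 -> ReLU -> pool 2x2 -> conv 5x5 x 50 -> ReLU -> pool 2x2
    -> flatten -> dense 500 -> ReLU -> dense K -> softmax

Convolutions are unpadded with stride 1; pooling is 2x2 stride 2 with floor
semantics, degenerating to identity on a 1x1 map so the stack remains
well-defined down to 14-pixel tiles (flatten size 50). For 28-pixel input
the spatial trace is 24 -> 12 -> 8 -> 4 and the flatten size is
4*4*50 = 800.

Training minimises the softmax cross entropy by mini-batch stochastic
gradient descent with momentum; the per-batch loss gradient is averaged
over the batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .functional import softmax
from .layers import Conv2D, Dense, Flatten, Pool2x2, ReLULayer

__all__ = ["LayerSpec", "NetworkSpec", "build_lenet", "LeNetNetwork", "SGDMomentum"]

CONV_KERNEL = 5
CONV1_FILTERS = 20
CONV2_FILTERS = 50
FC_HIDDEN = 500


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # convolution | pooling | fully_connected | softmax_output
    filter_size: int | None
    n_outputs: int | None
    input_shape: tuple
    output_shape: tuple


@dataclass(frozen=True)
class NetworkSpec:
    input_size: int
    in_channels: int
    n_classes: int
    pooling: str
    layers: tuple[LayerSpec, ...] = field(default_factory=tuple)

    @property
    def flatten_size(self) -> int:
        for spec in self.layers:
            if spec.kind == "fully_connected":
                return int(spec.input_shape[0])
        raise RuntimeError("no fully connected layer in spec")


def _pool_out(s: int) -> int:
    return s if s < 2 else s // 2


def build_lenet(
    input_size: int,
    in_channels: int = 3,
    n_classes: int = 2,
    pooling: str = "max",
) -> NetworkSpec:
    """Compute the layer stack and per-layer shapes for a given tile size.

    Raises ``ValueError`` naming the offending layer if a convolution would
    produce a feature map smaller than 1x1.
    """
    layers: list[LayerSpec] = []
    s, c = input_size, in_channels
    for name, f in (("convolution 1", CONV1_FILTERS), ("convolution 2", CONV2_FILTERS)):
        out = s - CONV_KERNEL + 1
        if out < 1:
            raise ValueError(
                f"{name}: input {s}x{s} too small for a valid "
                f"{CONV_KERNEL}x{CONV_KERNEL} convolution"
            )
        layers.append(LayerSpec("convolution", CONV_KERNEL, f, (c, s, s), (f, out, out)))
        s, c = out, f
        pooled = _pool_out(s)
        layers.append(LayerSpec("pooling", 2, None, (c, s, s), (c, pooled, pooled)))
        s = pooled
    flat = c * s * s
    layers.append(LayerSpec("fully_connected", None, FC_HIDDEN, (flat,), (FC_HIDDEN,)))
    layers.append(LayerSpec("fully_connected", None, n_classes, (FC_HIDDEN,), (n_classes,)))
    layers.append(LayerSpec("softmax_output", None, n_classes, (n_classes,), (n_classes,)))
    return NetworkSpec(
        input_size=input_size,
        in_channels=in_channels,
        n_classes=n_classes,
        pooling=pooling,
        layers=tuple(layers),
    )


class LeNetNetwork:
    """A concrete network instantiated from a :class:`NetworkSpec`.

    Holds the layer objects with their weights; forward yields logits,
    ``backward_from_probs`` propagates the averaged softmax cross-entropy
    gradient ``(y - t)/N`` and fills each layer's ``.grads``.
    """

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        self.layers: list = []
        for ls in spec.layers:
            if ls.kind == "convolution":
                self.layers.append(
                    Conv2D(ls.input_shape[0], ls.n_outputs, ls.filter_size, rng, dtype)
                )
                self.layers.append(ReLULayer())
            elif ls.kind == "pooling":
                self.layers.append(Pool2x2(spec.pooling))
            elif ls.kind == "fully_connected":
                if not any(isinstance(l, Flatten) for l in self.layers):
                    self.layers.append(Flatten())
                self.layers.append(Dense(ls.input_shape[0], ls.n_outputs, rng, dtype))
                if ls.n_outputs != spec.n_classes:
                    self.layers.append(ReLULayer())
            # softmax_output is applied functionally, not a stored layer

    @property
    def param_layers(self):
        return [l for l in self.layers if l.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x.astype(self.dtype, copy=False)
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x), axis=1)

    def backward_from_probs(self, probs: np.ndarray, targets: np.ndarray) -> None:
        n = probs.shape[0]
        grad = ((probs - targets) / n).astype(self.dtype)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)


class SGDMomentum:
    """Plain SGD with classical momentum: v <- mu v - lr g; w <- w + v."""

    def __init__(self, network: LeNetNetwork, learning_rate: float, momentum: float):
        self.lr = learning_rate
        self.momentum = momentum
        self.network = network
        self.velocities = [
            [np.zeros_like(p) for p in layer.params] for layer in network.param_layers
        ]

    def step(self) -> None:
        for layer, vels in zip(self.network.param_layers, self.velocities):
            for p, g, v in zip(layer.params, layer.grads, vels):
                v *= self.momentum
                v -= self.lr * g
                p += v
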