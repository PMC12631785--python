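"""Linear layers and MLPs on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Linear:
    """Affine map with fixed-seed uniform fan-in initialization."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(in_dim)
        self.weight = Tensor(rng.uniform(-bound, bound, (in_dim, out_dim)),
                             requires_grad=True)
        self.bias = Tensor(rng.uniform(-bound, bound, out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class MLP:
    """Two-layer (by default) MLP with SiLU activations between layers."""

    def __init__(self, dims: list[int], rng: np.random.Generator,
                 final_activation: bool = False):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.final_activation = final_activation

    def __call__(self, x: Tensor) -> Tensor:
        for k, layer in enumerate(self.layers):
            x = layer(x)
            if k < len(self.layers) - 1 or self.final_activation:
                x = x.silu()
        return x

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]


def dropout_mask(shape, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return np.ones(shape)
    keep = rng.random(shape) >= rate
    return keep / (1.0 - rate)
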