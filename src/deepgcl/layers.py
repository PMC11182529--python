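"""Dense layers shared by the prediction heads and the fusion trainer."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Linear:
    def __init__(
        self,
        rng: np.random.Generator,
        in_dim: int,
        out_dim: int,
        bias: bool = True,
    ):
        limit = np.sqrt(6.0 / (in_dim + out_dim))
        self.weight = ad.parameter(rng.uniform(-limit, limit, size=(in_dim, out_dim)))
        self.bias = ad.parameter(np.zeros((1, out_dim), dtype=np.float32)) if bias else None
        self.in_dim = in_dim
        self.out_dim = out_dim

    def parameters(self) -> list[Tensor]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_dim:
            raise ValueError(f"expected input width {self.in_dim}, got {x.shape[-1]}")
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class MLPHead:
    """Two-layer MLP with sigmoid output used by all three prediction heads."""

    def __init__(
        self,
        rng: np.random.Generator,
        in_dim: int,
        hidden: int = 64,
        dropout: float = 0.2,
    ):
        self.fc1 = Linear(rng, in_dim, hidden)
        self.fc2 = Linear(rng, hidden, 1)
        self.dropout = dropout

    def parameters(self) -> list[Tensor]:
        return self.fc1.parameters() + self.fc2.parameters()

    def __call__(
        self,
        x: Tensor,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        h = ad.relu(self.fc1(x))
        if training and self.dropout > 0:
            if rng is None:
                raise ValueError("training-mode head needs an rng for dropout")
            keep = rng.random(h.shape, dtype=np.float32) >= self.dropout
            h = h * Tensor(keep.astype(h.data.dtype) / (1.0 - self.dropout))
        return ad.sigmoid(self.fc2(h))
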