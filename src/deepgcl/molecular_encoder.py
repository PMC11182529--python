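"""Shared-weight GCN encoder for the two drugs' molecular graphs.

Both drugs of a pair are encoded by the *same* weight matrices (the two
branches hold references to one parameter set), pooled by column-wise
max, and concatenated into the 256-wide structure embedding.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data_io import ATOM_FEATURE_DIM, MolGraph
from .layers import MLPHead
from .subgraph_encoder import GCNStack, normalize_adjacency

DEFAULT_MOL_WIDTHS = (ATOM_FEATURE_DIM, 156, 128)


class SharedGCNStack(GCNStack):
    """GCN stack whose weights are shared by both drug branches.

    A single instance is applied to both molecules; sharing is by object
    identity rather than by copying.
    """

    @classmethod
    def init(
        cls,
        rng: np.random.Generator,
        widths: Sequence[int] = DEFAULT_MOL_WIDTHS,
        dropout: float = 0.2,
    ) -> "SharedGCNStack":
        base = GCNStack.init(rng, widths, dropout)
        return cls(widths=base.widths, dropout=base.dropout, weights=base.weights)


def encode_molecule(mol: MolGraph, stack: SharedGCNStack) -> np.ndarray:
    """Inference-mode per-atom embeddings (m x out_width) for one molecule."""
    if mol.atom_features.shape[1] != stack.widths[0]:
        raise ValueError(
            f"atom feature width {mol.atom_features.shape[1]} != stack input {stack.widths[0]}"
        )
    anorm = Tensor(normalize_adjacency(mol.adjacency))
    return stack.forward(anorm, Tensor(mol.atom_features), training=False).data


def readout_max(node_embeddings: np.ndarray) -> np.ndarray:
    """Column-wise max pooling over atoms."""
    arr = np.asarray(node_embeddings)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValueError("readout requires a non-empty (m, f) matrix")
    return arr.max(axis=0)


def pair_structure_embedding(
    mol_i: MolGraph, mol_j: MolGraph, stack: SharedGCNStack
) -> np.ndarray:
    """Structure embedding Z_C = readout(branch_t(mol_j)) || readout(branch_f(mol_i))."""
    z_f = readout_max(encode_molecule(mol_i, stack))
    z_t = readout_max(encode_molecule(mol_j, stack))
    return np.concatenate([z_t, z_f])


class MolecularEncoder:
    """Batched two-branch encoder producing Z_C for each pair in a batch."""

    def __init__(
        self,
        rng: np.random.Generator,
        widths: Sequence[int] = DEFAULT_MOL_WIDTHS,
        dropout: float = 0.2,
    ):
        self.stack = SharedGCNStack.init(rng, widths, dropout)

    def parameters(self) -> list[Tensor]:
        return self.stack.parameters()

    def encode_batch(
        self,
        anorm_i: Tensor,
        x_i: Tensor,
        anorm_j: Tensor,
        x_j: Tensor,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """(B, n, .) padded batches for both branches -> (B, 256) Z_C.

        Padded atom rows carry zero features and zero adjacency, so they
        contribute zeros that cannot exceed the post-ReLU maxima.
        """
        z_f = self.stack.forward(anorm_i, x_i, training=training, rng=rng).max(axis=1)
        z_t = self.stack.forward(anorm_j, x_j, training=training, rng=rng).max(axis=1)
        return ad.concat([z_t, z_f], axis=1)


def molecular_head(z_c: Tensor, head: MLPHead, **kwargs) -> Tensor:
    """Auxiliary interaction probability p_const from the structure embedding."""
    return head(z_c, **kwargs)
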