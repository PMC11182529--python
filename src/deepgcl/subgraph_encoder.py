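"""Common-neighbor subgraph construction and its GCN encoder.

For a query pair (i, j) the subgraph contains i, j and every node within
H hops of *both* endpoints on the sampling network, plus one virtual node
connected to everything.  The virtual node's final-layer embedding is the
pair's topology representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data_io import (
    FINGERPRINT_BITS,
    FeaturizationError,
    InteractionNetwork,
    canonical_pair,
)

VIRTUAL_ID = "__virtual__"

DEFAULT_SUBGRAPH_WIDTHS = (FINGERPRINT_BITS, 332, 128)


class LookupError_(KeyError):
    """Node not present in the network."""


@dataclass
class PairSubgraph:
    """Induced common-neighbor subgraph with an appended virtual node.

    ``node_ids`` lists the pair endpoints first, common neighbors next
    and the virtual node last.  ``node_features`` is None when no
    fingerprint table was supplied.
    """

    node_ids: list[str]
    adjacency: np.ndarray  # (n+1, n+1)
    node_features: np.ndarray | None  # (n+1, 166)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def virtual_index(self) -> int:
        return self.n_nodes - 1

    def export_edges(self, path: str | Path) -> None:
        """Debug dump as edge-list TSV with the virtual sentinel node."""
        with open(path, "w") as fh:
            n = self.n_nodes
            for a in range(n):
                for b in range(a + 1, n):
                    if self.adjacency[a, b]:
                        fh.write(f"{self.node_ids[a]}\t{self.node_ids[b]}\n")


def hhop_neighbors(
    net: InteractionNetwork,
    v: str,
    hops: int,
    adj: Mapping[str, set[str]] | None = None,
) -> set[str]:
    """Nodes at shortest-path distance 1..hops from ``v`` (``v`` excluded).

    ``adj`` may carry precomputed adjacency lists to amortize the cost
    over many queries on the same network.
    """
    if v not in net.nodes:
        raise LookupError_(f"node {v!r} not in network")
    if hops < 1:
        raise ValueError("hop count must be >= 1")
    if adj is None:
        adj = net.adjacency_lists()
    frontier = {v}
    visited = {v}
    result: set[str] = set()
    for _ in range(hops):
        nxt: set[str] = set()
        for u in frontier:
            nxt |= adj[u]
        nxt -= visited
        result |= nxt
        visited |= nxt
        frontier = nxt
        if not frontier:
            break
    return result


def sample_common_subgraph(
    net: InteractionNetwork,
    i: str,
    j: str,
    hops: int = 2,
    exclude_target_edge: bool = True,
    fingerprints: Mapping[str, np.ndarray] | None = None,
    adj: Mapping[str, set[str]] | None = None,
) -> PairSubgraph:
    """Build the pair's H-hop common-neighbor subgraph plus virtual node.

    Endpoints absent from the network are treated as isolated, yielding
    the degenerate two-node subgraph.  When a fingerprint table is given
    the node features are attached and the virtual node feature is the
    mean of the others.
    """
    if i == j:
        raise ValueError("subgraph endpoints must differ")
    if adj is None:
        adj = net.adjacency_lists()
    ni = hhop_neighbors(net, i, hops, adj) if i in net.nodes else set()
    nj = hhop_neighbors(net, j, hops, adj) if j in net.nodes else set()
    common = (ni & nj) - {i, j}
    node_ids = [i, j] + sorted(common)
    n = len(node_ids)
    adj = np.zeros((n + 1, n + 1), dtype=np.float64)
    index = {u: k for k, u in enumerate(node_ids)}
    for a_id in node_ids:
        for b_id in node_ids:
            a, b = index[a_id], index[b_id]
            if a < b and net.has_edge(a_id, b_id):
                adj[a, b] = adj[b, a] = 1.0
    if exclude_target_edge:
        adj[0, 1] = adj[1, 0] = 0.0
    adj[:n, n] = adj[n, :n] = 1.0  # virtual node connected to all

    features = None
    if fingerprints is not None:
        rows = []
        for u in node_ids:
            if u not in fingerprints:
                raise FeaturizationError(f"no fingerprint for drug {u!r}", drug_id=u)
            rows.append(fingerprints[u])
        real = np.stack(rows)
        features = np.vstack([real, real.mean(axis=0, keepdims=True)])
    return PairSubgraph(node_ids + [VIRTUAL_ID], adj, features)


def add_virtual_node(
    features: np.ndarray, adjacency: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Append a virtual node connected to all nodes; feature = mean of the rest."""
    n = features.shape[0]
    if n == 0:
        raise ValueError("cannot add a virtual node to an empty graph")
    adj = np.zeros((n + 1, n + 1), dtype=np.float64)
    adj[:n, :n] = adjacency
    adj[:n, n] = adj[n, :n] = 1.0
    feats = np.vstack([features, features.mean(axis=0, keepdims=True)])
    return feats, adj


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric GCN normalization D̃^{-1/2} (A + I) D̃^{-1/2}."""
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency must have zero diagonal")
    a_tilde = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float32)


@dataclass
class GCNStack:
    """A stack of bias-free graph-convolution layers with ReLU."""

    widths: Sequence[int] = DEFAULT_SUBGRAPH_WIDTHS
    dropout: float = 0.2
    weights: list[Tensor] = field(default_factory=list)

    @classmethod
    def init(
        cls,
        rng: np.random.Generator,
        widths: Sequence[int] = DEFAULT_SUBGRAPH_WIDTHS,
        dropout: float = 0.2,
    ) -> "GCNStack":
        weights = [
            ad.parameter(_glorot(rng, widths[k], widths[k + 1]))
            for k in range(len(widths) - 1)
        ]
        return cls(widths=tuple(widths), dropout=dropout, weights=weights)

    def parameters(self) -> list[Tensor]:
        return list(self.weights)

    def forward(
        self,
        anorm: Tensor,
        x: Tensor,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Apply the layers; works on (n, f) or batched (B, n, f) input."""
        z = x
        for w in self.weights:
            z = ad.relu(anorm @ z @ w)
            if training and self.dropout > 0:
                if rng is None:
                    raise ValueError("training-mode forward needs an rng for dropout")
                keep = rng.random(z.shape, dtype=np.float32) >= self.dropout
                z = z * Tensor(keep.astype(z.data.dtype) / (1.0 - self.dropout))
        return z


class SubgraphEncoder:
    """GCN over the pair subgraph; reads out the virtual node row."""

    def __init__(
        self,
        rng: np.random.Generator,
        widths: Sequence[int] = DEFAULT_SUBGRAPH_WIDTHS,
        dropout: float = 0.2,
    ):
        self.stack = GCNStack.init(rng, widths, dropout)

    def parameters(self) -> list[Tensor]:
        return self.stack.parameters()

    def encode_batch(
        self,
        anorm: Tensor,
        x: Tensor,
        virtual_index: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        z = self.stack.forward(anorm, x, training=training, rng=rng)
        return z.take_rows(virtual_index)


def subgraph_head(z_t: Tensor, head) -> Tensor:
    """Auxiliary interaction probability p_sub from the topology embedding."""
    return head(z_t)


def encode_subgraph(sub: PairSubgraph, stack: GCNStack) -> np.ndarray:
    """Inference-mode topology embedding Z_T of one subgraph."""
    if sub.node_features is None:
        raise ValueError("subgraph has no node features attached")
    if sub.node_features.shape[1] != stack.widths[0]:
        raise ValueError(
            f"feature width {sub.node_features.shape[1]} != stack input {stack.widths[0]}"
        )
    anorm = Tensor(normalize_adjacency(sub.adjacency))
    z = stack.forward(anorm, Tensor(sub.node_features), training=False)
    return z.data[sub.virtual_index]
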