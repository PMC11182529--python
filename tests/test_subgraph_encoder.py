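import numpy as np
import networkx as nx
import pytest

from deepgcl.autodiff import Tensor
from deepgcl.data_io import FeaturizationError, InteractionNetwork
from deepgcl.layers import MLPHead
from deepgcl.subgraph_encoder import (
    GCNStack,
    LookupError_,
    VIRTUAL_ID,
    add_virtual_node,
    encode_subgraph,
    hhop_neighbors,
    normalize_adjacency,
    sample_common_subgraph,
    subgraph_head,
)


def _net(edges):
    net = InteractionNetwork()
    for u, v in edges:
        net.add_edge(u, v)
    return net


def _random_net(n, p, seed):
    g = nx.gnp_random_graph(n, p, seed=seed)
    net = InteractionNetwork(nodes={f"n{k}" for k in range(n)})
    for u, v in g.edges:
        net.add_edge(f"n{u}", f"n{v}")
    return net, g


# ---------------------------------------------------------------------------
# H-hop neighborhoods
# ---------------------------------------------------------------------------


def test_hhop_path_one_hop():
    net = _net([("a", "b"), ("b", "c"), ("c", "d")])
    assert hhop_neighbors(net, "a", 1) == {"b"}


def test_hhop_path_two_hops():
    net = _net([("a", "b"), ("b", "c"), ("c", "d")])
    assert hhop_neighbors(net, "a", 2) == {"b", "c"}


def test_hhop_unknown_node():
    net = _net([("a", "b")])
    with pytest.raises(LookupError_):
        hhop_neighbors(net, "zz", 1)


def test_hhop_invalid_hops():
    net = _net([("a", "b")])
    with pytest.raises(ValueError):
        hhop_neighbors(net, "a", 0)


def test_hhop_matches_bfs_oracle():
    net, g = _random_net(50, 0.08, seed=2)
    for v in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, v, cutoff=2)
        oracle = {f"n{u}" for u, d in lengths.items() if 1 <= d <= 2}
        assert hhop_neighbors(net, f"n{v}", 2) == oracle


# ---------------------------------------------------------------------------
# subgraph sampling
# ---------------------------------------------------------------------------


def test_triangle_subgraph_excludes_target_edge():
    net = _net([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
    sub = sample_common_subgraph(net, "a", "b", hops=1, exclude_target_edge=True)
    assert sub.node_ids == ["a", "b", "c", VIRTUAL_ID]
    adj = sub.adjacency
    assert adj[0, 1] == 0  # target edge removed
    assert adj[0, 2] == 1 and adj[1, 2] == 1  # a-c, b-c kept
    assert (adj[:3, 3] == 1).all()  # virtual connected to all


def test_triangle_subgraph_keeps_target_edge_when_flag_off():
    net = _net([("a", "b"), ("b", "c"), ("a", "c")])
    sub = sample_common_subgraph(net, "a", "b", hops=1, exclude_target_edge=False)
    assert sub.adjacency[0, 1] == 1


def test_no_common_neighbors_degenerate_pair():
    net = _net([("a", "b"), ("c", "d")])
    sub = sample_common_subgraph(net, "a", "c", hops=1)
    assert len(sub.node_ids) == 3  # a, c, virtual
    assert sub.adjacency[:2, :2].sum() == 0


def test_endpoints_absent_from_network_are_isolated():
    net = _net([("a", "b")])
    sub = sample_common_subgraph(net, "x", "y", hops=2)
    assert sub.node_ids == ["x", "y", VIRTUAL_ID]


def test_subgraph_node_sets_match_bfs_intersection_oracle():
    net, g = _random_net(100, 0.05, seed=7)
    rng = np.random.default_rng(0)
    nodes = sorted(net.nodes)
    for _ in range(20):
        i, j = rng.choice(len(nodes), size=2, replace=False)
        vi, vj = nodes[i], nodes[j]
        for hops in (1, 2):
            sub = sample_common_subgraph(net, vi, vj, hops=hops)
            gi = nx.single_source_shortest_path_length(g, int(vi[1:]), cutoff=hops)
            gj = nx.single_source_shortest_path_length(g, int(vj[1:]), cutoff=hops)
            ni = {f"n{u}" for u, d in gi.items() if d >= 1}
            nj = {f"n{u}" for u, d in gj.items() if d >= 1}
            expected = ((ni & nj) - {vi, vj}) | {vi, vj}
            assert set(sub.node_ids[:-1]) == expected


def test_subgraph_requires_distinct_endpoints():
    net = _net([("a", "b")])
    with pytest.raises(ValueError):
        sample_common_subgraph(net, "a", "a")


def test_subgraph_missing_fingerprint_raises():
    net = _net([("a", "b")])
    with pytest.raises(FeaturizationError):
        sample_common_subgraph(net, "a", "b", fingerprints={"a": np.zeros(166)})


def test_subgraph_virtual_feature_is_mean():
    net = _net([("a", "b"), ("b", "c"), ("a", "c")])
    fps = {k: np.random.default_rng(3).random(166) for k in "abc"}
    sub = sample_common_subgraph(net, "a", "b", hops=1, fingerprints=fps)
    np.testing.assert_allclose(
        sub.node_features[-1],
        np.stack([fps["a"], fps["b"], fps["c"]]).mean(axis=0),
    )


# ---------------------------------------------------------------------------
# virtual node
# ---------------------------------------------------------------------------


def test_add_virtual_single_node():
    feats = np.array([[1.0, 2.0]])
    new_feats, new_adj = add_virtual_node(feats, np.zeros((1, 1)))
    np.testing.assert_array_equal(new_feats[1], feats[0])
    np.testing.assert_array_equal(new_adj, [[0, 1], [1, 0]])


def test_add_virtual_two_nodes_mean():
    x = np.array([[1.0, 0.0], [0.0, 1.0]])
    new_feats, _ = add_virtual_node(x, np.zeros((2, 2)))
    np.testing.assert_allclose(new_feats[2], [0.5, 0.5])


def test_add_virtual_adjacency_row():
    rng = np.random.default_rng(0)
    x = rng.random((5, 3))
    _, adj = add_virtual_node(x, np.zeros((5, 5)))
    assert adj[5].sum() == 5
    assert adj[5, 5] == 0


def test_add_virtual_empty_graph():
    with pytest.raises(ValueError):
        add_virtual_node(np.zeros((0, 3)), np.zeros((0, 0)))


# ---------------------------------------------------------------------------
# adjacency normalization
# ---------------------------------------------------------------------------


def test_normalize_single_node():
    np.testing.assert_array_equal(normalize_adjacency(np.zeros((1, 1))), [[1.0]])


def test_normalize_two_connected_nodes():
    a = np.array([[0.0, 1.0], [1.0, 0.0]])
    np.testing.assert_allclose(normalize_adjacency(a), [[0.5, 0.5], [0.5, 0.5]])


def test_normalize_rejects_asymmetric():
    with pytest.raises(ValueError):
        normalize_adjacency(np.array([[0.0, 1.0], [0.0, 0.0]]))


def test_normalize_spectral_bound_random_graphs():
    rng = np.random.default_rng(11)
    for _ in range(50):
        n = int(rng.integers(2, 12))
        g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(1 << 30)))
        a = nx.to_numpy_array(g)
        norm = normalize_adjacency(a)
        np.testing.assert_allclose(norm, norm.T, atol=1e-12)
        eig = np.linalg.eigvalsh(norm)
        assert np.abs(eig).max() <= 1 + 1e-9


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------


def _toy_subgraph(rng, n=4, width=166):
    g = nx.gnp_random_graph(n, 0.5, seed=1)
    a = nx.to_numpy_array(g)
    feats, adj = add_virtual_node(rng.random((n, width)), a)
    from deepgcl.subgraph_encoder import PairSubgraph

    return PairSubgraph([f"n{k}" for k in range(n)] + [VIRTUAL_ID], adj, feats)


def test_encode_zero_features_gives_zero_embedding(rng):
    sub = _toy_subgraph(rng)
    sub.node_features[:] = 0.0
    stack = GCNStack.init(np.random.default_rng(0))
    assert (encode_subgraph(sub, stack) == 0).all()


def test_encode_identity_weights_single_node():
    from deepgcl.subgraph_encoder import PairSubgraph
    import deepgcl.autodiff as ad

    feats = np.random.default_rng(0).normal(size=(1, 4))
    feats_v, adj = add_virtual_node(feats, np.zeros((1, 1)))
    sub = PairSubgraph(["a", VIRTUAL_ID], adj, feats_v)
    stack = GCNStack(widths=(4, 4), dropout=0.0, weights=[ad.parameter(np.eye(4))])
    # with identity weights the virtual row mixes the two nodes through
    # the normalized adjacency, then ReLU
    anorm = normalize_adjacency(adj)
    expected = np.maximum(anorm @ feats_v, 0.0)[1]
    np.testing.assert_allclose(encode_subgraph(sub, stack), expected, rtol=1e-6)


def test_encode_deterministic(rng):
    sub = _toy_subgraph(rng)
    stack = GCNStack.init(np.random.default_rng(5))
    z1 = encode_subgraph(sub, stack)
    z2 = encode_subgraph(sub, stack)
    np.testing.assert_array_equal(z1, z2)
    assert z1.shape == (128,)


def test_encode_width_mismatch():
    from deepgcl.subgraph_encoder import PairSubgraph

    feats, adj = add_virtual_node(np.zeros((2, 10)), np.zeros((2, 2)))
    sub = PairSubgraph(["a", "b", VIRTUAL_ID], adj, feats)
    with pytest.raises(ValueError, match="width"):
        encode_subgraph(sub, GCNStack.init(np.random.default_rng(0)))


def test_encode_permutation_equivariance(rng):
    """Relabeling non-virtual nodes leaves the virtual embedding unchanged."""
    from deepgcl.subgraph_encoder import PairSubgraph

    n = 6
    g = nx.gnp_random_graph(n, 0.5, seed=3)
    feats, adj = add_virtual_node(rng.random((n, 166)), nx.to_numpy_array(g))
    stack = GCNStack.init(np.random.default_rng(1))
    for w in stack.weights:  # float64 for a tight tolerance
        w.data = w.data.astype(np.float64)
    ids = [f"n{k}" for k in range(n)] + [VIRTUAL_ID]
    base = encode_subgraph(PairSubgraph(ids, adj, feats), stack)
    perm = np.concatenate([rng.permutation(n), [n]])
    sub_p = PairSubgraph(
        [ids[k] for k in perm], adj[np.ix_(perm, perm)], feats[perm]
    )
    permuted = encode_subgraph(sub_p, stack)
    np.testing.assert_allclose(permuted, base, atol=1e-5)


def test_anti_leakage_no_common_neighbors():
    """With the target edge excluded, positive and negative pairs without
    common neighbors yield identical subgraph adjacency."""
    net = _net([("a", "b"), ("c", "d")])
    pos = sample_common_subgraph(net, "a", "b", hops=1, exclude_target_edge=True)
    neg = sample_common_subgraph(net, "a", "c", hops=1, exclude_target_edge=True)
    np.testing.assert_array_equal(pos.adjacency, neg.adjacency)


# ---------------------------------------------------------------------------
# head
# ---------------------------------------------------------------------------


def test_subgraph_head_output_range(rng):
    head = MLPHead(np.random.default_rng(0), 128)
    z = Tensor(rng.normal(size=(7, 128)))
    p = subgraph_head(z, head)
    assert ((p.data > 0) & (p.data < 1)).all()


def test_subgraph_head_zeroed_final_layer(rng):
    head = MLPHead(np.random.default_rng(0), 128)
    head.fc2.weight.data[:] = 0.0
    head.fc2.bias.data[:] = 0.0
    p = subgraph_head(Tensor(rng.normal(size=(3, 128))), head)
    np.testing.assert_allclose(p.data, 0.5)


def test_subgraph_head_batch_order_preserved(rng):
    head = MLPHead(np.random.default_rng(0), 128)
    z = rng.normal(size=(5, 128))
    p = subgraph_head(Tensor(z), head).data.ravel()
    perm = rng.permutation(5)
    p_perm = subgraph_head(Tensor(z[perm]), head).data.ravel()
    np.testing.assert_allclose(p_perm, p[perm], rtol=1e-6)
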