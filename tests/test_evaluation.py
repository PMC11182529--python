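import json

import numpy as np
import networkx as nx
import pytest

from deepgcl.data_io import ConfigError, InteractionNetwork, PairSample
from deepgcl.evaluation import (
    MetricError,
    binary_metrics,
    cold_start_partition,
    edge_attack,
    export_embeddings,
    full_report,
    make_cold_start_factory,
    ranking_metrics,
    run_ablation,
    run_cold_start,
)
from deepgcl.fusion_trainer import DeepGCLModel, TrainConfig


def auc_oracle(scores, labels):
    """O(n^2) concordant-pair count with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def ap_oracle(scores, labels):
    """Literal average precision: mean of precision@rank over positives."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    ranked = np.asarray(labels)[order]
    hits = 0
    precisions = []
    for rank, y in enumerate(ranked, start=1):
        if y == 1:
            hits += 1
            precisions.append(hits / rank)
    return float(np.mean(precisions))


# ---------------------------------------------------------------------------
# binary metrics
# ---------------------------------------------------------------------------


def test_perfect_separation():
    rep = binary_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert rep.auc == rep.aupr == rep.f1 == 1.0


def test_shuffled_labels_auc_near_half(rng):
    scores = rng.random(10000)
    labels = rng.integers(0, 2, size=10000)
    rep = binary_metrics(scores, labels)
    assert rep.auc == pytest.approx(0.5, abs=0.02)


def test_auc_matches_concordance_oracle():
    scores = [0.9, 0.4, 0.6, 0.1]
    labels = [1, 0, 1, 0]
    rep = binary_metrics(scores, labels)
    assert rep.auc == pytest.approx(auc_oracle(scores, labels), abs=1e-12)


def test_single_class_rejected():
    with pytest.raises(MetricError):
        binary_metrics([0.1, 0.9], [1, 1])


# ---------------------------------------------------------------------------
# ranking metrics
# ---------------------------------------------------------------------------


def test_single_positive_ranked_first():
    out = ranking_metrics([0.9, 0.5, 0.1], [1, 0, 0], ks=(1,))
    assert out["mrr"] == 1.0
    assert out["hit_at_k"][1] == 1.0
    assert out["map"] == 1.0


def test_positive_ranked_last():
    scores = list(np.linspace(1, 0.1, 10))
    labels = [0] * 9 + [1]
    out = ranking_metrics(scores, labels, ks=(1,))
    assert out["hit_at_k"][1] == 0.0
    assert out["mrr"] == pytest.approx(0.1)


def test_map_matches_literal_oracle(rng):
    scores = rng.random(50)
    labels = rng.integers(0, 2, size=50)
    labels[0] = 1  # ensure a positive
    out = ranking_metrics(scores, labels)
    assert out["map"] == pytest.approx(ap_oracle(scores, labels), abs=1e-12)


def test_hit_frac_variant():
    out = ranking_metrics([0.9, 0.8, 0.1], [1, 0, 1], ks=(2,))
    assert out["hit_frac_at_k"][2] == pytest.approx(0.5)


def test_ranking_empty_input():
    with pytest.raises(ValueError):
        ranking_metrics([], [])


def test_ranking_no_positive():
    with pytest.raises(MetricError):
        ranking_metrics([0.5], [0])


# ---------------------------------------------------------------------------
# edge attack
# ---------------------------------------------------------------------------


def _random_net(n=60, p=0.06, seed=0):
    g = nx.gnp_random_graph(n, p, seed=seed)
    net = InteractionNetwork(nodes={f"n{k}" for k in range(n)})
    for u, v in g.edges:
        net.add_edge(f"n{u}", f"n{v}")
    return net


def test_attack_removes_exact_fraction():
    net = _random_net(seed=1)
    degraded = edge_attack(net, 0.3, seed=0)
    assert degraded.n_edges == net.n_edges - round(0.3 * net.n_edges)


def test_attack_deterministic():
    net = _random_net(seed=2)
    a = edge_attack(net, 0.5, seed=7)
    b = edge_attack(net, 0.5, seed=7)
    assert a.edges == b.edges


def test_attack_set_algebra():
    net = _random_net(seed=3)
    degraded = edge_attack(net, 0.4, seed=1)
    removed = net.edges - degraded.edges
    assert degraded.edges | removed == net.edges
    assert not degraded.edges & removed


def test_attack_fraction_validation():
    net = _random_net()
    for f in (0.0, 1.0, -0.1, 2.0):
        with pytest.raises(ConfigError):
            edge_attack(net, f, seed=0)


def test_attack_keeps_nodes():
    net = _random_net(seed=4)
    assert edge_attack(net, 0.2, seed=0).nodes == net.nodes


# ---------------------------------------------------------------------------
# cold start
# ---------------------------------------------------------------------------


def _route_count(sample, cold):
    return (sample.drug_i in cold) + (sample.drug_j in cold)


def test_cold_start_toy_routing():
    net = InteractionNetwork()
    drugs = [f"d{k}" for k in range(10)]
    for a in range(10):
        for b in range(a + 1, a + 3):
            if b < 10:
                net.add_edge(drugs[a], drugs[b])
    cold = cold_start_partition(net, drugs, cold_fraction=0.3, seed=0)
    assert len(cold.drugs_cold) == 3
    for s in cold.ddi_train:
        assert _route_count(s, cold.drugs_cold) == 0
    for s in cold.ddi_drugwise:
        assert _route_count(s, cold.drugs_cold) == 1
    for s in cold.ddi_pairwise:
        assert _route_count(s, cold.drugs_cold) == 2
    # positives exhaust the network's edges across the three subsets
    pos = [s.pair for subset in (cold.ddi_train, cold.ddi_drugwise, cold.ddi_pairwise)
           for s in subset if s.label == 1]
    assert sorted(pos) == sorted(net.edges)
    # 1:1 negatives per subset, all true non-edges
    for subset in (cold.ddi_train, cold.ddi_drugwise, cold.ddi_pairwise):
        labels = [s.label for s in subset]
        assert labels.count(1) == labels.count(0)
        assert all(s.pair not in net.edges for s in subset if s.label == 0)


def test_cold_start_many_partitions_no_violations(tiny_dataset):
    _, _, net = tiny_dataset
    drugs = sorted(net.nodes)
    for seed in range(10):
        cold = cold_start_partition(net, drugs, cold_fraction=0.25, seed=seed)
        for s in cold.ddi_train:
            assert _route_count(s, cold.drugs_cold) == 0
        for s in cold.ddi_drugwise:
            assert _route_count(s, cold.drugs_cold) == 1
        for s in cold.ddi_pairwise:
            assert _route_count(s, cold.drugs_cold) == 2


def test_cold_fraction_validation(tiny_dataset):
    _, _, net = tiny_dataset
    with pytest.raises(ConfigError):
        cold_start_partition(net, sorted(net.nodes), 0.0, seed=0)


def test_run_cold_start_smoke(small_dataset):
    records, _, net = small_dataset
    cold = cold_start_partition(net, [r.drug_id for r in records], 0.2, seed=1)
    factory = make_cold_start_factory(records, hop=1, seed=1)
    reports = run_cold_start(factory, cold, TrainConfig(epochs=1, seed=1))
    assert set(reports) == {"drugwise", "pairwise"}
    for rep in reports.values():
        assert 0.0 <= rep.auc <= 1.0


# ---------------------------------------------------------------------------
# ablations
# ---------------------------------------------------------------------------


def test_run_ablation_unknown_variant(small_prepared):
    with pytest.raises(ConfigError):
        run_ablation("bogus", small_prepared, TrainConfig(epochs=1))


def test_run_ablation_all_variants_smoke(small_prepared):
    for variant in ("full", "no_molecular", "no_subgraph", "no_contrastive"):
        report, result = run_ablation(variant, small_prepared, TrainConfig(epochs=1, seed=2))
        assert 0.0 <= report.auc <= 1.0
        assert report.n_samples == len(small_prepared.split.test)
        if variant == "no_contrastive":
            assert result.history[0]["l_contr"] == 0.0


# ---------------------------------------------------------------------------
# embedding export
# ---------------------------------------------------------------------------


def test_export_embeddings(tmp_path, small_prepared):
    model = DeepGCLModel(seed=0)
    samples = small_prepared.split.test[:7]
    out = tmp_path / "emb.tsv"
    export_embeddings(model, small_prepared, samples, out)
    lines = out.read_text().strip().split("\n")
    header = lines[0].split("\t")
    assert len(lines) == 8  # header + 7 rows
    assert header[:3] == ["drug_i", "drug_j", "label"]
    assert sum(c.startswith("z_t_") for c in header) == 128
    assert sum(c.startswith("z_c_proj_") for c in header) == 128
    assert sum(c.startswith("fused_") for c in header) == 512
    export_embeddings(model, small_prepared, samples, tmp_path / "emb2.tsv")
    assert (tmp_path / "emb2.tsv").read_text() == out.read_text()


def test_full_report_serializes(rng):
    scores = rng.random(40)
    labels = rng.integers(0, 2, size=40)
    labels[:2] = [0, 1]
    rep = full_report(scores, labels)
    payload = json.loads(json.dumps(rep.to_dict()))
    assert {"auc", "aupr", "f1", "map", "mrr"} <= set(payload)
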