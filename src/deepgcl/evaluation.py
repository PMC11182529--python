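"""Metrics and experimental protocols: ablations, edge attack, cold start.

Ranking-metric conventions (emitted under explicit names since several
are in circulation):

* ``mrr``      — mean over positives of 1 / rank of that positive.
* ``hit_at_k`` — 1 if any positive ranks in the global top K, else 0.
* ``hit_frac_at_k`` — fraction of the top K that are positives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

from .data_io import (
    CapacityError,
    ConfigError,
    DatasetSplit,
    DrugRecord,
    InteractionNetwork,
    PairSample,
    canonical_pair,
)
from .fusion_trainer import (
    DeepGCLModel,
    PreparedDataset,
    TrainConfig,
    TrainResult,
    VARIANTS,
    fusion_vector,
    prepare_dataset,
    train,
)


class MetricError(ValueError):
    """Metric undefined for the given labels."""


@dataclass
class MetricReport:
    auc: float
    aupr: float
    f1: float
    n_samples: int
    map: float | None = None
    mrr: float | None = None
    hit_at_k: dict[int, float] = field(default_factory=dict)
    hit_frac_at_k: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"auc": self.auc, "aupr": self.aupr, "f1": self.f1, "n_samples": self.n_samples}
        if self.map is not None:
            out["map"] = self.map
            out["mrr"] = self.mrr
            out["hit_at_k"] = {str(k): v for k, v in self.hit_at_k.items()}
            out["hit_frac_at_k"] = {str(k): v for k, v in self.hit_frac_at_k.items()}
        return out


def binary_metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> MetricReport:
    """AUC / AUPR / F1 at the fixed threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if labels.min() == labels.max():
        raise MetricError("binary metrics need at least one positive and one negative")
    return MetricReport(
        auc=float(roc_auc_score(labels, scores)),
        aupr=float(average_precision_score(labels, scores)),
        f1=float(f1_score(labels, (scores >= threshold).astype(int))),
        n_samples=len(labels),
    )


def ranking_metrics(
    scores: Sequence[float], labels: Sequence[int], ks: Sequence[int] = (1, 3, 10)
) -> dict:
    """MAP / MRR / HIT@K over the globally ranked score list."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.size == 0:
        raise ValueError("empty input")
    if labels.sum() == 0:
        raise MetricError("ranking metrics need at least one positive")
    order = np.argsort(-scores, kind="stable")
    ranked = labels[order]
    pos_ranks = np.flatnonzero(ranked == 1) + 1  # 1-based ranks of positives
    precisions = np.arange(1, len(pos_ranks) + 1) / pos_ranks
    out = {
        "map": float(precisions.mean()),
        "mrr": float((1.0 / pos_ranks).mean()),
        "hit_at_k": {},
        "hit_frac_at_k": {},
    }
    for k in ks:
        topk = ranked[:k]
        out["hit_at_k"][int(k)] = float(topk.any())
        out["hit_frac_at_k"][int(k)] = float(topk.sum() / k)
    return out


def full_report(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
    ks: Sequence[int] = (1, 3, 10),
) -> MetricReport:
    report = binary_metrics(scores, labels, threshold)
    rank = ranking_metrics(scores, labels, ks)
    report.map = rank["map"]
    report.mrr = rank["mrr"]
    report.hit_at_k = rank["hit_at_k"]
    report.hit_frac_at_k = rank["hit_frac_at_k"]
    return report


# ---------------------------------------------------------------------------
# edge attack
# ---------------------------------------------------------------------------


def edge_attack(
    net: InteractionNetwork, fraction: float, seed: int
) -> InteractionNetwork:
    """Remove round(fraction * |E|) edges uniformly at random."""
    if not 0 < fraction < 1:
        raise ConfigError(f"attack fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    edges = sorted(net.edges)
    n_remove = round(fraction * len(edges))
    removed = set(
        edges[k] for k in rng.choice(len(edges), size=n_remove, replace=False)
    )
    surviving = InteractionNetwork(nodes=set(net.nodes), edges=set(net.edges) - removed)
    return surviving


# ---------------------------------------------------------------------------
# cold start
# ---------------------------------------------------------------------------


@dataclass
class ColdStartSplit:
    drugs_train: set[str]
    drugs_cold: set[str]
    ddi_train: list[PairSample]
    ddi_drugwise: list[PairSample]
    ddi_pairwise: list[PairSample]
    seed: int


def _route(pair: tuple[str, str], cold: set[str]) -> str:
    n_cold = (pair[0] in cold) + (pair[1] in cold)
    return ("train", "drugwise", "pairwise")[n_cold]


def cold_start_partition(
    net: InteractionNetwork,
    drugs: Sequence[str],
    cold_fraction: float,
    seed: int,
    max_retries: int = 10,
) -> ColdStartSplit:
    """Split drugs into train/cold and route pairs into the three subsets.

    Negatives are sampled at 1:1 within each subset from non-edges whose
    endpoints satisfy the subset's routing rule.
    """
    if not 0 < cold_fraction < 1:
        raise ConfigError(f"cold_fraction must be in (0, 1), got {cold_fraction}")
    drugs = sorted(drugs)
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        n_cold = max(1, round(cold_fraction * len(drugs)))
        cold = set(np.array(drugs)[rng.choice(len(drugs), size=n_cold, replace=False)])
        train_set = set(drugs) - cold
        routed: dict[str, list[PairSample]] = {"train": [], "drugwise": [], "pairwise": []}
        for u, v in sorted(net.edges):
            routed[_route((u, v), cold)].append(PairSample(u, v, 1))
        if all(routed.values()):
            try:
                negatives = _cold_negatives(net, drugs, cold, routed, rng)
            except CapacityError:
                warnings.warn(
                    f"cold-start partition attempt {attempt} lacks non-edges "
                    "for 1:1 negatives; retrying",
                    stacklevel=2,
                )
                continue
            for key in routed:
                routed[key].extend(negatives[key])
            return ColdStartSplit(
                drugs_train=train_set,
                drugs_cold=cold,
                ddi_train=routed["train"],
                ddi_drugwise=routed["drugwise"],
                ddi_pairwise=routed["pairwise"],
                seed=seed + attempt,
            )
        warnings.warn(
            f"cold-start partition attempt {attempt} left a subset empty; retrying",
            stacklevel=2,
        )
    raise CapacityError(
        f"could not build a non-empty cold-start partition in {max_retries} attempts"
    )


def _cold_negatives(
    net: InteractionNetwork,
    drugs: Sequence[str],
    cold: set[str],
    routed: Mapping[str, list[PairSample]],
    rng: np.random.Generator,
) -> dict[str, list[PairSample]]:
    pools: dict[str, list[tuple[str, str]]] = {"train": [], "drugwise": [], "pairwise": []}
    for a in range(len(drugs)):
        for b in range(a + 1, len(drugs)):
            pair = (drugs[a], drugs[b])
            if pair not in net.edges:
                pools[_route(pair, cold)].append(pair)
    out: dict[str, list[PairSample]] = {}
    for key, positives in routed.items():
        pool = pools[key]
        want = len(positives)
        if want > len(pool):
            raise CapacityError(f"not enough non-edges for subset {key!r}")
        idx = rng.choice(len(pool), size=want, replace=False)
        out[key] = [PairSample(*pool[k], 0) for k in idx]
    return out


def make_cold_start_factory(
    records: Sequence[DrugRecord],
    hop: int = 2,
    exclude_target_edge: bool = True,
    fingerprint_kind: str = "maccs",
    val_fraction: float = 0.1,
    seed: int = 0,
):
    """Build the ``prepared_factory`` used by :func:`run_cold_start`.

    The factory shuffles the routed DDI_train samples into a train/val
    split (keeping the routed negatives), builds the sampling network
    from the training positives, and prepares feature caches that can
    collate the cold evaluation samples as well.
    """
    def factory(train_samples, eval_samples):
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(train_samples))
        shuffled = [train_samples[k] for k in order]
        n_val = max(1, round(val_fraction * len(shuffled)))
        split = DatasetSplit(
            train=shuffled[n_val:], val=shuffled[:n_val],
            test=list(eval_samples), seed=seed,
        )
        sampling = InteractionNetwork()
        for s in split.train:
            if s.label == 1:
                sampling.add_edge(s.drug_i, s.drug_j)
        return prepare_dataset(
            records, split, sampling_net=sampling, hop=hop,
            exclude_target_edge=exclude_target_edge,
            fingerprint_kind=fingerprint_kind,
        )

    return factory


def run_cold_start(
    prepared_factory,
    cold_split: ColdStartSplit,
    config: TrainConfig,
) -> dict[str, MetricReport]:
    """Train on DDI_train, freeze, then score cold subsets by logistic regression.

    ``prepared_factory(samples_train, samples_eval)`` must return a
    PreparedDataset whose split has the given train samples (val/test
    arbitrary) and that can collate every sample passed in.
    """
    prepared = prepared_factory(cold_split.ddi_train,
                                cold_split.ddi_drugwise + cold_split.ddi_pairwise)
    result = train(prepared, config, variant="full")
    model = result.model

    def embeddings(samples: Sequence[PairSample]) -> np.ndarray:
        feats = []
        for start in range(0, len(samples), 256):
            batch = prepared.collate(samples[start : start + 256])
            out = model.forward_batch(batch, variant="full", training=False)
            feats.append(fusion_vector(out["z_c_proj"], out["z_t"]).data)
        return np.vstack(feats)

    train_emb = embeddings(cold_split.ddi_train)
    train_y = np.array([s.label for s in cold_split.ddi_train])
    clf = LogisticRegression(max_iter=2000)
    clf.fit(train_emb, train_y)
    reports = {}
    for name, samples in (
        ("drugwise", cold_split.ddi_drugwise),
        ("pairwise", cold_split.ddi_pairwise),
    ):
        scores = clf.predict_proba(embeddings(samples))[:, 1]
        labels = [s.label for s in samples]
        reports[name] = binary_metrics(scores, labels)
    return reports


# ---------------------------------------------------------------------------
# ablations
# ---------------------------------------------------------------------------


def run_ablation(
    variant: str,
    prepared: PreparedDataset,
    config: TrainConfig,
) -> tuple[MetricReport, TrainResult]:
    """Train the requested variant and report test-set metrics."""
    if variant not in VARIANTS:
        raise ConfigError(f"unknown variant: {variant!r}")
    result = train(prepared, config, variant=variant)
    scores = result.model.predict_scores(prepared, prepared.split.test, variant)
    labels = [s.label for s in prepared.split.test]
    return full_report(scores, labels), result


# ---------------------------------------------------------------------------
# embedding export
# ---------------------------------------------------------------------------


def export_embeddings(
    model: DeepGCLModel,
    prepared: PreparedDataset,
    samples: Sequence[PairSample],
    path: str | Path,
) -> None:
    """TSV of per-pair Z_T, projected Z_C, and fused vectors."""
    dim = model.config["sub_widths"][-1]
    header = (
        ["drug_i", "drug_j", "label"]
        + [f"z_t_{k}" for k in range(dim)]
        + [f"z_c_proj_{k}" for k in range(dim)]
        + [f"fused_{k}" for k in range(4 * dim)]
    )
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for start in range(0, len(samples), 256):
            chunk = samples[start : start + 256]
            batch = prepared.collate(chunk)
            out = model.forward_batch(batch, variant="full", training=False)
            z_t, z_c = out["z_t"], out["z_c_proj"]
            fused = fusion_vector(z_c, z_t).data
            for k, s in enumerate(chunk):
                row = (
                    [s.drug_i, s.drug_j, str(s.label)]
                    + [f"{v:.6g}" for v in z_t.data[k]]
                    + [f"{v:.6g}" for v in z_c.data[k]]
                    + [f"{v:.6g}" for v in fused[k]]
                )
                fh.write("\t".join(row) + "\n")
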