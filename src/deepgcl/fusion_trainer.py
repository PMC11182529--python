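"""Model assembly, four-term objective and the training loop.

The final interaction probability fuses the projected structure
embedding with the topology embedding through the 4-block concatenation
[Z_C + Z_T, Z_C * Z_T, Z_C, Z_T] and an MLP head.  The objective is

    l_total = alpha * l_contr + beta * l_const + lambda * l_sub + eta * l_joint

with the contrastive term computed between Z_T and the projected Z_C.
The 256-wide structure embedding is mapped to width 128 by a learned
affine projection before both the contrastive and fusion computations;
the unprojected embedding feeds the structure head.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .contrastive import contrastive_loss
from .data_io import (
    ConfigError,
    DatasetSplit,
    DrugRecord,
    InteractionNetwork,
    PairSample,
    build_pair_dataset,
    fingerprint_table,
    random_split,
    smiles_to_molgraph,
)
from .layers import Linear, MLPHead
from .molecular_encoder import DEFAULT_MOL_WIDTHS, MolecularEncoder
from .subgraph_encoder import (
    DEFAULT_SUBGRAPH_WIDTHS,
    SubgraphEncoder,
    normalize_adjacency,
    sample_common_subgraph,
)

EMBED_DIM = 128
VARIANTS = ("full", "no_molecular", "no_subgraph", "no_contrastive")


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 0.1
    beta: float = 1.0
    lam: float = 1.0
    eta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "lam", "eta"):
            if getattr(self, name) < 0:
                raise ConfigError(f"loss weight {name} must be non-negative")


def binary_cross_entropy(p: Tensor, y: np.ndarray) -> Tensor:
    """Mean negative log-likelihood; probabilities clamped at 1e-7."""
    y = np.asarray(y, dtype=p.data.dtype).reshape(-1, 1)
    if p.shape[0] != y.shape[0]:
        raise ValueError(f"length mismatch: {p.shape[0]} probabilities, {y.shape[0]} labels")
    pc = p.clip(1e-7, 1.0 - 1e-7)
    yc = Tensor(y)
    ll = yc * pc.log() + (1.0 - yc) * (1.0 - pc).log()
    return -ll.mean()


def total_loss(
    l_contr: Tensor | float,
    l_const: Tensor | float,
    l_sub: Tensor | float,
    l_joint: Tensor | float,
    weights: LossWeights,
) -> Tensor:
    terms = [
        t if isinstance(t, Tensor) else Tensor(np.asarray(float(t)))
        for t in (l_contr, l_const, l_sub, l_joint)
    ]
    w = (weights.alpha, weights.beta, weights.lam, weights.eta)
    out = terms[0] * w[0]
    for t, c in zip(terms[1:], w[1:]):
        out = out + t * c
    return out


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


def project_structure(z_c: Tensor, projection: Linear) -> Tensor:
    """Affine map of the 256-wide structure embedding to width 128."""
    return projection(z_c)


def fusion_vector(z_c: Tensor, z_t: Tensor) -> Tensor:
    """The 4-block fusion [Z_C + Z_T, Z_C * Z_T, Z_C, Z_T] (width 4e)."""
    if z_c.shape != z_t.shape:
        raise ValueError(f"fusion width mismatch: {z_c.shape} vs {z_t.shape}")
    return ad.concat([z_c + z_t, z_c * z_t, z_c, z_t], axis=1)


def fuse_predict(
    z_c: Tensor, z_t: Tensor, head: MLPHead, **head_kwargs
) -> Tensor:
    """p_ct from the 4-block fusion of the two pair embeddings."""
    return head(fusion_vector(z_c, z_t), **head_kwargs)


class DeepGCLModel:
    """Dual-view DDI predictor with three heads and a structure projection."""

    def __init__(
        self,
        seed: int = 0,
        sub_widths: Sequence[int] = DEFAULT_SUBGRAPH_WIDTHS,
        mol_widths: Sequence[int] = DEFAULT_MOL_WIDTHS,
        mlp_hidden: int = 64,
        dropout: float = 0.2,
    ):
        rng = np.random.default_rng(seed)
        self.sub_encoder = SubgraphEncoder(rng, sub_widths, dropout)
        self.mol_encoder = MolecularEncoder(rng, mol_widths, dropout)
        struct_dim = 2 * mol_widths[-1]
        self.projection = Linear(rng, struct_dim, sub_widths[-1])
        self.sub_head = MLPHead(rng, sub_widths[-1], mlp_hidden, dropout)
        self.const_head = MLPHead(rng, struct_dim, mlp_hidden, dropout)
        self.joint_head = MLPHead(rng, 4 * sub_widths[-1], mlp_hidden, dropout)
        self.config = {
            "sub_widths": list(sub_widths),
            "mol_widths": list(mol_widths),
            "mlp_hidden": mlp_hidden,
            "dropout": dropout,
        }

    # -- parameter bookkeeping -----------------------------------------
    def parameter_groups(self) -> dict[str, list[Tensor]]:
        return {
            "sub_encoder": self.sub_encoder.parameters(),
            "mol_encoder": self.mol_encoder.parameters(),
            "projection": self.projection.parameters(),
            "sub_head": self.sub_head.parameters(),
            "const_head": self.const_head.parameters(),
            "joint_head": self.joint_head.parameters(),
        }

    def parameters(self) -> list[Tensor]:
        return [p for group in self.parameter_groups().values() for p in group]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{k}": p.data.copy()
            for name, group in self.parameter_groups().items()
            for k, p in enumerate(group)
        }

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, group in self.parameter_groups().items():
            for k, p in enumerate(group):
                p.data = np.array(state[f"{name}.{k}"])  # preserves stored dtype

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        path.with_suffix(".json").write_text(json.dumps(self.config))

    @classmethod
    def load(cls, path: str | Path) -> "DeepGCLModel":
        path = Path(path)
        config = json.loads(path.with_suffix(".json").read_text())
        model = cls(
            sub_widths=config["sub_widths"],
            mol_widths=config["mol_widths"],
            mlp_hidden=config["mlp_hidden"],
            dropout=config["dropout"],
        )
        with np.load(path.with_suffix(".npz")) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model

    # -- forward --------------------------------------------------------
    def forward_batch(
        self,
        batch: "CollatedBatch",
        variant: str = "full",
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> dict[str, Tensor]:
        """Compute the embeddings and head probabilities a variant needs."""
        if variant not in VARIANTS:
            raise ConfigError(f"unknown variant: {variant!r}")
        out: dict[str, Tensor] = {}
        kwargs = {"training": training, "rng": rng}
        if variant != "no_subgraph":
            z_t = self.sub_encoder.encode_batch(
                Tensor(batch.sub_anorm), Tensor(batch.sub_x), batch.sub_virtual, **kwargs
            )
            out["z_t"] = z_t
            out["p_sub"] = self.sub_head(z_t, **kwargs)
        if variant != "no_molecular":
            z_c = self.mol_encoder.encode_batch(
                Tensor(batch.mol_anorm_i),
                Tensor(batch.mol_x_i),
                Tensor(batch.mol_anorm_j),
                Tensor(batch.mol_x_j),
                **kwargs,
            )
            out["z_c"] = z_c
            out["p_const"] = self.const_head(z_c, **kwargs)
        if variant in ("full", "no_contrastive"):
            z_c_proj = project_structure(out["z_c"], self.projection)
            out["z_c_proj"] = z_c_proj
            out["p_ct"] = fuse_predict(z_c_proj, out["z_t"], self.joint_head, **kwargs)
        return out

    def predict_scores(
        self, prepared: "PreparedDataset", samples: Sequence[PairSample],
        variant: str = "full", batch_size: int = 256,
    ) -> np.ndarray:
        """Inference-mode interaction scores for a list of samples."""
        score_key = {"full": "p_ct", "no_contrastive": "p_ct",
                     "no_molecular": "p_sub", "no_subgraph": "p_const"}[variant]
        scores = []
        for start in range(0, len(samples), batch_size):
            batch = prepared.collate(samples[start : start + batch_size])
            out = self.forward_batch(batch, variant=variant, training=False)
            scores.append(out[score_key].data.ravel())
        return np.concatenate(scores)


# ---------------------------------------------------------------------------
# dataset preparation / collation
# ---------------------------------------------------------------------------


@dataclass
class CollatedBatch:
    labels: np.ndarray  # (B,)
    sub_anorm: np.ndarray  # (B, nmax, nmax)
    sub_x: np.ndarray  # (B, nmax, 166)
    sub_virtual: np.ndarray  # (B,)
    mol_anorm_i: np.ndarray  # (B, mmax, mmax)
    mol_x_i: np.ndarray  # (B, mmax, 78)
    mol_anorm_j: np.ndarray
    mol_x_j: np.ndarray


@dataclass
class _SubgraphCache:
    anorm: np.ndarray  # (n+1, n+1) normalized adjacency
    member_idx: np.ndarray  # (n,) indices into the fingerprint matrix


@dataclass
class PreparedDataset:
    """Split plus precomputed per-drug and per-sample feature caches."""

    split: DatasetSplit
    sampling_net: InteractionNetwork
    drug_index: dict[str, int]
    fingerprints: np.ndarray  # (n_drugs, 166)
    mol_anorm: list[np.ndarray]
    mol_x: list[np.ndarray]
    subgraphs: dict[tuple[str, str], _SubgraphCache]
    hop: int
    exclude_target_edge: bool

    def collate(self, samples: Sequence[PairSample]) -> CollatedBatch:
        b = len(samples)
        sub_sizes = [self.subgraphs[s.pair].anorm.shape[0] for s in samples]
        nmax = max(sub_sizes)
        sub_anorm = np.zeros((b, nmax, nmax), dtype=np.float32)
        sub_x = np.zeros((b, nmax, self.fingerprints.shape[1]), dtype=np.float32)
        sub_virtual = np.zeros(b, dtype=np.int64)
        idx_i = [self.drug_index[s.drug_i] for s in samples]
        idx_j = [self.drug_index[s.drug_j] for s in samples]
        mmax_i = max(self.mol_x[k].shape[0] for k in idx_i)
        mmax_j = max(self.mol_x[k].shape[0] for k in idx_j)
        mol_anorm_i = np.zeros((b, mmax_i, mmax_i), dtype=np.float32)
        mol_x_i = np.zeros((b, mmax_i, self.mol_x[0].shape[1]), dtype=np.float32)
        mol_anorm_j = np.zeros((b, mmax_j, mmax_j), dtype=np.float32)
        mol_x_j = np.zeros((b, mmax_j, self.mol_x[0].shape[1]), dtype=np.float32)
        for k, s in enumerate(samples):
            cache = self.subgraphs[s.pair]
            n_tot = cache.anorm.shape[0]
            sub_anorm[k, :n_tot, :n_tot] = cache.anorm
            members = self.fingerprints[cache.member_idx]
            sub_x[k, : n_tot - 1] = members
            sub_x[k, n_tot - 1] = members.mean(axis=0)
            sub_virtual[k] = n_tot - 1
            for (mi, target_a, target_x) in (
                (idx_i[k], mol_anorm_i, mol_x_i),
                (idx_j[k], mol_anorm_j, mol_x_j),
            ):
                m = self.mol_x[mi].shape[0]
                target_a[k, :m, :m] = self.mol_anorm[mi]
                target_x[k, :m] = self.mol_x[mi]
        return CollatedBatch(
            labels=np.array([s.label for s in samples], dtype=np.float64),
            sub_anorm=sub_anorm,
            sub_x=sub_x,
            sub_virtual=sub_virtual,
            mol_anorm_i=mol_anorm_i,
            mol_x_i=mol_x_i,
            mol_anorm_j=mol_anorm_j,
            mol_x_j=mol_x_j,
        )


def make_split(
    net: InteractionNetwork,
    seed: int,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> DatasetSplit:
    """1:1 positive/negative dataset split 8:1:1 by default."""
    return random_split(build_pair_dataset(net, seed), ratios, seed)


def training_network(split: DatasetSplit) -> InteractionNetwork:
    """Sampling network built from training positives only (no leakage)."""
    net = InteractionNetwork()
    for s in split.train:
        if s.label == 1:
            net.add_edge(s.drug_i, s.drug_j)
    return net


def prepare_dataset(
    records: Sequence[DrugRecord],
    split: DatasetSplit,
    sampling_net: InteractionNetwork | None = None,
    hop: int = 2,
    exclude_target_edge: bool = True,
    fingerprint_kind: str = "maccs",
) -> PreparedDataset:
    """Precompute all per-drug and per-sample features for fast batching."""
    if sampling_net is None:
        sampling_net = training_network(split)
    fps = fingerprint_table(records, kind=fingerprint_kind)
    drug_ids = [r.drug_id for r in records]
    drug_index = {d: k for k, d in enumerate(drug_ids)}
    fp_matrix = np.stack([fps[d] for d in drug_ids]).astype(np.float32)
    mol_anorm, mol_x = [], []
    for r in records:
        mol = smiles_to_molgraph(r.smiles, r.drug_id)
        mol_anorm.append(normalize_adjacency(mol.adjacency).astype(np.float32))
        mol_x.append(mol.atom_features.astype(np.float32))
    adj_lists = sampling_net.adjacency_lists()
    subgraphs: dict[tuple[str, str], _SubgraphCache] = {}
    for s in split.train + split.val + split.test:
        if s.pair in subgraphs:
            continue
        sub = sample_common_subgraph(
            sampling_net, s.drug_i, s.drug_j, hops=hop,
            exclude_target_edge=exclude_target_edge, adj=adj_lists,
        )
        member_idx = np.array([drug_index[d] for d in sub.node_ids[:-1]], dtype=np.int64)
        subgraphs[s.pair] = _SubgraphCache(
            anorm=normalize_adjacency(sub.adjacency).astype(np.float32),
            member_idx=member_idx,
        )
    return PreparedDataset(
        split=split,
        sampling_net=sampling_net,
        drug_index=drug_index,
        fingerprints=fp_matrix,
        mol_anorm=mol_anorm,
        mol_x=mol_x,
        subgraphs=subgraphs,
        hop=hop,
        exclude_target_edge=exclude_target_edge,
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 128
    dropout: float = 0.2
    seed: int = 0
    temperature: float = 0.5
    contrastive_mode: str = "as_printed"
    weights: LossWeights = field(default_factory=LossWeights)
    mlp_hidden: int = 64
    sub_widths: tuple[int, ...] = DEFAULT_SUBGRAPH_WIDTHS
    mol_widths: tuple[int, ...] = DEFAULT_MOL_WIDTHS

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.batch_size < 2 and self.weights.alpha > 0:
            raise ConfigError("batch size must be >= 2 when the contrastive loss is on")


@dataclass
class TrainResult:
    model: DeepGCLModel
    history: list[dict]
    best_epoch: int
    best_state: dict[str, np.ndarray]


def _epoch_metrics(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    if len(set(labels.tolist())) < 2:
        return {"auc": float("nan"), "aupr": float("nan"), "f1": float("nan")}
    return {
        "auc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
        "f1": float(f1_score(labels, (scores >= 0.5).astype(int))),
    }


def train(
    prepared: PreparedDataset,
    config: TrainConfig,
    variant: str = "full",
    verbose: bool = False,
) -> TrainResult:
    """Train a model on the prepared dataset; keep the best-val-AUC state."""
    if variant not in VARIANTS:
        raise ConfigError(f"unknown variant: {variant!r}")
    if not prepared.split.train:
        raise ValueError("empty training split")
    model = DeepGCLModel(
        seed=config.seed,
        sub_widths=config.sub_widths,
        mol_widths=config.mol_widths,
        mlp_hidden=config.mlp_hidden,
        dropout=config.dropout,
    )
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    train_samples = list(prepared.split.train)
    n = len(train_samples)
    history: list[dict] = []
    best_auc, best_epoch = -np.inf, -1
    best_state = model.state_dict()
    weights = config.weights
    if variant == "no_contrastive":
        weights = replace(weights, alpha=0.0)

    val_labels = np.array([s.label for s in prepared.split.val], dtype=np.float64)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        sums = {"contr": 0.0, "const": 0.0, "sub": 0.0, "joint": 0.0, "total": 0.0}
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            samples = [train_samples[k] for k in idx]
            batch = prepared.collate(samples)
            out = model.forward_batch(batch, variant=variant, training=True, rng=rng)
            zero = Tensor(np.asarray(0.0))
            l_sub = (
                binary_cross_entropy(out["p_sub"], batch.labels)
                if "p_sub" in out else zero
            )
            l_const = (
                binary_cross_entropy(out["p_const"], batch.labels)
                if "p_const" in out else zero
            )
            l_joint = (
                binary_cross_entropy(out["p_ct"], batch.labels)
                if "p_ct" in out else zero
            )
            if variant == "full" and weights.alpha > 0 and len(samples) >= 2:
                l_contr = contrastive_loss(
                    out["z_t"], out["z_c_proj"],
                    temperature=config.temperature, mode=config.contrastive_mode,
                )
            else:
                l_contr = zero
            if variant == "no_molecular":
                loss = total_loss(zero, zero, l_sub, zero, weights)
            elif variant == "no_subgraph":
                loss = total_loss(zero, l_const, zero, zero, weights)
            else:
                loss = total_loss(l_contr, l_const, l_sub, l_joint, weights)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: total={float(loss.data)} "
                    f"(contr={float(l_contr.data)}, const={float(l_const.data)}, "
                    f"sub={float(l_sub.data)}, joint={float(l_joint.data)})"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            w = len(samples) / n
            for key, t in (
                ("contr", l_contr), ("const", l_const),
                ("sub", l_sub), ("joint", l_joint), ("total", loss),
            ):
                sums[key] += float(t.data) * w
        record = {"epoch": epoch, **{f"l_{k}": v for k, v in sums.items()}}
        if prepared.split.val:
            val_scores = model.predict_scores(prepared, prepared.split.val, variant)
            record.update({f"val_{k}": v for k, v in _epoch_metrics(val_scores, val_labels).items()})
            if np.isfinite(record.get("val_auc", np.nan)) and record["val_auc"] > best_auc:
                best_auc = record["val_auc"]
                best_epoch = epoch
                best_state = model.state_dict()
        history.append(record)
        if verbose:
            print(
                f"epoch {epoch:3d} total={record['l_total']:.4f} "
                f"val_auc={record.get('val_auc', float('nan')):.4f}"
            )
    if best_epoch > 0:
        model.load_state_dict(best_state)
    else:
        best_epoch = config.epochs
        best_state = model.state_dict()
    return TrainResult(model=model, history=history, best_epoch=best_epoch, best_state=best_state)
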