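"""Input/output, featurization, negative sampling and random splits.

File dialects
-------------
* edge list: one interaction per line, ``drug_i<TAB>drug_j``; lines
  starting with ``#`` are comments; extra columns are ignored.
* drug table: ``drug_id<TAB>SMILES`` with the same comment rule.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, MACCSkeys

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

FINGERPRINT_BITS = 166
ATOM_FEATURE_DIM = 78

# Fixed atom-symbol alphabet (44 entries, last is the "other" bucket).
ATOM_SYMBOLS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca",
    "Fe", "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag",
    "Pd", "Co", "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni",
    "Cd", "In", "Mn", "Zr", "Cr", "Pt", "Hg", "Pb", "Unknown",
]


class ParseError(ValueError):
    """A malformed line in an input file."""


class FeaturizationError(ValueError):
    """A SMILES string could not be turned into features."""

    def __init__(self, message: str, drug_id: str | None = None):
        super().__init__(message)
        self.drug_id = drug_id


class CapacityError(ValueError):
    """More negative samples requested than non-edges exist."""


class ConfigError(ValueError):
    """Invalid configuration value."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    smiles: str


def canonical_pair(u: str, v: str) -> tuple[str, str]:
    """Unordered pair stored in lexicographic order."""
    return (u, v) if u <= v else (v, u)


@dataclass
class InteractionNetwork:
    """Undirected drug-drug interaction network without self-loops."""

    nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError(f"self-loop rejected: {u!r}")
        self.nodes.update((u, v))
        self.edges.add(canonical_pair(u, v))

    def has_edge(self, u: str, v: str) -> bool:
        return canonical_pair(u, v) in self.edges

    def adjacency_lists(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(set(self.nodes), set(self.edges))


@dataclass
class MolGraph:
    """Heavy-atom molecular graph with 78-dim atom features."""

    atom_features: np.ndarray  # (m, 78)
    adjacency: np.ndarray  # (m, m) symmetric 0/1, zero diagonal

    def __post_init__(self) -> None:
        if self.atom_features.shape[1] != ATOM_FEATURE_DIM:
            raise ValueError("atom feature width must be 78")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency must have zero diagonal")

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]


@dataclass(frozen=True)
class PairSample:
    drug_i: str
    drug_j: str
    label: int

    def __post_init__(self) -> None:
        if self.drug_i == self.drug_j:
            raise ValueError("a pair sample must reference two distinct drugs")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")

    @property
    def pair(self) -> tuple[str, str]:
        return canonical_pair(self.drug_i, self.drug_j)


@dataclass
class DatasetSplit:
    train: list[PairSample]
    val: list[PairSample]
    test: list[PairSample]
    seed: int

    def to_manifest(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "train": [[s.drug_i, s.drug_j, s.label] for s in self.train],
            "val": [[s.drug_i, s.drug_j, s.label] for s in self.val],
            "test": [[s.drug_i, s.drug_j, s.label] for s in self.test],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_manifest(cls, path: str | Path) -> "DatasetSplit":
        payload = json.loads(Path(path).read_text())
        parts = {
            k: [PairSample(i, j, int(y)) for i, j, y in payload[k]]
            for k in ("train", "val", "test")
        }
        return cls(parts["train"], parts["val"], parts["test"], int(payload["seed"]))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_network(path: str | Path) -> InteractionNetwork:
    """Read an edge-list TSV into a deduplicated undirected network.

    Self-loops and duplicate (unordered) edges are dropped with a log
    message reporting the counts.
    """
    net = InteractionNetwork()
    dropped_self = dropped_dup = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split("\t") if "\t" in line else line.split()
            if len(tokens) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 tab-separated tokens")
            u, v = tokens[0], tokens[1]
            if u == v:
                dropped_self += 1
                continue
            pair = canonical_pair(u, v)
            if pair in net.edges:
                dropped_dup += 1
                continue
            net.add_edge(u, v)
    if net.n_edges == 0:
        warnings.warn(f"{path}: no edges read", stacklevel=2)
    logger.info(
        "read %s: %d nodes, %d edges (%d self-loops dropped, %d duplicates dropped)",
        path, net.n_nodes, net.n_edges, dropped_self, dropped_dup,
    )
    return net


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")


def read_drug_table(path: str | Path) -> list[DrugRecord]:
    """Read a ``drug_id<TAB>SMILES`` table, excluding unparseable records."""
    records: list[DrugRecord] = []
    n_excluded = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split("\t") if "\t" in line else line.split()
            if len(tokens) < 2:
                raise ParseError(f"{path}:{lineno}: expected drug_id and SMILES")
            drug_id, smiles = tokens[0], tokens[1]
            mol = Chem.MolFromSmiles(smiles)
            if mol is None or mol.GetNumAtoms() == 0:
                n_excluded += 1
                logger.warning("excluding %s: unparseable SMILES %r", drug_id, smiles)
                continue
            records.append(DrugRecord(drug_id, smiles))
    seen = [r.drug_id for r in records]
    if len(set(seen)) != len(seen):
        raise ParseError(f"{path}: duplicate drug_id in table")
    if n_excluded:
        logger.info("excluded %d records with invalid SMILES", n_excluded)
    return records


def write_drug_table(records: Sequence[DrugRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.drug_id}\t{rec.smiles}\n")


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------


def _one_hot(value: int | str, choices: Sequence) -> list[float]:
    vec = [0.0] * len(choices)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0  # "other" bucket
    return vec


def atom_features(atom: Chem.Atom) -> np.ndarray:
    """78-dim atom descriptor: symbol, degree, total Hs, implicit valence, aromaticity."""
    feats = (
        _one_hot(atom.GetSymbol(), ATOM_SYMBOLS)
        + _one_hot(atom.GetDegree(), list(range(11)))
        + _one_hot(atom.GetTotalNumHs(), list(range(11)))
        + _one_hot(atom.GetImplicitValence(), list(range(11)))
        + [1.0 if atom.GetIsAromatic() else 0.0]
    )
    return np.asarray(feats, dtype=np.float64)


def smiles_to_molgraph(smiles: str, drug_id: str | None = None) -> MolGraph:
    """Build the heavy-atom graph (covalent-bond adjacency) for one SMILES."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise FeaturizationError(f"unparseable SMILES: {smiles!r}", drug_id=drug_id)
    m = mol.GetNumAtoms()
    feats = np.stack([atom_features(a) for a in mol.GetAtoms()])
    adj = np.zeros((m, m), dtype=np.float64)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[i, j] = adj[j, i] = 1.0
    return MolGraph(feats, adj)


def node_fingerprint(
    smiles: str, drug_id: str | None = None, kind: str = "maccs"
) -> np.ndarray:
    """166-bit structural fingerprint used as subgraph node features.

    ``kind='maccs'`` (default) uses the 166 MACCS structural keys;
    ``kind='morgan166'`` hashes a radius-2 Morgan fingerprint to 166 bits.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise FeaturizationError(f"unparseable SMILES: {smiles!r}", drug_id=drug_id)
    if kind == "maccs":
        bv = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
        vec = np.array(bv, dtype=np.float64)[1:]
    elif kind == "morgan166":
        bv = AllChem.GetMorganFingerprintAsBitVect(mol, radius=2, nBits=FINGERPRINT_BITS)
        vec = np.array(bv, dtype=np.float64)
    else:
        raise ConfigError(f"unknown fingerprint kind: {kind!r}")
    assert vec.shape == (FINGERPRINT_BITS,)
    return vec


def fingerprint_table(
    records: Iterable[DrugRecord], kind: str = "maccs"
) -> dict[str, np.ndarray]:
    return {r.drug_id: node_fingerprint(r.smiles, r.drug_id, kind=kind) for r in records}


# ---------------------------------------------------------------------------
# sampling and splitting
# ---------------------------------------------------------------------------


def sample_negatives(
    net: InteractionNetwork, n_neg: int, seed: int
) -> list[PairSample]:
    """Draw ``n_neg`` distinct non-edge pairs uniformly at random."""
    nodes = sorted(net.nodes)
    n = len(nodes)
    total_pairs = n * (n - 1) // 2
    available = total_pairs - net.n_edges
    if n_neg > available:
        raise CapacityError(
            f"requested {n_neg} negatives but only {available} non-edges exist"
        )
    rng = np.random.default_rng(seed)
    if total_pairs <= 2_000_000:
        non_edges = [
            (nodes[a], nodes[b])
            for a in range(n)
            for b in range(a + 1, n)
            if (nodes[a], nodes[b]) not in net.edges
        ]
        idx = rng.choice(len(non_edges), size=n_neg, replace=False)
        chosen = [non_edges[k] for k in idx]
    else:  # rejection sampling for large graphs
        chosen_set: set[tuple[str, str]] = set()
        while len(chosen_set) < n_neg:
            a, b = rng.integers(0, n, size=2)
            if a == b:
                continue
            pair = canonical_pair(nodes[a], nodes[b])
            if pair in net.edges or pair in chosen_set:
                continue
            chosen_set.add(pair)
        chosen = sorted(chosen_set)
    return [PairSample(u, v, 0) for u, v in chosen]


def positive_samples(net: InteractionNetwork) -> list[PairSample]:
    return [PairSample(u, v, 1) for u, v in sorted(net.edges)]


def random_split(
    samples: Sequence[PairSample],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Shuffle and partition samples into train/val/test by the given ratios."""
    if not math.isclose(sum(ratios), 1.0, abs_tol=1e-9):
        raise ConfigError(f"split ratios must sum to 1, got {ratios}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    shuffled = [samples[k] for k in order]
    n = len(samples)
    n_val = round(ratios[1] * n)
    n_test = round(ratios[2] * n)
    n_train = n - n_val - n_test
    return DatasetSplit(
        train=shuffled[:n_train],
        val=shuffled[n_train : n_train + n_val],
        test=shuffled[n_train + n_val :],
        seed=seed,
    )


def build_pair_dataset(
    net: InteractionNetwork, seed: int
) -> list[PairSample]:
    """All positives plus an equal number of uniformly sampled negatives (1:1)."""
    pos = positive_samples(net)
    neg = sample_negatives(net, len(pos), seed)
    return pos + neg
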