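"""Self-contained synthetic fixtures: a drug library plus a DDI network.

Signal is planted in *both* views so that every downstream experiment is
meaningful: drugs belong to latent classes realized as distinct SMILES
scaffolds (structure view), and edges follow a stochastic block model
over designated interacting class pairs (topology view).  The presets
concentrate interactions in dense intra-class blocks, so an interacting
pair both shares scaffold chemistry and has many common neighbors,
keeping the subgraph view informative.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .data_io import (
    DrugRecord,
    InteractionNetwork,
    write_drug_table,
    write_network,
)

# Linear fragments that stay valid SMILES when concatenated onto a
# scaffold (prefix fragments bond through their last atom, suffix
# fragments through their first).
_PREFIXES = ["", "C", "CC", "CCC", "CC(C)", "OC", "OCC", "NC", "NCC", "COC", "CCCC", "OCC(C)", "CNC"]
_SUFFIXES = ["", "C", "CC", "CCC", "O", "N", "CO", "CN", "Cl", "Br", "C(C)C", "CCO", "CC(C)N"]


class SpecError(ValueError):
    """Invalid synthetic-data specification."""


@dataclass
class SyntheticSpec:
    n_drugs: int
    n_classes: int
    scaffolds: Sequence[str]
    interacting_pairs: Sequence[tuple[int, int]]
    p_in: float = 0.3
    p_out: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise SpecError("need at least two classes")
        if len(self.scaffolds) != self.n_classes:
            raise SpecError("one scaffold per class required")
        if not self.p_in > self.p_out:
            raise SpecError("p_in must exceed p_out")
        for s in self.scaffolds:
            if Chem.MolFromSmiles(s) is None:
                raise SpecError(f"invalid scaffold SMILES: {s!r}")
        self.interacting_pairs = [tuple(sorted(p)) for p in self.interacting_pairs]


def generate_drug_library(spec: SyntheticSpec) -> tuple[list[DrugRecord], np.ndarray]:
    """Decorate each class scaffold with enumerated substituent combos.

    Returns the records plus an integer class label per drug.  SMILES
    within a class are distinct by construction (distinct decoration
    combos); every SMILES is validated with RDKit.
    """
    rng = np.random.default_rng(spec.seed)
    per_class = [spec.n_drugs // spec.n_classes] * spec.n_classes
    for k in range(spec.n_drugs % spec.n_classes):
        per_class[k] += 1
    records: list[DrugRecord] = []
    labels: list[int] = []
    for cls, scaffold in enumerate(spec.scaffolds):
        by_canonical: dict[str, str] = {}
        for pre, post in itertools.product(_PREFIXES, _SUFFIXES):
            smiles = pre + scaffold + post
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                continue
            # chain scaffolds make distinct decorations collide on the
            # same molecule; keep one SMILES per canonical structure
            by_canonical.setdefault(Chem.MolToSmiles(mol), smiles)
        combos = list(by_canonical.values())
        if len(combos) < per_class[cls]:
            raise SpecError(
                f"class {cls}: only {len(combos)} valid decorations for "
                f"{per_class[cls]} requested drugs"
            )
        order = rng.permutation(len(combos))
        for k in range(per_class[cls]):
            drug_id = f"D{len(records):04d}"
            records.append(DrugRecord(drug_id, combos[order[k]]))
            labels.append(cls)
    return records, np.asarray(labels, dtype=np.int64)


def generate_network(
    records: Sequence[DrugRecord],
    labels: np.ndarray,
    spec: SyntheticSpec,
) -> InteractionNetwork:
    """Stochastic block model: p_in on designated class pairs, p_out elsewhere."""
    if not (0 <= spec.p_out < spec.p_in <= 1):
        raise SpecError("edge probabilities must satisfy 0 <= p_out < p_in <= 1")
    rng = np.random.default_rng(spec.seed + 1)
    designated = set(spec.interacting_pairs)
    n = len(records)
    ids = [r.drug_id for r in records]
    a_idx, b_idx = np.triu_indices(n, k=1)
    class_pairs = np.stack(
        [np.minimum(labels[a_idx], labels[b_idx]), np.maximum(labels[a_idx], labels[b_idx])],
        axis=1,
    )
    is_designated = np.array(
        [(int(p[0]), int(p[1])) in designated for p in class_pairs]
    )
    probs = np.where(is_designated, spec.p_in, spec.p_out)
    draws = rng.random(len(a_idx)) < probs
    net = InteractionNetwork(nodes=set(ids))
    for a, b in zip(a_idx[draws], b_idx[draws]):
        net.add_edge(ids[a], ids[b])
    return net


# ---------------------------------------------------------------------------
# named presets
# ---------------------------------------------------------------------------

_SCAFFOLDS_12 = [
    "c1ccccc1",   # benzene
    "c1ccncc1",   # pyridine
    "c1ccoc1",    # furan
    "c1ccsc1",    # thiophene
    "c1cncnc1",   # pyrimidine
    "c1cc[nH]c1", # pyrrole
    "C1CCCCC1",   # cyclohexane
    "C1CCCC1",    # cyclopentane
    "C1CCOC1",    # tetrahydrofuran
    "CCCCCC",     # hexane
    "CCOCC",      # diethyl ether
    "CC(=O)CC",   # ketone chain
]

# Interactions are concentrated *within* classes: dense intra-class
# blocks mean an interacting pair both shares many common neighbors
# (topology signal) and shares a scaffold (structure signal), while the
# designated blocks stay sparse in the overall pair population so the
# planted signal nearly determines the label.
def _self_pairs(n_classes: int) -> list[tuple[int, int]]:
    return [(c, c) for c in range(n_classes)]


PRESETS: dict[str, SyntheticSpec] = {
    "tiny": SyntheticSpec(
        n_drugs=20,
        n_classes=4,
        scaffolds=_SCAFFOLDS_12[:4],
        interacting_pairs=_self_pairs(4) + [(0, 1), (2, 3)],
        p_in=0.6,
        p_out=0.05,
        seed=7,
    ),
    "small": SyntheticSpec(
        n_drugs=100,
        n_classes=6,
        scaffolds=_SCAFFOLDS_12[:3] + _SCAFFOLDS_12[6:9],
        interacting_pairs=_self_pairs(6),
        p_in=0.7,
        p_out=0.01,
        seed=11,
    ),
    "default": SyntheticSpec(
        n_drugs=400,
        n_classes=12,
        scaffolds=_SCAFFOLDS_12,
        interacting_pairs=_self_pairs(12),
        p_in=0.75,
        p_out=0.002,
        seed=13,
    ),
}

# Hop count recommended for training on each preset (the default preset
# is dense enough that 1-hop subgraphs already carry the signal and keep
# the runtime of the end-to-end experiments low).
PRESET_HOP = {"tiny": 2, "small": 1, "default": 1}


def make_dataset(name: str) -> tuple[list[DrugRecord], np.ndarray, InteractionNetwork]:
    """Generate a preset's library and network in memory."""
    if name not in PRESETS:
        raise SpecError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    spec = PRESETS[name]
    records, labels = generate_drug_library(spec)
    net = generate_network(records, labels, spec)
    return records, labels, net


def make_fixture(name: str, out_dir: str | Path) -> dict:
    """Write a preset fixture (drugs.tsv, edges.tsv, manifest.json) to disk."""
    records, labels, net = make_dataset(name)
    spec = PRESETS[name]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_drug_table(records, out / "drugs.tsv")
    write_network(net, out / "edges.tsv")
    manifest = {
        "preset": name,
        "seed": spec.seed,
        "n_drugs": len(records),
        "n_classes": spec.n_classes,
        "p_in": spec.p_in,
        "p_out": spec.p_out,
        "interacting_pairs": [list(p) for p in spec.interacting_pairs],
        "n_edges": net.n_edges,
        "recommended_hop": PRESET_HOP[name],
        "class_labels": {r.drug_id: int(c) for r, c in zip(records, labels)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
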