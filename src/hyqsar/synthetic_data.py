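"""Seeded synthetic molecules and descriptor tables with planted signal.

Every stage of the pipeline is testable without downloads: the generator
emits (i) small valence-correct molecules as SMILES (random bonded trees over
a configurable atom alphabet, optionally seeded with one benzene ring), and
(ii) descriptor tables whose informative columns are simple graph statistics,
padded with standard-normal decoy columns, with a target that is a noisy
linear function of the informative columns. The planted ground truth is
returned alongside, so feature-recovery and significance experiments can be
scored exactly. Everything is deterministic from one root seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemio import DescriptorTable, MolecularGraph, parse_smiles

__all__ = [
    "SyntheticSpec",
    "generate_molecules",
    "generate_descriptor_table",
    "generate_dataset",
    "GRAPH_STATISTICS",
]

#: Maximum heavy-atom valence used while growing molecules.
VALENCE_CAPS = {"C": 4, "N": 3, "O": 2, "S": 2, "Cl": 1, "F": 1, "Br": 1, "P": 3}

#: Graph statistics available as informative descriptor columns, in order.
GRAPH_STATISTICS = (
    "atom_count",
    "heteroatom_count",
    "ring_count",
    "branch_count",
    "mean_bond_order",
)

_ORDER_VALUE = {"single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a synthetic dataset.

    Defaults are the conditions of the planted-signal experiments: 300
    molecules, 2 informative graph statistics with coefficients (2, -1), 50
    standard-normal decoys and Gaussian target noise with sigma 0.1.
    """

    n_molecules: int = 300
    alphabet: tuple[str, ...] = ("C", "N", "O", "S", "Cl")
    size_range: tuple[int, int] = (3, 12)
    ring_probability: float = 0.3
    double_bond_probability: float = 0.15
    n_informative: int = 2
    n_decoys: int = 50
    coefficients: tuple[float, ...] = (2.0, -1.0)
    noise_sigma: float = 0.1
    classification_rule: Optional[object] = None  # a DiscretizationRule
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("need at least one molecule")
        if self.size_range[0] < 1 or self.size_range[0] > self.size_range[1]:
            raise ValueError("invalid size range")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if len(self.coefficients) != self.n_informative:
            raise ValueError("coefficient vector length must equal n_informative")
        bad = [a for a in self.alphabet if a not in VALENCE_CAPS]
        if bad:
            raise ValueError(f"elements without valence caps: {bad}")


def _grow_molecule(rng: np.random.Generator, spec: SyntheticSpec) -> str:
    """Build one valence-correct molecule and return its canonical SMILES."""
    size = int(rng.integers(spec.size_range[0], spec.size_range[1] + 1))
    mol = Chem.RWMol()
    free: list[int] = []   # free valence per atom index

    use_ring = size >= 6 and rng.random() < spec.ring_probability
    if use_ring:
        idx = [mol.AddAtom(Chem.Atom("C")) for _ in range(6)]
        for k in range(6):
            mol.AddBond(idx[k], idx[(k + 1) % 6], Chem.BondType.AROMATIC)
        for a in mol.GetAtoms():
            a.SetIsAromatic(True)
        for b in mol.GetBonds():
            b.SetIsAromatic(True)
        free = [1] * 6  # each aromatic carbon can carry one substituent
        remaining = size - 6
    else:
        # non-leaf start so the tree can grow
        starters = [a for a in spec.alphabet if VALENCE_CAPS[a] >= 2] or list(spec.alphabet)
        sym = starters[int(rng.integers(len(starters)))]
        mol.AddAtom(Chem.Atom(sym))
        free = [VALENCE_CAPS[sym]]
        remaining = size - 1

    for _ in range(remaining):
        anchors = [i for i, f in enumerate(free) if f >= 1]
        if not anchors:
            break
        anchor = anchors[int(rng.integers(len(anchors)))]
        sym = spec.alphabet[int(rng.integers(len(spec.alphabet)))]
        new = mol.AddAtom(Chem.Atom(sym))
        free.append(VALENCE_CAPS[sym])
        aromatic_anchor = mol.GetAtomWithIdx(anchor).GetIsAromatic()
        if (not aromatic_anchor and free[anchor] >= 2 and free[new] >= 2
                and rng.random() < spec.double_bond_probability):
            mol.AddBond(anchor, new, Chem.BondType.DOUBLE)
            used = 2
        else:
            mol.AddBond(anchor, new, Chem.BondType.SINGLE)
            used = 1
        free[anchor] -= used
        free[new] -= used

    m = mol.GetMol()
    Chem.SanitizeMol(m)
    return Chem.MolToSmiles(m)


def generate_molecules(spec: SyntheticSpec) -> list[tuple[str, str]]:
    """Deterministically generate ``(id, SMILES)`` records."""
    rng = np.random.default_rng(spec.seed)
    width = max(4, len(str(spec.n_molecules)))
    return [(f"MOL{i + 1:0{width}d}", _grow_molecule(rng, spec))
            for i in range(spec.n_molecules)]


def graph_statistics(graph: MolecularGraph) -> dict[str, float]:
    """The five structural statistics used as informative columns."""
    hetero = sum(1 for a in graph.atoms if a.element != "C")
    branches = sum(1 for i in range(graph.n_atoms) if graph.degree(i) >= 3)
    rings = len(graph.bonds) - graph.n_atoms + 1  # connected graph cyclomatic number
    mean_order = (float(np.mean([_ORDER_VALUE[o] for _, _, o in graph.bonds]))
                  if graph.bonds else 0.0)
    return {
        "atom_count": float(graph.n_atoms),
        "heteroatom_count": float(hetero),
        "ring_count": float(max(rings, 0)),
        "branch_count": float(branches),
        "mean_bond_order": mean_order,
    }


def generate_descriptor_table(
    graphs: Sequence[MolecularGraph],
    spec: SyntheticSpec,
    ids: Optional[Sequence[str]] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[DescriptorTable, dict]:
    """Descriptor table: informative graph statistics plus seeded noise decoys.

    Returns (table, ground truth); the ground truth names exactly the planted
    informative columns.
    """
    if spec.n_informative > len(GRAPH_STATISTICS):
        raise ValueError(
            f"at most {len(GRAPH_STATISTICS)} informative statistics available")
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    if ids is None:
        ids = [f"MOL{i + 1:04d}" for i in range(len(graphs))]
    stats_rows = [graph_statistics(g) for g in graphs]
    informative = list(GRAPH_STATISTICS[: spec.n_informative])
    frame = pd.DataFrame(
        {name: [row[name] for row in stats_rows] for name in informative},
        index=list(ids))
    decoys = rng.standard_normal((len(graphs), spec.n_decoys))
    for j in range(spec.n_decoys):
        frame[f"DECOY{j + 1:03d}"] = decoys[:, j]
    ground_truth = {"informative": informative,
                    "coefficients": list(spec.coefficients),
                    "noise_sigma": spec.noise_sigma}
    return DescriptorTable(frame), ground_truth


def generate_dataset(spec: SyntheticSpec) -> tuple[DescriptorTable, Optional[pd.Series], dict]:
    """Full synthetic dataset: molecules -> descriptor table -> noisy target.

    ``target = sum(coefficients * informative) + Normal(0, sigma^2)``.
    Returns (table with numeric target attached, optional class-label series
    from the spec's discretization rule, ground truth metadata).
    """
    molecules = generate_molecules(spec)
    ids = [mid for mid, _ in molecules]
    graphs = [parse_smiles(smi) for _, smi in molecules]
    rng = np.random.default_rng(spec.seed + 1)
    table, truth = generate_descriptor_table(graphs, spec, ids=ids, rng=rng)
    signal = table.values[truth["informative"]].to_numpy() @ np.asarray(spec.coefficients)
    noise = rng.normal(0.0, spec.noise_sigma, size=len(ids)) if spec.noise_sigma > 0 \
        else np.zeros(len(ids))
    y = pd.Series(signal + noise, index=table.values.index, name="target")
    labels = None
    if spec.classification_rule is not None:
        for name in truth["informative"]:
            if float(table.values[name].std(ddof=0)) == 0:
                raise ValueError(
                    f"informative column {name} is constant; classes would degenerate")
        labels = pd.Series(spec.classification_rule.apply(y.to_numpy()),
                           index=y.index, name="class")
    truth = dict(truth, smiles=dict(molecules), seed=spec.seed)
    return table.with_target(y, "target"), labels, truth
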