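"""Molecular and tabular I/O.

Parses SMILES into light-weight molecular graphs (the topological space the
neural encoder operates on) and reads/writes the descriptor tables that every
downstream stage consumes: CSV for DRAGON-style descriptor exports and dense
ARFF for interchange with WEKA-family tools.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "AtomNode",
    "MolecularGraph",
    "DescriptorTable",
    "parse_smiles",
    "read_smiles_file",
    "read_descriptor_table",
    "write_descriptor_table",
    "write_arff",
    "read_arff",
]

_BOND_ORDERS = ("single", "double", "triple", "aromatic")

#: Elements recognised without an "unknown" flag; anything else is kept but flagged.
KNOWN_ELEMENTS = frozenset(
    "H B C N O F Si P S Cl Br I Se As Na K Li Mg Ca Fe Zn Cu Mn".split()
)


@dataclass(frozen=True)
class AtomNode:
    """One heavy atom of a molecular graph."""

    element: str
    aromatic: bool = False
    formal_charge: int = 0
    stereo: str = "none"  # one of {"R", "S", "none"}
    known: bool = True


@dataclass
class MolecularGraph:
    """Heavy-atom molecular graph with typed bonds and R/S stereo tags."""

    atoms: list[AtomNode]
    bonds: list[tuple[int, int, str]] = field(default_factory=list)
    smiles: Optional[str] = None

    def __post_init__(self) -> None:
        a = len(self.atoms)
        if a < 1:
            raise ValueError("molecular graph needs at least one atom")
        seen: set[tuple[int, int]] = set()
        for i, j, order in self.bonds:
            if not (0 <= i < a and 0 <= j < a) or i == j:
                raise ValueError(f"bond ({i},{j}) out of range for {a} atoms")
            if order not in _BOND_ORDERS:
                raise ValueError(f"unknown bond order {order!r}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond between atoms {i} and {j}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for i, j, _ in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def degree(self, i: int) -> int:
        return sum(1 for a, b, _ in self.bonds if i in (a, b))

    def to_networkx(self):
        """Export as a networkx.Graph (element/aromatic node attrs, order edge attr)."""
        import networkx as nx

        g = nx.Graph()
        for idx, atom in enumerate(self.atoms):
            g.add_node(idx, element=atom.element, aromatic=atom.aromatic,
                       charge=atom.formal_charge, stereo=atom.stereo)
        for i, j, order in self.bonds:
            g.add_edge(i, j, order=order)
        return g


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed or fails valence rules."""


_ORDER_FROM_RDKIT = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


def parse_smiles(text: str, explicit_h: bool = False) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Heavy atoms only by default (hydrogens stay implicit, matching how SMILES
    suppresses them); pass ``explicit_h=True`` to materialise hydrogens as
    graph nodes. Aromatic perception and R/S assignment follow RDKit.
    """
    if not isinstance(text, str) or not text.strip():
        raise SmilesParseError("empty SMILES string")
    smiles = text.strip()
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        # locate the offending token for the error message
        pos = _first_bad_position(smiles)
        raise SmilesParseError(f"unparsable SMILES {smiles!r} near position {pos}")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # rdkit raises several sanitization subclasses
        raise SmilesParseError(f"invalid molecule {smiles!r}: {exc}") from exc
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    if explicit_h:
        mol = Chem.AddHs(mol)

    atoms: list[AtomNode] = []
    for atom in mol.GetAtoms():
        tag = atom.GetPropsAsDict().get("_CIPCode", "none")
        atoms.append(
            AtomNode(
                element=atom.GetSymbol(),
                aromatic=atom.GetIsAromatic(),
                formal_charge=atom.GetFormalCharge(),
                stereo=tag if tag in ("R", "S") else "none",
                known=atom.GetSymbol() in KNOWN_ELEMENTS,
            )
        )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _ORDER_FROM_RDKIT.get(b.GetBondType(), "single"))
        for b in mol.GetBonds()
    ]
    return MolecularGraph(atoms=atoms, bonds=bonds, smiles=Chem.MolToSmiles(mol))


def _first_bad_position(smiles: str) -> int:
    for end in range(1, len(smiles) + 1):
        if Chem.MolFromSmiles(smiles[:end], sanitize=False) is None:
            return end - 1
    return len(smiles) - 1


def read_smiles_file(path) -> list[tuple[str, str]]:
    """Read a .smi file (``SMILES<TAB>ID`` per line, ID optional) -> [(id, smiles)]."""
    records: list[tuple[str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{lineno}"
            records.append((mol_id, smiles))
    return records


# ---------------------------------------------------------------------------
# Descriptor tables
# ---------------------------------------------------------------------------

class DescriptorTable:
    """Compounds x named numeric descriptors, with an optional target column.

    The common currency of the whole pipeline: DRAGON-style descriptor exports,
    learned code tables and hybrid (joined) tables are all carried in this form.
    Backed by a pandas DataFrame indexed by compound id.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        target: Optional[pd.Series] = None,
        target_name: Optional[str] = None,
    ):
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate compound ids: {dupes}")
        if values.columns.has_duplicates:
            dupes = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate descriptor names: {dupes}")
        arr = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            bad = values.columns[~np.isfinite(arr).all(axis=0)].tolist()
            raise ValueError(f"non-finite values in descriptor columns: {bad}")
        self.values = values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.target = None
        self.target_name = target_name
        if target is not None:
            if len(target) != len(values):
                raise ValueError("target length does not match compound count")
            self.target = pd.Series(np.asarray(target), index=self.values.index,
                                    name=target_name or getattr(target, "name", "target"))
            self.target_name = self.target.name

    # -- basic surface ------------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_compounds(self) -> int:
        return len(self.values)

    def subset(self, names: Sequence[str]) -> "DescriptorTable":
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise KeyError(f"descriptors not in table: {missing}")
        return DescriptorTable(self.values[list(names)].copy(), self.target,
                               self.target_name)

    def take(self, ids: Sequence[str]) -> "DescriptorTable":
        sub = self.values.loc[list(ids)]
        tgt = self.target.loc[list(ids)] if self.target is not None else None
        return DescriptorTable(sub.copy(), tgt, self.target_name)

    def with_target(self, target: pd.Series, name: Optional[str] = None) -> "DescriptorTable":
        return DescriptorTable(self.values.copy(), target, name or getattr(target, "name", "target"))

    def is_numeric_target(self) -> bool:
        if self.target is None:
            raise ValueError("table has no target")
        return pd.api.types.is_numeric_dtype(self.target)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        t = f", target={self.target_name!r}" if self.target is not None else ""
        return f"DescriptorTable({self.n_compounds}x{len(self.values.columns)}{t})"


def read_descriptor_table(
    path,
    id_column: Optional[str] = None,
    target_column: Optional[str] = None,
    impute_mean: bool = False,
) -> DescriptorTable:
    """Read a descriptor CSV (comma separator, '.' decimal, UTF-8).

    The first column is the compound id unless ``id_column`` names another.
    Empty/NA cells are rejected by default; ``impute_mean=True`` replaces them
    with the column mean instead.
    """
    df = pd.read_csv(path, encoding="utf-8")
    if df.empty:
        raise ValueError(f"empty descriptor table: {path}")
    idc = id_column if id_column is not None else df.columns[0]
    if idc not in df.columns:
        raise ValueError(f"id column {idc!r} not found")
    ids = df[idc].astype(str)
    if ids.duplicated().any():
        raise ValueError(f"duplicate compound ids: {ids[ids.duplicated()].unique().tolist()}")
    df = df.drop(columns=[idc])
    df.index = ids

    target = None
    if target_column is not None:
        if target_column not in df.columns:
            raise ValueError(f"target column {target_column!r} not found")
        target = df[target_column]
        if pd.api.types.is_numeric_dtype(target) or _all_floatable(target):
            target = pd.to_numeric(target)
        df = df.drop(columns=[target_column])

    df = df.apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        if impute_mean:
            df = df.fillna(df.mean())
        else:
            bad = df.columns[df.isna().any()].tolist()
            raise ValueError(
                f"missing/non-numeric cells in columns {bad}; "
                "pass impute_mean=True to mean-impute"
            )
    return DescriptorTable(df, target, target_column)


def _all_floatable(series: pd.Series) -> bool:
    try:
        pd.to_numeric(series)
        return True
    except (ValueError, TypeError):
        return False


def write_descriptor_table(table: DescriptorTable, path, id_column: str = "ID") -> None:
    """Write a DescriptorTable as CSV (lossless for finite values)."""
    df = table.values.copy()
    if table.target is not None:
        df[table.target.name] = table.target
    df.index.name = id_column
    df.to_csv(path, float_format="%.17g", encoding="utf-8")


# ---------------------------------------------------------------------------
# ARFF (dense)
# ---------------------------------------------------------------------------

def _quote_nominal(v: str) -> str:
    return f"'{v}'" if re.search(r"[\s,{}]", v) else v


def write_arff(
    table: DescriptorTable,
    path,
    discretization=None,
    relation: str = "hyqsar",
) -> None:
    """Write a dense ARFF file.

    Numeric descriptors are declared numeric. If ``discretization`` (a
    DiscretizationRule from :mod:`hyqsar.qsar_harness`) is given, the numeric
    target is mapped to nominal class labels declared in rule order; otherwise
    a numeric target is written as a numeric attribute and a label target as
    nominal (labels in first-occurrence order).
    """
    if table.n_compounds == 0 or not table.descriptor_names:
        raise ValueError("cannot write an empty table to ARFF")
    lines = [f"@RELATION {relation}", ""]
    for name in table.descriptor_names:
        lines.append(f"@ATTRIBUTE {_quote_nominal(name)} NUMERIC")

    target_values: Optional[list[str]] = None
    if table.target is not None:
        tname = table.target.name
        if discretization is not None:
            labels = discretization.class_labels()
            lines.append(
                f"@ATTRIBUTE {_quote_nominal(tname)} "
                + "{" + ",".join(_quote_nominal(l) for l in labels) + "}"
            )
            target_values = list(discretization.apply(table.target.to_numpy(dtype=float)))
        elif pd.api.types.is_numeric_dtype(table.target):
            lines.append(f"@ATTRIBUTE {_quote_nominal(tname)} NUMERIC")
            target_values = [repr(float(v)) for v in table.target]
        else:
            labels = list(dict.fromkeys(str(v) for v in table.target))
            lines.append(
                f"@ATTRIBUTE {_quote_nominal(tname)} "
                + "{" + ",".join(_quote_nominal(l) for l in labels) + "}"
            )
            target_values = [str(v) for v in table.target]

    lines += ["", "@DATA"]
    mat = table.values.to_numpy(dtype=float)
    for r in range(table.n_compounds):
        row = [repr(float(x)) for x in mat[r]]
        if target_values is not None:
            row.append(_quote_nominal(target_values[r]))
        lines.append(",".join(row))
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)


def read_arff(path) -> DescriptorTable:
    """Read a dense ARFF file written by :func:`write_arff`.

    The last attribute is taken as the target when it is nominal; an
    all-numeric file is read as a plain (untargeted) table.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    attr_names: list[str] = []
    attr_kinds: list[str] = []  # "numeric" | "nominal"
    data_rows: list[list[str]] = []
    in_data = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("@relation"):
            continue
        if low.startswith("@attribute"):
            m = re.match(r"@attribute\s+('(?:[^']*)'|\S+)\s+(.+)$", line, re.I)
            if not m:
                raise ValueError(f"bad attribute line: {line!r}")
            name = m.group(1).strip("'")
            kind = "nominal" if m.group(2).strip().startswith("{") else "numeric"
            attr_names.append(name)
            attr_kinds.append(kind)
            continue
        if low.startswith("@data"):
            in_data = True
            continue
        if in_data:
            data_rows.append([tok.strip().strip("'") for tok in line.split(",")])
    if not attr_names or not data_rows:
        raise ValueError("ARFF file has no attributes or no data")

    has_nominal_target = attr_kinds[-1] == "nominal"
    n_desc = len(attr_names) - 1 if has_nominal_target else len(attr_names)
    values = pd.DataFrame(
        [[float(tok) for tok in row[:n_desc]] for row in data_rows],
        columns=attr_names[:n_desc],
        index=[str(i) for i in range(len(data_rows))],
    )
    target = None
    tname = None
    if has_nominal_target:
        target = pd.Series([row[-1] for row in data_rows], name=attr_names[-1])
        tname = attr_names[-1]
    return DescriptorTable(values, target, tname)
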