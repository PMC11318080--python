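"""Multi-task molecule tables and molecular graph construction.

Datasets are delimited text tables with one SMILES column and one column
per binary property task (cells 0, 1, or empty for missing).  Molecules
are turned into heavy-atom graphs whose atoms carry (atomic number,
chirality tag) and whose bonds carry (bond type, bond direction) as
categorical indices; each bond is stored as two directed edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

MISSING = -1  # sentinel for an absent task label

# Categorical vocabularies.  Atomic numbers 1..118 plus an out-of-range
# slot; chirality and bond enums follow RDKit's order with a trailing
# "other" slot so unseen categories fail loudly downstream rather than
# aliasing a real one.
ATOM_NUM_CLASSES = 119
CHIRALITY_TAGS = [
    Chem.rdchem.ChiralType.CHI_UNSPECIFIED,
    Chem.rdchem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.rdchem.ChiralType.CHI_TETRAHEDRAL_CCW,
    Chem.rdchem.ChiralType.CHI_OTHER,
]
BOND_TYPES = [
    Chem.rdchem.BondType.SINGLE,
    Chem.rdchem.BondType.DOUBLE,
    Chem.rdchem.BondType.TRIPLE,
    Chem.rdchem.BondType.AROMATIC,
]
BOND_DIRS = [
    Chem.rdchem.BondDir.NONE,
    Chem.rdchem.BondDir.ENDUPRIGHT,
    Chem.rdchem.BondDir.ENDDOWNRIGHT,
]

NUM_CHIRALITY = len(CHIRALITY_TAGS)
NUM_BOND_TYPES = len(BOND_TYPES) + 1  # + other
NUM_BOND_DIRS = len(BOND_DIRS)


@dataclass
class MoleculeRecord:
    """One molecule with its per-task binary labels.

    ``labels`` maps task id -> 0/1/MISSING; ``mol_id`` is the stable row
    index within the dataset.
    """

    smiles: str
    labels: dict = field(default_factory=dict)
    mol_id: int = 0


@dataclass
class MolecularGraph:
    """Directed molecular graph with categorical node/edge features.

    node_features: (N, 2) int — atomic number, chirality tag index.
    edge_index:    (2, E) int — source/target, both directions per bond.
    edge_features: (E, 2) int — bond type index, bond direction index.
    """

    node_features: np.ndarray
    edge_index: np.ndarray
    edge_features: np.ndarray

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def num_edges(self) -> int:
        return self.edge_index.shape[1]


class SmilesParseError(ValueError):
    pass


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def _coerce_label(value, row: int, col: str):
    if value is None:
        return MISSING
    if isinstance(value, float) and math.isnan(value):
        return MISSING
    if isinstance(value, str):
        value = value.strip()
        if value == "":
            return MISSING
        try:
            value = float(value)
        except ValueError:
            raise ValueError(
                f"non-binary label {value!r} in column {col!r} at row {row}"
            ) from None
    value = float(value)
    if value not in (0.0, 1.0):
        raise ValueError(f"non-binary label {value!r} in column {col!r} at row {row}")
    return int(value)


def read_dataset(path, smiles_col: str = "smiles", task_cols=None):
    """Read a molecule table into records; invalid SMILES rows are skipped.

    Returns ``(records, n_skipped)``.  ``task_cols=None`` uses every
    column except the SMILES column.  The file extension selects the
    delimiter (``.tsv``/``.txt`` -> tab, otherwise comma).
    """
    import os

    if not os.path.exists(path):
        raise FileNotFoundError(f"dataset file not found: {path}")
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if smiles_col not in df.columns:
        raise ValueError(f"SMILES column {smiles_col!r} not in {list(df.columns)}")
    if task_cols is None:
        task_cols = [c for c in df.columns if c != smiles_col]
    for c in task_cols:
        if c not in df.columns:
            raise ValueError(f"task column {c!r} not in table")

    records: list[MoleculeRecord] = []
    n_skipped = 0
    for row_idx, row in enumerate(df.itertuples(index=False)):
        raw = getattr(row, smiles_col, None)
        if raw is None:  # column name not identifier-safe; fall back by position
            raw = df.iloc[row_idx][smiles_col]
        mol = Chem.MolFromSmiles(str(raw))
        if mol is None:
            n_skipped += 1
            continue
        labels = {
            c: _coerce_label(df.iloc[row_idx][c], row_idx, c) for c in task_cols
        }
        records.append(
            MoleculeRecord(
                smiles=Chem.MolToSmiles(mol), labels=labels, mol_id=len(records)
            )
        )
    if not records:
        raise ValueError(f"no parseable SMILES rows in {path}")
    return records, n_skipped


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Build the heavy-atom graph of ``smiles``.

    One node per heavy atom; every bond contributes two directed edges so
    message passing treats the graph as symmetric.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {smiles!r}")

    node_features = np.empty((mol.GetNumAtoms(), 2), dtype=np.int64)
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        chir = atom.GetChiralTag()
        chir_idx = (
            CHIRALITY_TAGS.index(chir)
            if chir in CHIRALITY_TAGS
            else NUM_CHIRALITY - 1
        )
        node_features[atom.GetIdx()] = (min(z, ATOM_NUM_CLASSES - 1), chir_idx)

    src, dst, efeat = [], [], []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bt = bond.GetBondType()
        bt_idx = BOND_TYPES.index(bt) if bt in BOND_TYPES else NUM_BOND_TYPES - 1
        bd = bond.GetBondDir()
        bd_idx = BOND_DIRS.index(bd) if bd in BOND_DIRS else 0
        src += [u, v]
        dst += [v, u]
        efeat += [(bt_idx, bd_idx), (bt_idx, bd_idx)]

    edge_index = (
        np.array([src, dst], dtype=np.int64)
        if src
        else np.zeros((2, 0), dtype=np.int64)
    )
    edge_features = (
        np.array(efeat, dtype=np.int64) if efeat else np.zeros((0, 2), dtype=np.int64)
    )
    return MolecularGraph(node_features, edge_index, edge_features)


class GraphCache:
    """Memoize graphs keyed by canonical SMILES."""

    def __init__(self):
        self._cache: dict[str, MolecularGraph] = {}

    def get(self, smiles: str) -> MolecularGraph:
        key = canonical_smiles(smiles)
        if key not in self._cache:
            self._cache[key] = smiles_to_graph(key)
        return self._cache[key]
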