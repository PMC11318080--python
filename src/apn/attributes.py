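"""Molecular attribute extraction.

Each molecule gets an attribute vector ``a`` built from one of 14
fingerprint families (seven circular Morgan variants, five path/pair/
torsion hashes, MACCS keys and the Avalon fingerprint), reduced to 100
dimensions with PCA.  Single attributes can be combined in pairs or
triplets by elementwise addition (keeps 100-d) or concatenation, and
precomputed deep embeddings can be ingested from a table keyed by SMILES
and reduced the same way.

Attribute names follow the lowercase convention ``ecfp4``,
``hashap_avalon_ecfp4`` (components joined by underscores).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Avalon import pyAvalonTools
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from sklearn.decomposition import PCA

from .chem_data import canonical_smiles

ATTRIBUTE_DIM = 100  # d^a for single / added attributes

# family -> (generator factory, dimension); MACCS is the one 167-bit kind
_FOLDED_BITS = 1024


def _morgan(radius, features=False):
    kwargs = {"radius": radius, "fpSize": _FOLDED_BITS}
    if features:
        kwargs["atomInvariantsGenerator"] = (
            rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
        )
    return rdFingerprintGenerator.GetMorganGenerator(**kwargs)


def _rdkit_paths(max_path):
    return rdFingerprintGenerator.GetRDKitFPGenerator(
        maxPath=max_path, fpSize=_FOLDED_BITS
    )


_GENERATORS = {
    # circular: trailing digit is the diameter, radius = diameter / 2
    "ecfp0": (lambda: _morgan(0), _FOLDED_BITS),
    "ecfp2": (lambda: _morgan(1), _FOLDED_BITS),
    "ecfp4": (lambda: _morgan(2), _FOLDED_BITS),
    "ecfp6": (lambda: _morgan(3), _FOLDED_BITS),
    "fcfp2": (lambda: _morgan(1, features=True), _FOLDED_BITS),
    "fcfp4": (lambda: _morgan(2, features=True), _FOLDED_BITS),
    "fcfp6": (lambda: _morgan(3, features=True), _FOLDED_BITS),
    # path-based
    "rdk5": (lambda: _rdkit_paths(5), _FOLDED_BITS),
    "rdk6": (lambda: _rdkit_paths(6), _FOLDED_BITS),
    "rdk7": (lambda: _rdkit_paths(7), _FOLDED_BITS),
    "hashap": (
        lambda: rdFingerprintGenerator.GetAtomPairGenerator(fpSize=_FOLDED_BITS),
        _FOLDED_BITS,
    ),
    "hashtt": (
        lambda: rdFingerprintGenerator.GetTopologicalTorsionGenerator(
            fpSize=_FOLDED_BITS
        ),
        _FOLDED_BITS,
    ),
}

FINGERPRINT_REGISTRY = {k: _FOLDED_BITS for k in _GENERATORS}
FINGERPRINT_REGISTRY["maccs"] = 167
FINGERPRINT_REGISTRY["avalon"] = _FOLDED_BITS

FINGERPRINT_KINDS = tuple(FINGERPRINT_REGISTRY)

_GEN_CACHE: dict[str, object] = {}


def fingerprint_dim(kind: str) -> int:
    try:
        return FINGERPRINT_REGISTRY[kind.lower()]
    except KeyError:
        raise KeyError(
            f"unknown fingerprint kind {kind!r}; valid kinds: "
            f"{sorted(FINGERPRINT_REGISTRY)}"
        ) from None


def compute_fingerprint(smiles: str, kind: str) -> np.ndarray:
    """One bit vector of the registry dimension for ``smiles``."""
    kind = kind.lower()
    dim = fingerprint_dim(kind)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES: {smiles!r}")
    if kind == "maccs":
        bits = MACCSkeys.GenMACCSKeys(mol)
    elif kind == "avalon":
        bits = pyAvalonTools.GetAvalonFP(mol, nBits=dim)
    else:
        if kind not in _GEN_CACHE:
            _GEN_CACHE[kind] = _GENERATORS[kind][0]()
        bits = _GEN_CACHE[kind].GetFingerprint(mol)
    arr = np.zeros(dim, dtype=np.float64)
    arr[list(bits.GetOnBits())] = 1.0
    return arr


@dataclass
class FingerprintMatrix:
    """n x dim matrix of one fingerprint family (or a deep embedding)."""

    kind: str
    values: np.ndarray

    @property
    def dim(self) -> int:
        return self.values.shape[1]


def fingerprint_matrix(smiles_list, kind: str) -> FingerprintMatrix:
    rows = [compute_fingerprint(s, kind) for s in smiles_list]
    return FingerprintMatrix(kind=kind.lower(), values=np.vstack(rows))


# ---------------------------------------------------------------------------
# PCA reduction


@dataclass
class ReducerParams:
    """Fitted centering vector + orthonormal projection basis."""

    kind: str
    mean: np.ndarray          # (dim,)
    components: np.ndarray    # (k, dim), k <= target_dim
    target_dim: int

    @property
    def input_dim(self) -> int:
        return self.mean.shape[0]


def fit_reducer(fp: FingerprintMatrix, target_dim: int = ATTRIBUTE_DIM) -> ReducerParams:
    """Fit a centered PCA basis with min(target_dim, n-1, dim) components.

    The full (LAPACK) SVD solver is used so the basis is deterministic;
    sklearn fixes each component's sign so its largest-magnitude loading
    is positive.
    """
    X = fp.values
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 rows")
    k = min(target_dim, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full", whiten=False)
    pca.fit(X)
    return ReducerParams(
        kind=fp.kind,
        mean=pca.mean_,
        components=pca.components_,
        target_dim=target_dim,
    )


@dataclass
class AttributeMatrix:
    """n x d^a attribute vectors, aligned with the dataset's mol_id order."""

    components: list          # source kind names, length 1-3
    agg: str                  # "none" | "addition" | "concatenation"
    values: np.ndarray

    @property
    def name(self) -> str:
        return "_".join(self.components)

    @property
    def dim(self) -> int:
        return self.values.shape[1]


def apply_reducer(fp: FingerprintMatrix, params: ReducerParams) -> AttributeMatrix:
    """Project fingerprints onto the fitted basis, zero-padded to target_dim."""
    if fp.dim != params.input_dim:
        raise ValueError(
            f"dimension mismatch: fingerprints are {fp.dim}-d but the reducer "
            f"was fitted on {params.input_dim}-d input"
        )
    proj = (fp.values - params.mean) @ params.components.T
    if proj.shape[1] < params.target_dim:
        proj = np.hstack(
            [proj, np.zeros((proj.shape[0], params.target_dim - proj.shape[1]))]
        )
    return AttributeMatrix(components=[fp.kind], agg="none", values=proj)


def combine_attributes(parts: list, agg: str) -> AttributeMatrix:
    """Form a dual/triplet attribute by addition or concatenation."""
    if not 2 <= len(parts) <= 3:
        raise ValueError(f"expected 2 or 3 attribute parts, got {len(parts)}")
    if agg not in ("addition", "concatenation"):
        raise ValueError(f"unknown aggregation {agg!r}")
    n = parts[0].values.shape[0]
    if any(p.values.shape[0] != n for p in parts):
        raise ValueError("attribute parts have mismatched row counts")
    if agg == "addition":
        if len({p.dim for p in parts}) != 1:
            raise ValueError("addition requires identical attribute dimensions")
        values = np.sum([p.values for p in parts], axis=0)
    else:
        values = np.hstack([p.values for p in parts])
    components = [c for p in parts for c in p.components]
    return AttributeMatrix(components=components, agg=agg, values=values)


def attribute_pipeline(smiles_list, spec: str, agg: str = "addition") -> AttributeMatrix:
    """Full pipeline: ``spec`` like "ecfp4" or "hashap_avalon_ecfp4".

    Fingerprints are generated for all molecules, each family is reduced
    to 100-d by its own PCA fit on those molecules, and multi-part specs
    are aggregated with ``agg``.
    """
    kinds = spec.lower().split("_")
    singles = []
    for kind in kinds:
        fp = fingerprint_matrix(smiles_list, kind)
        singles.append(apply_reducer(fp, fit_reducer(fp)))
    if len(singles) == 1:
        return singles[0]
    return combine_attributes(singles, agg)


# ---------------------------------------------------------------------------
# Deep (precomputed) embeddings


def load_deep_fingerprints(path, records, tag: str = "deep") -> FingerprintMatrix:
    """Read an embedding table (smiles, v0, v1, ...) aligned to record order.

    Rows are joined on canonical SMILES, so table row order is irrelevant.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    smiles_col = df.columns[0]
    table = {}
    for _, row in df.iterrows():
        table[canonical_smiles(str(row[smiles_col]))] = row.iloc[1:].to_numpy(
            dtype=np.float64
        )
    missing = [r.smiles for r in records if canonical_smiles(r.smiles) not in table]
    if missing:
        raise KeyError(
            f"{len(missing)} molecules missing from embedding table; "
            f"first: {missing[:5]}"
        )
    rows = [table[canonical_smiles(r.smiles)] for r in records]
    values = np.vstack(rows)
    if not np.isfinite(values).all():
        raise ValueError("embedding table contains non-finite values")
    return FingerprintMatrix(kind=f"deep:{tag}", values=values)


# ---------------------------------------------------------------------------
# Relationship taxonomy for attribute combinations

R1, R2, R3 = "R1", "R2", "R3"
HEATMAP_VALUE = {R1: 1.0, R2: 0.5, R3: 0.0}


def classify_relationship(auc_combined: float, auc_fp1: float, auc_fp2: float) -> str:
    """Mutual promotion (R1), one-sided promotion (R2) or inhibition (R3).

    R1 when the combination strictly beats both singles, R3 when it is
    strictly below both; everything else (including ties) is R2.
    """
    for v in (auc_combined, auc_fp1, auc_fp2):
        if not np.isfinite(v):
            raise ValueError("relationship scores must be finite")
    if auc_combined > auc_fp1 and auc_combined > auc_fp2:
        return R1
    if auc_combined < auc_fp1 and auc_combined < auc_fp2:
        return R3
    return R2
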