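"""Synthetic molecule libraries with motif-defined binary property tasks.

Molecules are assembled from an alkyl-chain scaffold whose carbons carry
functional-group decorations (nitro, carboxylic acid, sulfonamide, CF3,
halogens, ...) and optional ring appendages.  Each task is defined by
one functional-group motif (a SMARTS pattern): a molecule is positive
for the task iff the motif occurs, after which labels are flipped with a
configurable noise probability.  Because decorations are sampled
independently per motif, task labels are near-independent and
fingerprint families (ECFP and friends) separate the classes sharply —
a controllable, fully in-silico stand-in for multi-assay screening
panels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

# motif name -> (decoration fragment appended as a chain branch, SMARTS
# that detects it and nothing else in this library).  Motifs are distinct
# heteroaromatic rings and heteroatom-rich groups so circular fingerprints
# separate the classes sharply (each motif seeds many unique atom
# environments); no motif's SMARTS matches any other motif or any decoy
# ring.
MOTIFS = {
    "furan": ("c1ccoc1", "c1ccoc1"),
    "thiophene": ("c1ccsc1", "c1ccsc1"),
    "pyridine": ("c1ccncc1", "c1ccncc1"),
    "pyrimidine": ("c1cncnc1", "c1cncnc1"),
    "pyrrole": ("c1cc[nH]c1", "c1cc[nH]c1"),
    "imidazole": ("c1c[nH]cn1", "c1c[nH]cn1"),
    "morpholine": ("N1CCOCC1", "C1COCCN1"),
    "piperidine": ("N1CCCCC1", "C1CCNCC1"),
    "nitro": ("[N+](=O)[O-]", "[NX3+](=O)[O-]"),
    "sulfonamide": ("S(=O)(=O)N", "[SX4](=O)(=O)[NX3]"),
    "cf3": ("C(F)(F)F", "[CX4](F)(F)F"),
    "carboxyl": ("C(=O)O", "[CX3](=O)[OX2H1]"),
}

# motif-free decoy appendages (carbocycles only)
_RINGS = ("c1ccccc1", "C1CCCCC1", "C1CCCC1")


@dataclass
class SynthSpec:
    n_molecules: int = 2000
    motifs: list = field(default_factory=lambda: list(MOTIFS))
    positive_fraction: float = 0.35
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must be in (0, 1)")
        unknown = [m for m in self.motifs if m not in MOTIFS]
        if unknown:
            raise ValueError(f"unknown motifs {unknown}; available: {list(MOTIFS)}")


def _assemble(frags: list[str], n_extra: int, ring: str | None) -> str:
    """One decorated chain: each fragment branches off its own carbon."""
    parts = [f"C({frag})" for frag in frags]
    if ring is not None:
        parts.append(f"C({ring})")
    parts.append("C" * max(n_extra, 1))
    return "".join(parts)


def generate_library(spec: SynthSpec, return_presence: bool = False):
    """Deterministically build ``n_molecules`` unique, valid SMILES.

    ``return_presence`` additionally returns the boolean motif-inclusion
    matrix used during assembly (one column per motif in spec order).
    """
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    smiles_out: list[str] = []
    presence_out: list[np.ndarray] = []
    while len(smiles_out) < spec.n_molecules:
        include = rng.random(len(spec.motifs)) < spec.positive_fraction
        frags = [MOTIFS[m][0] for m, inc in zip(spec.motifs, include) if inc]
        ring = _RINGS[rng.integers(len(_RINGS))] if rng.random() < 0.4 else None
        n_extra = int(rng.integers(1, 7))
        smi = _assemble(frags, n_extra, ring)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:  # should not happen; skip defensively
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen:
            continue
        seen.add(can)
        smiles_out.append(can)
        presence_out.append(include.copy())
    if return_presence:
        return smiles_out, np.array(presence_out, dtype=bool)
    return smiles_out


def motif_labels(smiles: str, motif: str) -> int:
    """Noise-free label: does the motif's SMARTS occur in the molecule?"""
    patt = Chem.MolFromSmarts(MOTIFS[motif][1])
    mol = Chem.MolFromSmiles(smiles)
    return int(mol.HasSubstructMatch(patt))


def label_tasks(library: list[str], spec: SynthSpec) -> "object":
    """Label the library for every motif task; returns a pandas DataFrame.

    Columns: ``smiles`` plus one 0/1 column per motif.  Labels are the
    motif-presence indicator flipped with probability ``label_noise``
    (one independent noise stream per task).
    """
    import pandas as pd

    patterns = {m: Chem.MolFromSmarts(MOTIFS[m][1]) for m in spec.motifs}
    mols = [Chem.MolFromSmiles(s) for s in library]
    data = {"smiles": library}
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    for m in spec.motifs:
        clean = np.array(
            [int(mol.HasSubstructMatch(patterns[m])) for mol in mols], dtype=np.int64
        )
        if clean.sum() == 0:
            raise ValueError(
                f"motif {m!r} matched nothing in the library; "
                "increase n_molecules or positive_fraction"
            )
        flips = rng.random(len(library)) < spec.label_noise
        data[m] = np.where(flips, 1 - clean, clean)
    return pd.DataFrame(data)


def make_benchmark(
    spec: SynthSpec,
    n_train_tasks: int = 9,
    n_test_tasks: int = 3,
    out_dir=None,
):
    """Build a meta-train / meta-test benchmark with disjoint task motifs.

    Returns ``(table, split)`` where ``split`` is a dict with
    ``train_tasks`` and ``test_tasks`` lists.  When ``out_dir`` is given,
    writes ``molecules.csv`` and ``split.json`` there (byte-stable for a
    fixed spec).
    """
    if n_train_tasks + n_test_tasks > len(spec.motifs):
        raise ValueError(
            f"need {n_train_tasks + n_test_tasks} motifs but spec has "
            f"{len(spec.motifs)}"
        )
    library = generate_library(spec)
    table = label_tasks(library, spec)
    split = {
        "train_tasks": list(spec.motifs[:n_train_tasks]),
        "test_tasks": list(spec.motifs[n_train_tasks:n_train_tasks + n_test_tasks]),
    }
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        table.to_csv(os.path.join(out_dir, "molecules.csv"), index=False)
        with open(os.path.join(out_dir, "split.json"), "w") as fh:
            json.dump(split, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return table, split
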