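"""Molecule parsing and the 179-descriptor featurization.

Every compound is mapped to a fixed-length vector of 179 two-dimensional
descriptors arranged in three blocks:

* ``[0, 8)``   — eight drug-likeness properties (molecular weight, calculated
  logP, H-bond donor/acceptor counts, rotatable bonds, topological polar
  surface area, ring count, heavy-atom count);
* ``[8, 32)``  — twenty-four continuous BCUT-style descriptors: the four
  lowest and four highest eigenvalues of the Burden connectivity matrix under
  three atomic weightings (atomic mass, Pauling electronegativity, covalent
  radius);
* ``[32, 179)`` — a 147-bit pharmacophore-pair fingerprint: 21 unordered
  pairs of six pharmacophore classes (donor, acceptor, aromatic, hydrophobe,
  positive, negative) times 7 topological-distance bins.

The exact descriptor panel of the original PowerMV/CDK pipeline is
proprietary; this scheme is a documented structural equivalent with the same
8 + 24 + 147 block layout.  All descriptors are computed on the
implicit-hydrogen (heavy-atom) molecular graph and are pure functions of
that graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

logger = logging.getLogger("rfscreen")

# RDKit's C++ layer prints its own parse diagnostics; we report skips through
# the package logger instead.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

ACTIVE = 1
INACTIVE = 0

N_DESCRIPTORS = 179
BLOCK_DRUGLIKE = slice(0, 8)
BLOCK_BCUT = slice(8, 32)
BLOCK_FINGERPRINT = slice(32, 179)

_ACTIVE_TOKENS = {"active", "1", "true"}
_INACTIVE_TOKENS = {"inactive", "0", "false"}


class DescriptorError(RuntimeError):
    """Raised when descriptor computation fails for a molecule."""


class InputFormatError(ValueError):
    """Raised for unreadable or structurally invalid input files."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MoleculeRecord:
    """One parsed compound: identifier, RDKit graph, optional activity label."""

    id: str
    structure: Chem.Mol
    activity: Optional[int] = None
    source_index: int = 0

    def __post_init__(self) -> None:
        if self.structure is None or self.structure.GetNumAtoms() == 0:
            raise ValueError(f"molecule {self.id!r} has no atoms")
        if self.activity is not None and self.activity not in (ACTIVE, INACTIVE):
            raise ValueError(f"activity must be {ACTIVE} or {INACTIVE}")


@dataclass
class FeatureTable:
    """n compounds x 179 descriptors, with ids and optional binary labels."""

    matrix: np.ndarray
    ids: list[str]
    labels: Optional[np.ndarray] = None
    column_names: list[str] = field(default_factory=lambda: descriptor_names())

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != N_DESCRIPTORS:
            raise ValueError(
                f"feature matrix must be n x {N_DESCRIPTORS}, got {self.matrix.shape}"
            )
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("ids length does not match row count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.matrix.shape[0],):
                raise ValueError("labels length does not match row count")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _map_activity(raw: str) -> Optional[int]:
    token = raw.strip().lower()
    if token in _ACTIVE_TOKENS:
        return ACTIVE
    if token in _INACTIVE_TOKENS:
        return INACTIVE
    return None


def read_sdf(path: str | Path, activity_tag: Optional[str] = None) -> list[MoleculeRecord]:
    """Parse an MDL SDF file into molecule records.

    Malformed molecule blocks are skipped with a logged warning.  When
    ``activity_tag`` is given, tag values are mapped case-insensitively:
    active/1/true -> active, inactive/0/false -> inactive; records carrying
    any other value (e.g. "Inconclusive") are dropped with a warning so they
    never enter training.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"SDF file not found: {path}")
    try:
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    except OSError as exc:
        raise InputFormatError(f"unreadable SDF file {path}: {exc}") from exc
    records: list[MoleculeRecord] = []
    skipped = 0
    for i, mol in enumerate(supplier):
        if mol is None:
            skipped += 1
            logger.warning("skipping malformed SDF block %d in %s", i, path.name)
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
        activity: Optional[int] = None
        if activity_tag is not None and mol.HasProp(activity_tag):
            activity = _map_activity(mol.GetProp(activity_tag))
            if activity is None:
                skipped += 1
                logger.warning(
                    "dropping molecule %s: unrecognised %s value %r",
                    mol_id, activity_tag, mol.GetProp(activity_tag),
                )
                continue
        records.append(MoleculeRecord(id=mol_id, structure=mol, activity=activity, source_index=i))
    if not records:
        raise InputFormatError(f"no parseable molecules in {path}")
    if skipped:
        logger.warning("%d of %d SDF entries skipped in %s", skipped, skipped + len(records), path.name)
    return records


def read_smiles(path: str | Path) -> list[MoleculeRecord]:
    """Parse a one-SMILES-per-line file (optional second token used as id)."""
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"SMILES file not found: {path}")
    records: list[MoleculeRecord] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            tokens = line.split()
            mol = Chem.MolFromSmiles(tokens[0])
            if mol is None:
                skipped += 1
                logger.warning("skipping unparseable SMILES on line %d of %s", i + 1, path.name)
                continue
            mol_id = tokens[1] if len(tokens) > 1 else f"mol{i}"
            records.append(MoleculeRecord(id=mol_id, structure=mol, source_index=i))
    if not records:
        raise InputFormatError(f"no parseable molecules in {path}")
    if skipped:
        logger.warning("%d lines skipped in %s", skipped, path.name)
    return records


# ---------------------------------------------------------------------------
# Block 1: drug-likeness panel
# ---------------------------------------------------------------------------

def _druglike_block(mol: Chem.Mol) -> np.ndarray:
    return np.array(
        [
            Descriptors.MolWt(mol),
            Crippen.MolLogP(mol),
            Lipinski.NumHDonors(mol),
            Lipinski.NumHAcceptors(mol),
            Lipinski.NumRotatableBonds(mol),
            rdMolDescriptors.CalcTPSA(mol),
            rdMolDescriptors.CalcNumRings(mol),
            mol.GetNumHeavyAtoms(),
        ],
        dtype=float,
    )


# ---------------------------------------------------------------------------
# Block 2: Burden-matrix (BCUT-style) eigenvalue descriptors
# ---------------------------------------------------------------------------

# Pauling electronegativities for elements common in drug-like molecules.
_ELECTRONEGATIVITY = {
    1: 2.20, 3: 0.98, 5: 2.04, 6: 2.55, 7: 3.04, 8: 3.44, 9: 3.98,
    11: 0.93, 12: 1.31, 14: 1.90, 15: 2.19, 16: 2.58, 17: 3.16,
    19: 0.82, 20: 1.00, 26: 1.83, 29: 1.90, 30: 1.65, 33: 2.18,
    34: 2.55, 35: 2.96, 50: 1.96, 53: 2.66,
}
_DEFAULT_ELECTRONEGATIVITY = 2.0

_BOND_ORDER_WEIGHT = {
    Chem.BondType.SINGLE: 0.1,
    Chem.BondType.DOUBLE: 0.2,
    Chem.BondType.TRIPLE: 0.3,
    Chem.BondType.AROMATIC: 0.15,
}

_PT = Chem.GetPeriodicTable()


def _atomic_property(atom: Chem.Atom, weighting: str) -> float:
    z = atom.GetAtomicNum()
    if weighting == "mass":
        return _PT.GetAtomicWeight(z)
    if weighting == "eneg":
        return _ELECTRONEGATIVITY.get(z, _DEFAULT_ELECTRONEGATIVITY)
    if weighting == "radius":
        return _PT.GetRcovalent(z)
    raise ValueError(f"unknown weighting {weighting!r}")


def _burden_matrix(mol: Chem.Mol, weighting: str) -> np.ndarray:
    """Symmetric Burden connectivity matrix on the heavy-atom graph.

    Diagonal carries the atomic property; bonded pairs get 0.1 x bond-order
    weight (+0.01 if either endpoint is terminal, after Burden); non-bonded
    pairs a small constant 0.001 so the matrix couples the whole graph.
    """
    n = mol.GetNumAtoms()
    b = np.full((n, n), 0.001)
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        b[i, i] = _atomic_property(atom, weighting)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        w = _BOND_ORDER_WEIGHT.get(bond.GetBondType(), 0.1)
        if bond.GetBeginAtom().GetDegree() == 1 or bond.GetEndAtom().GetDegree() == 1:
            w += 0.01
        b[i, j] = b[j, i] = w
    return b


def _extreme_eigenvalues(matrix: np.ndarray, k: int = 4) -> np.ndarray:
    """k lowest then k highest eigenvalues, padded by repetition for tiny graphs."""
    eig = np.sort(np.linalg.eigvalsh(matrix))
    lo = eig[:k]
    hi = eig[-k:]
    if eig.size < k:
        lo = np.concatenate([eig, np.repeat(eig[0], k - eig.size)])
        hi = np.concatenate([np.repeat(eig[-1], k - eig.size), eig])
    return np.concatenate([lo, hi])


def _bcut_block(mol: Chem.Mol) -> np.ndarray:
    parts = [
        _extreme_eigenvalues(_burden_matrix(mol, weighting))
        for weighting in ("mass", "eneg", "radius")
    ]
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# Block 3: pharmacophore-pair fingerprint
# ---------------------------------------------------------------------------

_PHARMACOPHORE_CLASSES = ("donor", "acceptor", "aromatic", "hydrophobe", "positive", "negative")

_PHARMACOPHORE_SMARTS = {
    "donor": "[$([#7;!H0]),$([#8;!H0]),$([#16;!H0])]",
    "acceptor": "[$([#8;!$(O=N)]),$([#7;!+;!X4])]",
    "aromatic": "[a]",
    "hydrophobe": "[$([C;!$(C~[#7,#8,F,Cl,Br,I])]),$([c;!$(c~[#7,#8])]),$([Cl,Br,I]),$([S;X2;$(S(C)C)])]",
    "positive": "[$([*;+;!$([*;-])]),$([NX3;H2;$(N[CX4]);!$(NC=O)]),$([NX4])]",
    "negative": "[$([*;-]),$([OX2H1][CX3]=O),$([OX2H1][SX4](=O)=O),$([OX2H1][PX4]=O)]",
}

_PHARMACOPHORE_PATTERNS = {
    name: Chem.MolFromSmarts(smarts) for name, smarts in _PHARMACOPHORE_SMARTS.items()
}
assert all(p is not None for p in _PHARMACOPHORE_PATTERNS.values())

# unordered pairs with repetition: 6 classes -> 21 pairs
_CLASS_PAIRS = [
    (i, j)
    for i in range(len(_PHARMACOPHORE_CLASSES))
    for j in range(i, len(_PHARMACOPHORE_CLASSES))
]
_N_DISTANCE_BINS = 7  # bond-path distance 1..6, then >=7


def _distance_bin(d: int) -> int:
    return min(int(d), 7) - 1


def _fingerprint_block(mol: Chem.Mol) -> np.ndarray:
    """147 bits: bit (pair, bin) set iff atoms of those classes occur at that
    topological distance. Same-class pairs require two distinct atoms."""
    class_atoms: list[np.ndarray] = []
    for name in _PHARMACOPHORE_CLASSES:
        matches = mol.GetSubstructMatches(_PHARMACOPHORE_PATTERNS[name])
        class_atoms.append(np.unique([m[0] for m in matches]).astype(int) if matches else np.empty(0, dtype=int))
    dmat = Chem.GetDistanceMatrix(mol)
    bits = np.zeros(len(_CLASS_PAIRS) * _N_DISTANCE_BINS)
    for pair_idx, (a, b) in enumerate(_CLASS_PAIRS):
        atoms_a, atoms_b = class_atoms[a], class_atoms[b]
        if atoms_a.size == 0 or atoms_b.size == 0:
            continue
        sub = dmat[np.ix_(atoms_a, atoms_b)]
        # disconnected fragments get a huge sentinel distance; exclude them
        dists = np.unique(sub[(sub >= 1) & (sub < 1e6)])
        for d in dists:
            bits[pair_idx * _N_DISTANCE_BINS + _distance_bin(d)] = 1.0
    return bits


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

def compute_descriptors(mol: MoleculeRecord) -> np.ndarray:
    """Full 179-slot descriptor vector for one molecule (deterministic)."""
    blocks = (
        ("drug-likeness", _druglike_block),
        ("BCUT", _bcut_block),
        ("fingerprint", _fingerprint_block),
    )
    parts = []
    for block_name, fn in blocks:
        try:
            part = fn(mol.structure)
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise DescriptorError(
                f"descriptor failure for molecule {mol.id!r} in {block_name} block: {exc}"
            ) from exc
        if not np.all(np.isfinite(part)):
            raise DescriptorError(
                f"non-finite descriptor for molecule {mol.id!r} in {block_name} block"
            )
        parts.append(part)
    vec = np.concatenate(parts)
    assert vec.shape == (N_DESCRIPTORS,)
    return vec


def descriptor_names() -> list[str]:
    """Stable names for all 179 descriptor slots (DL_/BCUT_/PF_ prefixes)."""
    names = [
        "DL_mol_weight", "DL_logp", "DL_hbond_donors", "DL_hbond_acceptors",
        "DL_rotatable_bonds", "DL_tpsa", "DL_ring_count", "DL_heavy_atoms",
    ]
    for weighting in ("mass", "eneg", "radius"):
        names.extend(f"BCUT_{weighting}_lo{i}" for i in range(1, 5))
        names.extend(f"BCUT_{weighting}_hi{i}" for i in range(1, 5))
    for a, b in _CLASS_PAIRS:
        pa, pb = _PHARMACOPHORE_CLASSES[a], _PHARMACOPHORE_CLASSES[b]
        names.extend(f"PF_{pa}_{pb}_d{d}" for d in range(1, _N_DISTANCE_BINS + 1))
    assert len(names) == N_DESCRIPTORS and len(set(names)) == N_DESCRIPTORS
    return names


def featurize(mols: Sequence[MoleculeRecord]) -> FeatureTable:
    """Featurize a molecule list into a FeatureTable (row i <-> mols[i]).

    Labels are populated only when every molecule carries an activity label;
    a mixed list yields an unlabelled table with a warning.
    """
    mols = list(mols)
    if not mols:
        raise ValueError("cannot featurize an empty molecule list")
    rows = np.empty((len(mols), N_DESCRIPTORS))
    for i, rec in enumerate(mols):
        try:
            rows[i] = compute_descriptors(rec)
        except DescriptorError as exc:
            raise DescriptorError(f"row {i}: {exc}") from exc
    labelled = [rec.activity is not None for rec in mols]
    labels: Optional[np.ndarray] = None
    if all(labelled):
        labels = np.array([rec.activity for rec in mols], dtype=int)
    elif any(labelled):
        logger.warning("mixed labelled/unlabelled molecules: labels dropped")
    return FeatureTable(matrix=rows, ids=[rec.id for rec in mols], labels=labels)


# ---------------------------------------------------------------------------
# CSV persistence
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV: id, 179 descriptor columns, optional activity."""
    df = pd.DataFrame(table.matrix, columns=table.column_names)
    df.insert(0, "id", table.ids)
    if table.labels is not None:
        df["activity"] = table.labels
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature-table CSV written by :func:`write_feature_table`."""
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"feature table not found: {path}")
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise InputFormatError("feature table is missing the 'id' column")
    feature_cols = [c for c in df.columns if c not in ("id", "activity")]
    if len(feature_cols) != N_DESCRIPTORS:
        raise InputFormatError(
            f"expected {N_DESCRIPTORS} feature columns, got {len(feature_cols)}"
        )
    labels = df["activity"].to_numpy(dtype=int) if "activity" in df.columns else None
    return FeatureTable(
        matrix=df[feature_cols].to_numpy(dtype=float),
        ids=[str(x) for x in df["id"]],
        labels=labels,
        column_names=feature_cols,
    )
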