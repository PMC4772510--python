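"""Synthetic bioassay-like data for testing and desk-scale experiments.

``generate_assay`` emulates a PubChem-style binary bioassay feature table:
imbalanced active/inactive labels (default active fraction 0.125, echoing
large antimycobacterial screens where roughly one compound in eight is
active), 32 continuous descriptor columns and 147 sparse fingerprint bits
honouring the 8 + 24 + 147 block structure.  Class signal is injected
linearly: a seed-chosen subset of columns is mean-shifted (continuous) or
probability-shifted (bits) for the actives.  ``generate_molecules`` writes
small valid drug-like structures as paired SDF/SMILES fixture files so the
parsing and featurization pipeline is testable without any download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem

from .descriptors import (
    ACTIVE,
    INACTIVE,
    BLOCK_FINGERPRINT,
    N_DESCRIPTORS,
    FeatureTable,
)

N_CONTINUOUS = BLOCK_FINGERPRINT.start  # 32
N_BITS = N_DESCRIPTORS - N_CONTINUOUS  # 147
BIT_BASE_PROBABILITY = 0.1  # sparse fingerprints are the realistic regime


@dataclass
class AssaySpec:
    """Parameters of one synthetic bioassay."""

    n: int
    active_fraction: float = 0.125
    n_informative: int = 20
    effect_size: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not (0.0 < self.active_fraction < 1.0):
            raise ValueError("active_fraction must be in (0, 1)")
        if not (0 <= self.n_informative <= N_DESCRIPTORS):
            raise ValueError(f"n_informative must be in [0, {N_DESCRIPTORS}]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        n_active = math.ceil(self.n * self.active_fraction)
        if n_active == 0 or n_active == self.n:
            raise ValueError("spec yields a single-class assay")

    @property
    def n_active(self) -> int:
        return math.ceil(self.n * self.active_fraction)


def generate_assay(spec: AssaySpec) -> FeatureTable:
    """Labelled n x 179 feature table with exactly ceil(n * active_fraction) actives.

    Informative columns are chosen deterministically from the seed,
    stratified across the two blocks in proportion to their sizes
    (``round(n_informative * 32/179)`` continuous columns, the rest bits) so
    that a given effect size injects a comparable amount of signal whatever
    the seed.  For active compounds, informative continuous columns are
    shifted by ``effect_size * noise_sd`` and informative bit columns get
    their on-probability raised by ``min(effect_size * 0.1, 0.4)``.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    n_active = spec.n_active
    labels = np.full(spec.n, INACTIVE, dtype=int)
    labels[:n_active] = ACTIVE
    rng.shuffle(labels)

    n_cont_inf = min(round(spec.n_informative * N_CONTINUOUS / N_DESCRIPTORS), N_CONTINUOUS)
    info_cont = np.sort(rng.choice(N_CONTINUOUS, size=n_cont_inf, replace=False))
    info_bits = np.sort(rng.choice(N_BITS, size=spec.n_informative - n_cont_inf, replace=False))

    cont = rng.normal(0.0, spec.noise_sd, size=(spec.n, N_CONTINUOUS))
    cont[np.ix_(labels == ACTIVE, info_cont)] += spec.effect_size * spec.noise_sd

    p = np.full((spec.n, N_BITS), BIT_BASE_PROBABILITY)
    bit_shift = min(spec.effect_size * 0.1, 0.4)
    p[np.ix_(labels == ACTIVE, info_bits)] += bit_shift
    bits = (rng.random((spec.n, N_BITS)) < p).astype(float)

    ids = [f"cmpd{i:06d}" for i in range(spec.n)]
    return FeatureTable(matrix=np.hstack([cont, bits]), ids=ids, labels=labels)


# ---------------------------------------------------------------------------
# Toy molecule files
# ---------------------------------------------------------------------------

_SCAFFOLD_TEMPLATES = [
    "c1ccc({})cc1",            # benzene
    "c1ccc2ccccc2c1{}",        # naphthalene (appended chain)
    "c1ccncc1{}",              # pyridine
    "c1ccc(C(=O)N{})cc1",      # benzamide
    "C1CCCCC1{}",              # cyclohexane
    "c1ccc(O{})cc1",           # phenol ether
    "c1ccc(S(=O)(=O)N{})cc1",  # benzenesulfonamide
    "c1ccc(-c2ccccc2){}cc1",   # biphenyl
    "C1CCNCC1{}",              # piperidine
    "c1ccoc1{}",               # furan
]

_DECORATIONS = ["C", "CC", "CCO", "CCN", "CC(C)C", "CCl", "CC(=O)O", "CCF", "CCCN", "CC#N"]


def _molecule_pool() -> list[str]:
    """Enumerated scaffold x decoration SMILES pool (valid structures only)."""
    pool = []
    for template in _SCAFFOLD_TEMPLATES:
        for dec in _DECORATIONS:
            smiles = template.format(dec)
            mol = Chem.MolFromSmiles(smiles)
            if mol is not None:
                pool.append(Chem.MolToSmiles(mol))
    return pool


def generate_molecules(n: int, seed: int, path: str | Path) -> tuple[Path, Path]:
    """Write n toy drug-like molecules as ``<path>.sdf`` and ``<path>.smi``.

    Each record carries an id and a synthetic ACTIVITY tag (Active/Inactive,
    drawn at rate 0.3) so the SDF exercises activity parsing.  Output is
    byte-identical for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    path = Path(path)
    pool = _molecule_pool()
    rng = np.random.Generator(np.random.PCG64(seed))
    picks = rng.integers(0, len(pool), size=n)
    activities = rng.random(n) < 0.3

    sdf_path = path.with_suffix(".sdf")
    smi_path = path.with_suffix(".smi")
    writer = Chem.SDWriter(str(sdf_path))
    try:
        with open(smi_path, "w", encoding="utf-8") as smi:
            for i, (k, active) in enumerate(zip(picks, activities)):
                mol = Chem.MolFromSmiles(pool[k])
                mol_id = f"synth{i:05d}"
                mol.SetProp("_Name", mol_id)
                mol.SetProp("ACTIVITY", "Active" if active else "Inactive")
                writer.write(mol)
                smi.write(f"{pool[k]} {mol_id}\n")
    finally:
        writer.close()
    return sdf_path, smi_path
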