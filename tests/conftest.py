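import numpy as np
import pytest

import rfscreen as rf


@pytest.fixture(scope="session")
def molfiles(tmp_path_factory):
    """Toy SDF/SMILES fixture files (12 molecules, ACTIVITY tag)."""
    base = tmp_path_factory.mktemp("mols") / "toy"
    sdf, smi = rf.generate_molecules(12, seed=42, path=base)
    return sdf, smi


@pytest.fixture(scope="session")
def assay_small():
    """Separable labelled assay, n=200."""
    return rf.generate_assay(rf.AssaySpec(n=200, effect_size=2.0, seed=1))


@pytest.fixture(scope="session")
def small_model(assay_small):
    return rf.train_forest(assay_small, rf.ForestParams(n_trees=7, seed=3))


def split_table(table, frac=0.75, seed=0):
    """Deterministic train/test split of a FeatureTable."""
    rng = np.random.Generator(np.random.PCG64(seed))
    idx = rng.permutation(table.n)
    k = int(table.n * frac)

    def sub(ix):
        return rf.FeatureTable(
            matrix=table.matrix[ix],
            ids=[table.ids[i] for i in ix],
            labels=None if table.labels is None else table.labels[ix],
        )

    return sub(idx[:k]), sub(idx[k:])
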