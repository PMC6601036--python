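import numpy as np
import pytest

from lbvs import chemio
from lbvs.ml import split_dataset, train_random_forest
from lbvs.synthdata import SyntheticSpec, gen_dataset

# Standard two-Gaussian benchmark: 500 compounds per class, 10 descriptors,
# one informative with class-mean separation 4 pooled sd (Bayes error ~2.3%).
BENCH_SPEC = SyntheticSpec(
    n_per_class=500, p=10, separation=4.0, informative=1, seed=20190604 % 2**31
)
BENCH_SEED = 42


@pytest.fixture(scope="session")
def bench_data():
    return gen_dataset(BENCH_SPEC)


@pytest.fixture(scope="session")
def bench_split(bench_data):
    return split_dataset(bench_data, 2.0 / 3.0, BENCH_SEED)


@pytest.fixture(scope="session")
def bench_rf(bench_split):
    train, _ = bench_split
    return train_random_forest(train, m_try=3, n_tree=300, seed=BENCH_SEED)


def mol(smiles: str, mol_id: str = "") -> chemio.Molecule:
    return chemio.standardize(chemio.read_smiles(smiles, mol_id or smiles))


@pytest.fixture(scope="session")
def test_molecules():
    """Small organics spanning rings, branches, heteroatoms (<= 8 heavy atoms)."""
    smiles = [
        "CC", "CCC", "CCCC", "CC(C)C", "CC(C)(C)C", "CCO", "CC(=O)O",
        "C1CCCC1", "C1CCCCC1", "c1ccccc1", "c1ccncc1", "C1CC1", "C1CCC1",
        "CC(=O)N", "CCS", "FC(F)(F)C", "C1=CC=CO1", "CC#N", "CCCl",
        "OC1CCCC1",
    ]
    return [mol(s) for s in smiles]
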