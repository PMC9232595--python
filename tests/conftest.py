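import numpy as np
import pytest

from pepos import (
    SignalSpec,
    gen_feature_dataset,
    gen_toy_complex,
    score_structure,
)


@pytest.fixture(scope="session")
def toy_complex():
    return gen_toy_complex(seed=7, peptide_length=9, perturbation_scale=0.1)


@pytest.fixture(scope="session")
def toy_table(toy_complex):
    return score_structure(toy_complex)


@pytest.fixture(scope="session")
def small_dataset():
    """Two alleles x 400 records, default anchor threshold-interaction signal."""
    return gen_feature_dataset(n_alleles=2, n_per_allele=400, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def make_atoms(spec_rows):
    """Build Atom objects from (chain, resix, resname, atom_name, element, xyz)."""
    from pepos import Atom

    return [Atom(c, i, rn, an, el, tuple(map(float, xyz)))
            for c, i, rn, an, el, xyz in spec_rows]
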