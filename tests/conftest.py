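import numpy as np
import pytest

from oncorepurpose.chem import Molecule
from oncorepurpose.curation import CatalogueEntry
from oncorepurpose.synthetic import BenchmarkConfig, make_benchmark


@pytest.fixture(scope="session")
def toy_catalogue():
    """Six-drug catalogue exercising every curation rule by hand.

    Two positives, one approved drug in a cancer trial, one approved drug
    chemically identical to a positive, and two clean approved drugs.
    """
    return [
        CatalogueEntry(Molecule("pos1", "c1ccc2cc3cc4ccccc4cc3cc2c1"),
                       approved=True, in_cancer_trial=False, known_anticancer=True),
        CatalogueEntry(Molecule("pos2", "O=[N+]([O-])c1ccc2ccccc2c1"),
                       approved=True, in_cancer_trial=True, known_anticancer=True),
        CatalogueEntry(Molecule("trial1", "Clc1ccc2ncccc2c1"),
                       approved=True, in_cancer_trial=True, known_anticancer=False),
        CatalogueEntry(Molecule("dup_pos", "c1ccc2cc3cc4ccccc4cc3cc2c1"),
                       approved=True, in_cancer_trial=False, known_anticancer=False),
        CatalogueEntry(Molecule("clean1", "CCO"),
                       approved=True, in_cancer_trial=False, known_anticancer=False),
        CatalogueEntry(Molecule("clean2", "CC(=O)Nc1ccc(O)cc1"),
                       approved=True, in_cancer_trial=False, known_anticancer=False),
    ]


@pytest.fixture(scope="session")
def small_bundle():
    """Small synthetic benchmark shared by feature/model tests."""
    return make_benchmark(BenchmarkConfig(n_drugs=120, n_targets=40, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
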