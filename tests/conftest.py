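import numpy as np
import pandas as pd
import pytest

from mirdecoy import constructs
from mirdecoy.cohort import CohortConfig, generate_cohort
from mirdecoy.duplex import load_default_parameters
from mirdecoy.sponge import MatureMiRNA


@pytest.fixture(scope="session")
def mir155() -> MatureMiRNA:
    return MatureMiRNA("mmu-miR-155", constructs.MIR155_MATURE)


@pytest.fixture(scope="session")
def mir802() -> MatureMiRNA:
    return MatureMiRNA("mmu-miR-802", constructs.MIR802_MATURE)


@pytest.fixture(scope="session")
def params():
    return load_default_parameters()


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared across read-only tests."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture
def small_cohort_config():
    """A scaled-down cohort for fast pipeline smoke tests."""
    return CohortConfig(
        n_genes=400,
        n_trisomic_genes=40,
        n_targets_per_mirna=40,
        n_decoy_predictions=60,
        seed=3,
    )


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=length)])
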