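import numpy as np
import pytest

from anole_admix.coalsim import DemographicModel, simulate_dataset
from anole_admix.io import PopulationMap
from anole_admix.synthetic_data import FixtureSpec, make_toy_tables


@pytest.fixture(scope="session")
def toys():
    return make_toy_tables()


@pytest.fixture(scope="session")
def study_samples():
    return PopulationMap(["SFL", "MIA", "WCU"],
                         {"SFL": 32, "MIA": 92, "WCU": 54})


@pytest.fixture(scope="session")
def study_model():
    # published posterior medians of the demographic scenario
    return DemographicModel(n_sfl=4980, n_mia=4410, n_wcu=8570,
                            t_admix=887, r_admix=0.24, t_split=1.03e7)


@pytest.fixture(scope="session")
def study_dataset(study_model, study_samples):
    """One study-shaped simulated dataset, shared across tests."""
    return simulate_dataset(study_model, study_samples, 18, 42)


@pytest.fixture(scope="session")
def study_fixture_dir(tmp_path_factory):
    from anole_admix.synthetic_data import make_study_like_dataset
    out = tmp_path_factory.mktemp("study")
    truth = make_study_like_dataset(FixtureSpec(seed=5), out)
    return out, truth


def random_table(seed: int, n_per_pop=(5, 6, 4), n_loci=4, missing_rate=0.1):
    """A random valid GenotypeTable for round-trip/property tests."""
    from anole_admix.io import GenotypeTable
    rng = np.random.default_rng(seed)
    pops = []
    for k, n in enumerate(n_per_pop):
        pops += [f"P{k + 1}"] * n
    n_ind = len(pops)
    alleles = rng.integers(80, 140, (n_ind, n_loci, 2)).astype(np.int32)
    miss = rng.random((n_ind, n_loci)) < missing_rate
    alleles[miss] = 0
    return GenotypeTable([f"ind{i:02d}" for i in range(n_ind)], pops,
                         [f"L{j}" for j in range(n_loci)], alleles)
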