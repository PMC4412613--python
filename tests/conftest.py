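import numpy as np
import pytest

from vactrace.solutions import IonSpecies, SolutionSpec, btp_acid_solution


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def nitrate_gradient():
    """Tenfold NO3- gradient: vacuolar 200 mM vs cytoplasmic 20 mM HNO3."""
    vac = btp_acid_solution("NO3", acid_mM=200, btp_mM=101, pH=5.0)
    cyt = btp_acid_solution("NO3", acid_mM=20, btp_mM=16, pH=7.0)
    return cyt, vac


@pytest.fixture
def selectivity_pair():
    """Vacuolar 200 mM HCl vs cytoplasmic 200 mM HNO3 (both + 2 CaCl2/2 MgCl2)."""
    vac = btp_acid_solution("Cl", acid_mM=200, btp_mM=82, pH=5.0)
    cyt = btp_acid_solution("NO3", acid_mM=200, btp_mM=160, pH=7.0)
    return cyt, vac


def random_anion_pair(rng):
    """Random NO3/Cl solution pair for property tests."""
    def one(label):
        return SolutionSpec(
            species=(
                IonSpecies("NO3", -1, float(rng.uniform(5, 300))),
                IonSpecies("Cl", -1, float(rng.uniform(5, 300))),
                IonSpecies("BTP", +1, float(rng.uniform(10, 200))),
                IonSpecies("Ca", +2, float(rng.uniform(0, 5))),
            ),
            pH=float(rng.uniform(5, 8)),
            label=label,
        )
    return one("cyt"), one("vac")
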