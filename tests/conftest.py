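import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from glycoevo.kinetics import Genotype, KineticParameters, MetaboliteState
from glycoevo.physiology import (
    REFERENCE_GENOTYPE,
    CostModel,
    PhysiologyParameters,
    normalize_cost,
)


@pytest.fixture(scope="session")
def kin():
    return KineticParameters()


@pytest.fixture(scope="session")
def phys():
    return PhysiologyParameters()


@pytest.fixture(scope="session")
def cost():
    return normalize_cost(CostModel(), REFERENCE_GENOTYPE)


@pytest.fixture(scope="session")
def reference():
    return REFERENCE_GENOTYPE


@pytest.fixture(scope="session")
def table2():
    return {
        "BC": Genotype(9.90956, 6.97388, 6.14105, 1.27357),
        "IC": Genotype(10.92211, 5.65143, 4.82003, 2.07099),
    }


@pytest.fixture(scope="session")
def balanced_fixed_point():
    """Balanced steady state of the reference genotype at 2 mM glucose with
    self-consistent growth dilution (frozen from an independent scipy
    root-find on the rate equations)."""
    return MetaboliteState(FBP=3.66451847, ATP=1.25861824, Pi=9.54119687)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
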