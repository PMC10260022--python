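import numpy as np
import pytest

from tifmkit import synthetic_data as sd
from tifmkit import tracing


@pytest.fixture(scope="session")
def abundances() -> tracing.AbundanceTable:
    return tracing.load_abundance_table()


@pytest.fixture(scope="session")
def asa_formula() -> tracing.ElementalFormula:
    """Argininosuccinate carbon skeleton with a 5-carbon tracer window."""
    return tracing.ElementalFormula.parse("C10H18N4O6", "C", 5)


@pytest.fixture()
def ground_truth() -> sd.GroundTruth:
    return sd.default_ground_truth(seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
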