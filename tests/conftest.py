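import numpy as np
import pytest

from ciliovet.genetic_codes import build_code
from ciliovet.model import AA_ALPHABET


@pytest.fixture(scope="session")
def codes():
    return {
        "standard": build_code("standard"),
        "table6": build_code("table6"),
        "mesodinium": build_code("mesodinium"),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_aa(rng, n):
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, n))


def random_nt(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic dataset reused across tests (30 genes)."""
    from ciliovet.simulate import SimulationConfig, generate_dataset

    return generate_dataset(SimulationConfig(n_genes=30, seed=42))
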