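import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "mitocomp",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("mitocomp")


@pytest.fixture(scope="session")
def opama_table():
    from mitocomp.fixtures import load_opama_gene_table

    return load_opama_gene_table()


@pytest.fixture(scope="session")
def opama_geometry(opama_table):
    from mitocomp.geometry import summarize_geometry

    return summarize_geometry(opama_table)


@pytest.fixture(scope="session")
def sim_genome():
    """One deterministic synthetic genome with its annotation."""
    from mitocomp.synthetic_data import simulate_genome

    return simulate_genome(seed=42)


def random_dna(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), n))
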