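import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pistasurvey.diversity import MISSING, NULL, GenotypeTable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_table() -> GenotypeTable:
    """Two species x three loci; L3 is null in species B, L2 has a missing call."""
    individuals = ["a1", "a2", "b1", "b2"]
    species = ["A", "A", "B", "B"]
    loci = ["L1", "L2", "L3"]
    a1 = np.array([
        [100, 200, 300],
        [100, 202, 302],
        [102, 200, NULL],
        [104, MISSING, NULL],
    ])
    a2 = np.array([
        [100, 202, 300],
        [120, 202, 300],
        [102, 204, NULL],
        [104, MISSING, NULL],
    ])
    return GenotypeTable(individuals, species, loci, a1, a2)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join("ACGT"[i] for i in rng.choice(4, size=length, p=p))
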