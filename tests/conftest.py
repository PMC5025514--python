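import numpy as np
import pytest

from polyarray import ReferenceGenome, SimConfig, simulate_allotetraploid

BASES = np.array(list("ACGT"))


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def small_reference() -> ReferenceGenome:
    """Deterministic two-subgenome reference, 20 kb per chromosome."""
    cfg = SimConfig(seed=42, n_chromosomes=1, chromosome_length=20_000, divergence=0.05)
    ref, _ = simulate_allotetraploid(cfg)
    return ref


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
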