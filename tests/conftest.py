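import numpy as np
import pytest

from numtforge.synthetic_data import MitogenomeConfig, simulate_mitogenome

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def mutate(rng, seq: str, rate: float) -> str:
    """Substitution-only divergence at per-site probability ``rate``."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for p in np.nonzero(rng.random(len(arr)) < rate)[0]:
        arr[p] = rng.choice(BASES[BASES != arr[p]])
    return arr.tobytes().decode()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_mito():
    """A compact annotated mitogenome shared across discovery tests."""
    config = MitogenomeConfig(
        total_length=8000,
        gene_lengths=(("ND1", 957), ("ND3", 348), ("CYTB", 1140)),
        leading_rrna=800,
    )
    record, annotations = simulate_mitogenome(config, seed=11)
    return record, annotations


@pytest.fixture(scope="session")
def full_mito():
    return simulate_mitogenome(seed=3)
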