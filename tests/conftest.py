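import numpy as np
import pytest

from clippair import ReferenceStore, SimCnv
from clippair.simulate import engineer_homology, generate_reference, make_header


@pytest.fixture(scope="session")
def small_ref() -> ReferenceStore:
    """A 2 kb deterministic random reference used across unit tests."""
    return generate_reference(2000, seed=42)


@pytest.fixture
def header_factory():
    return make_header


@pytest.fixture
def del_with_homology():
    """Reference + engineered 3-base-homology deletion (a=600, b=1100)."""
    cnv = SimCnv("sim1", 600, 1100, "DEL", homology_len=3)
    store = engineer_homology(generate_reference(2000, seed=7), cnv)
    return store, cnv


def random_dna(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
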