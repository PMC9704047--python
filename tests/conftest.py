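import numpy as np
import pytest

from editdev import synth
from editdev.config import FilterConfig


@pytest.fixture(scope="session")
def cfg() -> FilterConfig:
    return FilterConfig()


@pytest.fixture(scope="session")
def small_reference():
    """One shared synthetic reference (60 kb, 6 genes, 20 Alu copies)."""
    return synth.simulate_reference(length=60_000, n_repeats=20, n_genes=6, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    return synth.simulate_cohort(n_prenatal=12, n_postnatal=10, seed=11)


def make_qual(n: int, phred: int = 37) -> np.ndarray:
    return np.full(n, phred, dtype=np.int16)
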