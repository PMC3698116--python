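import numpy as np
import pytest

from biocode.synthetic import SyntheticGeneSpec, generate_synthetic_cds


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_cds():
    """A ~120-codon synthetic gene with stops allowed (fixed seed)."""
    return generate_synthetic_cds(
        SyntheticGeneSpec(n_codons=120, include_stops=True, seed=7)
    )


def random_bits(rng, n):
    return rng.integers(0, 2, size=n, dtype=np.uint8)
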