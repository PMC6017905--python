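import numpy as np
import pytest

from tripmove import build_chain_from_internal
from tripmove.fixtures import build_polypeptide_fixture


@pytest.fixture(scope="session")
def helix14():
    """Alpha-helical 14-alanine, the autocorrelation benchmark system."""
    return build_polypeptide_fixture("A" * 14, "helix")


@pytest.fixture()
def coil30():
    """A 30-residue polyalanine in a reproducible irregular conformation."""
    rng = np.random.default_rng(2024)
    n = 30
    phi = rng.uniform(-2.8, -0.7, n)
    psi = rng.uniform(-1.0, 2.9, n)
    return build_chain_from_internal("A" * n, phi, psi)


@pytest.fixture()
def mixed_chain():
    """Short chain with rotatable side chains of several lengths."""
    seq = ["LEU", "ALA", "LYS", "SER", "VAL", "GLY", "PHE", "ALA"]
    rng = np.random.default_rng(7)
    n = len(seq)
    return build_chain_from_internal(seq, rng.uniform(-2.5, -0.8, n), rng.uniform(-0.5, 2.5, n))
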