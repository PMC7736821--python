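import numpy as np
import pytest

from nmquant import fixtures
from nmquant.refmodel import GM18, NM32, NmSite, RnaRef
from nmquant.simulate import SimParams


@pytest.fixture(scope="session")
def builtin_refs():
    return fixtures.builtin_refs()


@pytest.fixture(scope="session")
def builtin_sites():
    return fixtures.builtin_sites()


@pytest.fixture
def small_ref():
    """A 60-nt reference with a G planted at position 30 (fast unit tests)."""
    rng = np.random.default_rng(7)
    seq = list("ACGU"[i] for i in rng.integers(0, 4, size=60))
    seq[29] = "G"
    return RnaRef(ref_id="tRNA-test", sequence="".join(seq), abundance=1.0)


@pytest.fixture
def small_site(small_ref):
    return NmSite(
        ref_id=small_ref.ref_id,
        position=30,
        pos_label="18",
        base="G",
        mod_name="Gm18",
        site_class=GM18,
    )


@pytest.fixture
def fast_params():
    """Reduced depth for unit tests; defaults otherwise."""
    return SimParams(n_molecules=20_000, seed=11)
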