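import pytest

import pbletools as pt


@pytest.fixture(scope="session")
def small_genome():
    """Two-contig background genome with a few planted TTAA sites."""
    genome, truth = pt.make_genome(
        {"chr1": 20000, "chr2": 20000}, gc_fraction=0.41, seed=42
    )
    return genome


@pytest.fixture(scope="session")
def donor():
    return pt.make_donor("ifp2_like", cassette_len=1000, seed=1)


@pytest.fixture(scope="session")
def mer75_donor():
    return pt.make_donor("mer75_like", cassette_len=1000, seed=2)
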