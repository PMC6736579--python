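import numpy as np
import pytest

from ampmag import fixtures
from ampmag.io_formats import SeqRecord


@pytest.fixture(scope="session")
def default_spec():
    return fixtures.FixtureSpec(seed=11)


@pytest.fixture(scope="session")
def count_fixture(default_spec):
    """Full-size planted count table (200 OTUs, 4 specimens, 2 blanks, 5e4)."""
    return fixtures.make_count_table(default_spec)


@pytest.fixture(scope="session")
def mag_fixture(default_spec):
    """23-MAG set with 12 linked, 8 unlinked, 3 lacking a 16S gene."""
    return fixtures.make_mag_set(default_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_record(rng, length, rec_id="seq"):
    return SeqRecord(id=rec_id, seq=fixtures.random_seq(rng, length))
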