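import pytest

from altej import JunctionRead, pwa_construct
from altej.io import FIXTURE_IDS, load_fixture


@pytest.fixture(scope="session")
def construct():
    return pwa_construct()


@pytest.fixture(scope="session")
def all_fixture_rows():
    rows = []
    for table_id in FIXTURE_IDS:
        rows.extend(load_fixture(table_id))
    return rows


def make_read(sequence, read_id="r", genotype="", multiplicity=1):
    return JunctionRead(
        read_id=read_id,
        sequence=sequence,
        genotype=genotype,
        multiplicity=multiplicity,
    )
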