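import numpy as np
import pytest

from lsgf.codes import get_code
from lsgf.orf import OrfRecord


@pytest.fixture(scope="session")
def standard_code():
    return get_code(1)


@pytest.fixture(scope="session")
def ciliate_code():
    return get_code(6)


@pytest.fixture(scope="session")
def euplotes_code():
    return get_code(10)


def make_orf(record_id, cds, taxon="t1", code_id=6):
    code = get_code(code_id)
    return OrfRecord(
        record_id=record_id,
        taxon=taxon,
        nucleotide=cds,
        protein=code.translate(cds),
        frame=1,
        source_id=record_id,
        start=0,
        end=len(cds),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240125)
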