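import numpy as np
import pytest

from msdin import dedup_genes, load_packaged_fixtures
from msdin.mining import build_pssms


@pytest.fixture(scope="session")
def fixtures():
    return load_packaged_fixtures()


@pytest.fixture(scope="session")
def nonrepetitive(fixtures):
    return dedup_genes(fixtures)


@pytest.fixture(scope="session")
def amanita(nonrepetitive):
    return [r for r in nonrepetitive if r.genus == "Amanita"]


@pytest.fixture(scope="session")
def pssms(nonrepetitive):
    return build_pssms(nonrepetitive)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240601)
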