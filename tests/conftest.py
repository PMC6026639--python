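import pytest
from hypothesis import settings

import iappdesign as iap

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def peptides() -> dict[str, iap.PeptideSequence]:
    return iap.builtin_sequences()


@pytest.fixture(scope="session")
def hiapp(peptides) -> iap.PeptideSequence:
    return peptides["hIAPP"]


@pytest.fixture(scope="session")
def scale() -> iap.PropensityScale:
    return iap.PropensityScale()


@pytest.fixture(scope="session")
def species_catalog() -> iap.VariantCatalog:
    return iap.load_species_table()


@pytest.fixture(scope="session")
def single_scan_table(hiapp, species_catalog) -> iap.ScanTable:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return iap.single_scan(hiapp, species_catalog)
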