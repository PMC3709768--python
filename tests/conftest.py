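from pathlib import Path

import pytest

from yakldh import GeneratorConfig, make_m_subunit, make_reference_cds
from yakldh.synthetic_data import canonical_subunit_profiles, make_genomic_template

REPO_ROOT = Path(__file__).resolve().parent.parent


@pytest.fixture(scope="session")
def config():
    return GeneratorConfig(seed=42)


@pytest.fixture(scope="session")
def reference(config):
    return make_reference_cds(config)


@pytest.fixture(scope="session")
def canonical_profiles(reference, config):
    """Hf/Hm/Hs subunit profiles of the canonical single-substitution alleles."""
    return canonical_subunit_profiles(reference, config)


@pytest.fixture(scope="session")
def m_subunit(config):
    return make_m_subunit(config)


@pytest.fixture(scope="session")
def templates(config):
    """(A-allele, G-allele) genomic templates of the diagnostic assay."""
    return make_genomic_template(config, "A"), make_genomic_template(config, "G")
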