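import pytest

from acrskit.synth import (
    FIXTURE_PRIMERS,
    FIXTURE_SNPS,
    build_reference_template,
    default_template_spec,
    reference_assays,
)


@pytest.fixture(scope="session")
def template():
    """The synthetic fixture template (seed 17, 1000 bp)."""
    return build_reference_template(default_template_spec(seed=17))


@pytest.fixture(scope="session")
def assays(template):
    """The three shipped assays instantiated on the fixture template."""
    return reference_assays(template)


@pytest.fixture(scope="session")
def assays_by_snp(assays):
    return {d.snp.id: d for d in assays}


@pytest.fixture(scope="session")
def primers():
    return FIXTURE_PRIMERS


@pytest.fixture(scope="session")
def snps():
    return {s.id: s for s in FIXTURE_SNPS}
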