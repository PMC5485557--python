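import pytest
from hypothesis import settings

from hv1hap.classifier import load_motifs
from hv1hap.fixtures import FixtureSpec, make_reference, make_registry
from hv1hap.mutation_model import ReferenceWindow
from hv1hap.registry import deduplicate, load_registry

settings.register_profile("suite", derandomize=True, max_examples=200)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def motifs():
    return load_motifs()


@pytest.fixture(scope="session")
def published_registry():
    """The packaged registry of in-print definitions, reconciled."""
    return deduplicate(load_registry())


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=2024)


@pytest.fixture(scope="session")
def synthetic_ref(fixture_spec, motifs):
    return make_reference(fixture_spec, motifs)


@pytest.fixture(scope="session")
def synthetic_registry(fixture_spec, synthetic_ref, motifs):
    return make_registry(fixture_spec, synthetic_ref, motifs)
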