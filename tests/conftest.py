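import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study: 200 genes, 16 tissues, seed 42."""
    from txome454.synthetic import GenConfig, generate_study

    return generate_study(GenConfig())


@pytest.fixture(scope="session")
def default_annotations(default_bundle):
    from txome454.annotation import annotate

    return annotate(default_bundle.hits)
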