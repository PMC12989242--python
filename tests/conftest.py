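import pytest

from psdoc.synth import GeneratorConfig, generate_cohort, generate_documents


@pytest.fixture(scope="session")
def small_world():
    """A 50-patient generated world shared across read-only tests."""
    cfg = GeneratorConfig(n_patients=50, seed=42)
    patients, events = generate_cohort(cfg)
    documents = generate_documents(patients, events, cfg)
    return cfg, patients, events, documents


@pytest.fixture(scope="session")
def medium_corpus():
    """A larger annotated corpus for extractor performance checks."""
    cfg = GeneratorConfig(n_patients=400, seed=202)
    patients, events = generate_cohort(cfg)
    documents = generate_documents(patients, events, cfg)
    return documents
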