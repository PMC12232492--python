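import pytest

from pdcmner.bio_codec import BioLabelScheme
from pdcmner.registry import DEFAULT_TYPE_NAMES
from pdcmner.synthetic import GeneratorConfig, generate_corpus, make_backbone_fixture

# The sentence used throughout as a worked offset example: "ALK" occupies
# characters [48, 51).
ALK_SENTENCE = (
    "Oncogenic fusion of anaplastic lymphoma kinase (ALK) with echinoderm "
    "microtubule associated protein like 4 protein or other partner genes "
    "occurs in lung adenocarcinomas."
)


@pytest.fixture(scope="session")
def scheme() -> BioLabelScheme:
    return BioLabelScheme(DEFAULT_TYPE_NAMES)


@pytest.fixture(scope="session")
def small_corpus():
    """20 synthetic abstracts with gold annotations and the planted ledger."""
    return generate_corpus(GeneratorConfig(n_documents=20, seed=3))


@pytest.fixture(scope="session")
def tiny_backbone():
    return make_backbone_fixture(seed=0)
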