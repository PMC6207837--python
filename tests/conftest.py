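import random

import pytest

from nssresolve import (
    GeneratorConfig,
    NssLexicon,
    generate,
    worked_examples,
)


@pytest.fixture(scope="session")
def worked():
    """The two walk-through statements with their licensing ontology."""
    statements, ontology, lexicon = worked_examples()
    return statements, ontology, lexicon


@pytest.fixture(scope="session")
def default_lexicon():
    return NssLexicon.default()


@pytest.fixture(scope="session")
def small_corpus():
    """A 60-statement mixed-signal corpus with its ontology."""
    statements, ontology, provenance = generate(GeneratorConfig(n_statements=60, seed=7))
    return statements, ontology, provenance


@pytest.fixture()
def rng():
    return random.Random(1234)
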