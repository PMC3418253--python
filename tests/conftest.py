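"""Shared fixtures: generated corpora and planted proproteins."""

import pytest

from pepscreen import ScreenConfig
from pepscreen.synthetic import PlantSpec, generate_corpus, generate_proprotein


@pytest.fixture(scope="session")
def planted():
    """One planted proprotein (with TM) and its layout, seed 17."""
    return generate_proprotein(PlantSpec(seed=17))


@pytest.fixture(scope="session")
def corpus_truth():
    """Three-species corpus: 1 planted family + one decoy per kind."""
    return generate_corpus(seed=1)


@pytest.fixture(scope="session")
def corpus(corpus_truth):
    return corpus_truth[0]


@pytest.fixture()
def config():
    return ScreenConfig()
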