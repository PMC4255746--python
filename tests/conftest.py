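import random

import pytest

from litmine.fixtures import FixtureSpec, build_corpus
from litmine.terminology import Lexicon, LexiconEntry


@pytest.fixture(scope="session")
def small_bundle():
    """A 10-document synthetic corpus with all ambiguity classes planted."""
    return build_corpus(FixtureSpec(seed=7, n_docs=10))


@pytest.fixture(scope="session")
def standard_bundle():
    """The standard fixture conditions: seed 42, 50 documents, density 0.1."""
    return build_corpus(FixtureSpec())


@pytest.fixture
def rng():
    return random.Random(12345)


@pytest.fixture
def tiny_lexicon():
    return Lexicon([
        LexiconEntry("Tim18p", "P1", "protein", "TIM18", "PROTDB", "taxon:4932"),
        LexiconEntry("Tim12p", "P2", "protein", "TIM12", "PROTDB", "taxon:4932"),
        LexiconEntry("aspirin", "C1", "chemical", "aspirin", "CHEMDB"),
        LexiconEntry("headache", "D1", "disease", "headache", "DISDB"),
        LexiconEntry("folD", "G1", "gene", "folD", "GENEDB", "taxon:511145"),
        LexiconEntry("SEX", "C2", "chemical", "sodium ethyl xanthate", "CHEMDB"),
        LexiconEntry("IL-2", "P3", "protein", "interleukin-2", "PROTDB", "taxon:9606"),
        LexiconEntry("alpha-synuclein", "P4", "protein", "SNCA", "PROTDB", "taxon:9606"),
        LexiconEntry("GFP", "P5", "protein", "green fluorescent protein", "PROTDB"),
        LexiconEntry("GFP", "M1", "experimental_method", "GFP imaging", "METHDB"),
    ])


def make_passage(text, offset=0, sentences=None):
    """Helper: a passage with either plain text or pre-segmented sentences."""
    from litmine.bioc import BioCPassage, BioCSentence

    p = BioCPassage(offset=offset, infons={"type": "abstract"})
    if sentences is None:
        p.text = text
    else:
        pos = offset
        for i, s in enumerate(sentences):
            p.sentences.append(BioCSentence(offset=pos, text=s, index=i))
            pos += len(s) + 1
    return p
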