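"""Shared fixtures: hand-built documents and generated corpora."""

import pytest

from bibliome_events.simulate import GeneratorConfig, generate
from bibliome_events.standoff import (
    Document,
    EntityAnnotation,
    EventAnnotation,
    EventArgument,
    TextSpan,
)


def entity(eid, etype, start, text, doc_text):
    assert doc_text[start : start + len(text)] == text
    return EntityAnnotation(eid, etype, TextSpan(start, start + len(text), text))


def span_of(word, doc_text, occurrence=0):
    pos = -1
    for _ in range(occurrence + 1):
        pos = doc_text.index(word, pos + 1)
    return TextSpan(pos, pos + len(word), word)


@pytest.fixture
def regulation_doc():
    """One sentence: 'SgA0 activates the transcription of SgB0.'"""
    text = "SgA0 activates the transcription of SgB0.\n"
    a = entity("T1", "Gene", 0, "SgA0", text)
    b = entity("T2", "Protein", 37, "SgB0", text)
    inner = EventAnnotation(
        "E1", "Transcription", span_of("transcription", text),
        (EventArgument("Theme", b),), confidence=0.8,
    )
    outer = EventAnnotation(
        "E2", "Positive_regulation", span_of("activates", text),
        (EventArgument("Theme", inner), EventArgument("Cause", a)), confidence=0.9,
    )
    doc = Document("1001", text, [a, b], [inner, outer],
                   [TextSpan(0, len(text) - 1, text[:-1])])
    doc.validate()
    return doc


@pytest.fixture(scope="session")
def zero_noise_corpus():
    """Small deterministic corpus with exact planted-network recovery."""
    config = GeneratorConfig.zero_noise(
        seed=7, n_genes=12, n_edges=20, n_docs=10,
        mentions_per_edge=3, sentences_per_doc=10,
    )
    return generate(config)


@pytest.fixture(scope="session")
def noisy_corpus():
    """Small corpus with false positives, variants and unmatched symbols."""
    config = GeneratorConfig(
        seed=7, n_genes=12, n_edges=20, n_docs=12,
        mentions_per_edge=3, sentences_per_doc=14,
    )
    return generate(config)
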