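import pytest
from hypothesis import HealthCheck, settings

import genestatus as gs

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def top8_corpus():
    """Clean (noise-free) corpus with the skewed top-eight category mix."""
    spec = gs.make_preset_spec("top8_skewed", seed=7)
    return spec, gs.generate_corpus(spec)


@pytest.fixture(scope="session")
def top8_featurized(top8_corpus):
    _, corpus = top8_corpus
    return gs.featurize_instances(corpus.documents, corpus.instances)


@pytest.fixture(scope="session")
def balanced_corpus():
    spec = gs.make_preset_spec("balanced", seed=11)
    return spec, gs.generate_corpus(spec)


def make_doc(text, section="eligibility", trial_id="T1"):
    return gs.TrialDocument(trial_id=trial_id, status="active",
                            sections=[(section, text)])


def make_mention(doc, surface, section="eligibility", gene=None):
    """Locate ``surface`` in a document section and build a GeneMention."""
    text = doc.section_text(section)
    start = text.index(surface)
    sentences = gs.tokenize_and_split(text)
    for si, sent in enumerate(sentences):
        for ti, tok in enumerate(sent.tokens):
            if tok.span[0] == start:
                n = sum(1 for t in sent.tokens
                        if start <= t.span[0] and t.span[1] <= start + len(surface))
                return gs.GeneMention(
                    trial_id=doc.trial_id, gene_symbol=gene or surface.upper(),
                    matched_text=surface, section_name=section,
                    char_span=(start, start + len(surface)),
                    sentence_index=si, token_index=ti, n_tokens=n,
                )
    raise AssertionError(f"{surface!r} does not start at a token boundary")
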