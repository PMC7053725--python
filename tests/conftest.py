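import pytest

from cpirex.corpus import (
    CandidatePair,
    Corpus,
    Document,
    Entity,
    EntityType,
    PairLabel,
    Sentence,
)
from cpirex.evaluation import prepare_corpus
from cpirex.preprocess import blind_entities, default_interaction_verbs, parse_sentence
from cpirex.synthetic import SyntheticConfig, generate_corpus


@pytest.fixture(scope="session")
def verbs():
    return default_interaction_verbs()


def make_sentence(text, annotations, sent_id="d0.s0", label=PairLabel.UNKNOWN):
    """Build a sentence by locating each (surface, type) left to right.

    If the sentence ends up with exactly one compound and one protein, a
    single candidate pair with the given label is attached.
    """
    sent = Sentence(sent_id=sent_id, text=text)
    cursor = {}
    for i, (surface, etype) in enumerate(annotations):
        start = text.index(surface, cursor.get(surface, 0))
        cursor[surface] = start + 1
        sent.entities.append(
            Entity(
                ent_id=f"{sent_id}.e{i}",
                ent_type=EntityType(etype),
                char_start=start,
                char_end=start + len(surface),
                surface=surface,
            )
        )
    compounds = sent.compounds()
    proteins = sent.proteins()
    if len(compounds) == 1 and len(proteins) == 1:
        sent.pairs.append(
            CandidatePair(
                pair_id=f"{sent_id}.p0",
                compound_ref=compounds[0].ent_id,
                protein_ref=proteins[0].ent_id,
                label=label,
            )
        )
    return sent


def make_instance(text, annotations, blind_others=True, label=PairLabel.UNKNOWN):
    """Parse and blind a one-pair sentence into a kernel-ready instance."""
    sent = make_sentence(text, annotations, label=label)
    parsed = parse_sentence(sent)
    return blind_entities(parsed, sent.pairs[0], blind_others=blind_others)


def wrap_corpus(*sentences):
    docs = [Document(doc_id=f"doc{i}", sentences=[s]) for i, s in enumerate(sentences)]
    corpus = Corpus(documents=docs)
    corpus.validate()
    return corpus


@pytest.fixture(scope="session")
def synthetic_instances():
    """Eight deterministic kernel instances from the synthetic generator."""
    cfg = SyntheticConfig(n_docs=8, sentences_per_doc=1, seed=42)
    corpus = generate_corpus(cfg)
    return [p.instance for p in prepare_corpus(corpus)]
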