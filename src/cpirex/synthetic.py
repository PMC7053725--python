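"""Seeded synthetic benchmark corpora.

The generator emulates the statistical skeleton of the curated benchmark:
documents of sentences that each contain at least one compound and one
protein mention, binary functional/non-functional pair labels with a
controllable positive rate, and a controllable class-conditional probability
that an interaction verb sits between the pair (the label-verb dependence
the benchmark exhibits). Positives additionally receive a lexical marker
token ("assoc") adjacent to the verb slot with configurable probability,
planting a surface signal that both kernels can learn through the fixture
chain parse.

Defaults mirror the benchmark's marginals: positive rate 0.527 and
verb-given-label rates 0.545 / 0.482 (derived from the published pair and
verb-stratum counts). Everything is driven by one ``random.Random(seed)``,
so a given configuration is byte-reproducible.

It emits ordinary :class:`~cpirex.corpus.Corpus` objects (and hence the
unified XML dialect), so the full pipeline runs on synthetic files exactly
as on real data. It makes no attempt at realistic biomedical language.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .corpus import (
    Corpus,
    Document,
    Entity,
    EntityType,
    PairLabel,
    Sentence,
    generate_candidate_pairs,
)
from .preprocess import ParsedSentence, default_interaction_verbs, parse_sentence

# Verb surfaces are third-person forms so the suffix-stripping lemma fallback
# is exercised; neutral mid tokens are function words, never verbs.
_NEUTRAL_MID = ("with", "without", "near", "versus", "plus", "and")
_MARKER = "assoc"


@dataclass(frozen=True)
class SyntheticConfig:
    n_docs: int = 200
    sentences_per_doc: int = 2
    p_positive: float = 0.527
    p_verb_given_pos: float = 0.545
    p_verb_given_neg: float = 0.482
    p_marker_given_pos: float = 0.8
    p_marker_given_neg: float = 0.0
    vocab_size: int = 100
    filler_min: int = 2
    filler_max: int = 5
    multi_pair: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.p_positive, self.p_verb_given_pos, self.p_verb_given_neg,
            self.p_marker_given_pos, self.p_marker_given_neg,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_docs < 1 or self.sentences_per_doc < 1:
            raise ValueError("n_docs and sentences_per_doc must be >= 1")
        if not (0 <= self.filler_min <= self.filler_max):
            raise ValueError("invalid filler length range")


def _verb_surfaces() -> list[str]:
    return sorted(lemma + "s" for lemma in default_interaction_verbs())


def generate_corpus(cfg: SyntheticConfig) -> Corpus:
    """Deterministically generate an annotated corpus from a config.

    Sentence layout: ``filler* COMPOUND mid [marker] PROTEIN filler* .`` with
    ``mid`` an interaction verb with the class-conditional probability and a
    neutral function word otherwise. In ``multi_pair`` mode each sentence has
    two compounds and two proteins (four candidate pairs sharing the
    sentence's label) to exercise enumeration and non-candidate blinding.
    """
    rng = random.Random(cfg.seed)
    verbs = _verb_surfaces()
    corpus = Corpus(source=f"synthetic-seed{cfg.seed}")

    for di in range(cfg.n_docs):
        doc = Document(doc_id=f"d{di:05d}")
        for si in range(cfg.sentences_per_doc):
            sent_id = f"{doc.doc_id}.s{si}"
            positive = rng.random() < cfg.p_positive
            p_verb = cfg.p_verb_given_pos if positive else cfg.p_verb_given_neg
            p_marker = cfg.p_marker_given_pos if positive else cfg.p_marker_given_neg
            mid = rng.choice(verbs) if rng.random() < p_verb else rng.choice(
                _NEUTRAL_MID
            )
            marker = rng.random() < p_marker

            def fillers() -> list[str]:
                return [
                    f"w{rng.randrange(cfg.vocab_size)}"
                    for _ in range(rng.randint(cfg.filler_min, cfg.filler_max))
                ]

            n_comp = 2 if cfg.multi_pair else 1
            n_prot = 2 if cfg.multi_pair else 1
            compounds = [f"CPD{rng.randrange(50)}" for _ in range(n_comp)]
            proteins = [f"PRT{rng.randrange(50)}" for _ in range(n_prot)]

            words: list[str] = fillers()
            entity_slots: list[tuple[int, str, EntityType]] = []
            for surf in compounds:
                entity_slots.append((len(words), surf, EntityType.COMPOUND))
                words.append(surf)
            words.append(mid)
            if marker:
                words.append(_MARKER)
            for surf in proteins:
                entity_slots.append((len(words), surf, EntityType.PROTEIN))
                words.append(surf)
            words += fillers()
            words.append(".")

            # The final "." attaches without a preceding space.
            text = " ".join(words[:-1]) + "."
            offsets = []
            pos = 0
            for w in words[:-1]:
                offsets.append(pos)
                pos += len(w) + 1

            sent = Sentence(sent_id=sent_id, text=text)
            for slot, surf, etype in entity_slots:
                start = offsets[slot]
                sent.entities.append(
                    Entity(
                        ent_id=f"{sent_id}.e{len(sent.entities)}",
                        ent_type=etype,
                        char_start=start,
                        char_end=start + len(surf),
                        surface=surf,
                    )
                )
            label = PairLabel.FUNCTIONAL if positive else PairLabel.NON_FUNCTIONAL
            sent.pairs = generate_candidate_pairs(sent, label=label)
            doc.sentences.append(sent)
        corpus.documents.append(doc)

    corpus.validate()
    return corpus


def generate_parse_fixtures(
    corpus: Corpus, verbs: frozenset[str] | None = None
) -> dict[str, ParsedSentence]:
    """Attach deterministic chain parses to every sentence (keyed by sent_id).

    Chain parses connect the full sentence, so all-paths instances are
    well-defined without an external parser and the shortest path between a
    pair is exactly the inter-entity token segment.
    """
    return {
        sent.sent_id: parse_sentence(sent, verbs, backend="fixture")
        for _, sent in corpus.iter_sentences()
    }
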