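"""Annotated corpora of compound/protein entities and candidate pairs.

A corpus is a list of documents (typically abstracts keyed by PubMed ID),
each a list of sentences. Every sentence carries character-offset entity
annotations (compounds and proteins) and candidate compound-protein pairs,
the classification unit of the whole pipeline: each pair is labeled as
describing a functional relationship, not describing one, or unknown
(prediction-time corpora).

Two on-disk dialects are supported: a unified interaction-corpus XML format
(the common PPI-corpus convention: inclusive character offsets, one
``<pair>`` element per candidate) and the PubTator pipe/tab format used for
large-scale PubMed ingestion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional

from lxml import etree

logger = logging.getLogger(__name__)


class CorpusValidationError(ValueError):
    """An invariant of the corpus model is violated."""


class EntityType(str, Enum):
    COMPOUND = "compound"
    PROTEIN = "protein"


class PairLabel(str, Enum):
    FUNCTIONAL = "functional"
    NON_FUNCTIONAL = "non_functional"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Entity:
    """A compound or protein mention with a 0-based end-exclusive span."""

    ent_id: str
    ent_type: EntityType
    char_start: int
    char_end: int
    surface: str
    norm_id: Optional[str] = None


@dataclass(frozen=True)
class CandidatePair:
    """One compound x protein co-occurrence within a sentence."""

    pair_id: str
    compound_ref: str
    protein_ref: str
    label: PairLabel = PairLabel.UNKNOWN
    encloses_verb: Optional[bool] = None


@dataclass
class Sentence:
    sent_id: str
    text: str
    entities: list[Entity] = field(default_factory=list)
    pairs: list[CandidatePair] = field(default_factory=list)

    def entity_by_id(self, ent_id: str) -> Entity:
        for ent in self.entities:
            if ent.ent_id == ent_id:
                return ent
        raise KeyError(ent_id)

    def compounds(self) -> list[Entity]:
        return [e for e in self.entities if e.ent_type is EntityType.COMPOUND]

    def proteins(self) -> list[Entity]:
        return [e for e in self.entities if e.ent_type is EntityType.PROTEIN]

    def validate(self) -> None:
        for ent in self.entities:
            if not (0 <= ent.char_start < ent.char_end <= len(self.text)):
                raise CorpusValidationError(
                    f"entity {ent.ent_id!r} span [{ent.char_start},{ent.char_end}) "
                    f"outside sentence {self.sent_id!r} of length {len(self.text)}"
                )
            if self.text[ent.char_start:ent.char_end] != ent.surface:
                raise CorpusValidationError(
                    f"entity {ent.ent_id!r} surface {ent.surface!r} does not match "
                    f"text slice in sentence {self.sent_id!r}"
                )
        by_id = {e.ent_id: e for e in self.entities}
        if len(by_id) != len(self.entities):
            raise CorpusValidationError(
                f"duplicate entity ids in sentence {self.sent_id!r}"
            )
        for pair in self.pairs:
            for ref, wanted in (
                (pair.compound_ref, EntityType.COMPOUND),
                (pair.protein_ref, EntityType.PROTEIN),
            ):
                ent = by_id.get(ref)
                if ent is None:
                    raise CorpusValidationError(
                        f"pair {pair.pair_id!r} references missing entity {ref!r} "
                        f"in sentence {self.sent_id!r}"
                    )
                if ent.ent_type is not wanted:
                    raise CorpusValidationError(
                        f"pair {pair.pair_id!r}: entity {ref!r} has type "
                        f"{ent.ent_type.value}, expected {wanted.value}"
                    )


@dataclass
class Document:
    doc_id: str
    sentences: list[Sentence] = field(default_factory=list)


@dataclass(frozen=True)
class CorpusCounts:
    sentences: int
    positive: int
    negative: int
    unknown: int

    @property
    def pairs(self) -> int:
        return self.positive + self.negative + self.unknown


@dataclass
class Corpus:
    documents: list[Document] = field(default_factory=list)
    source: str = "cpirex"

    @property
    def counts(self) -> CorpusCounts:
        n_sent = pos = neg = unk = 0
        for _, _, pair in self.iter_pairs():
            if pair.label is PairLabel.FUNCTIONAL:
                pos += 1
            elif pair.label is PairLabel.NON_FUNCTIONAL:
                neg += 1
            else:
                unk += 1
        n_sent = sum(len(doc.sentences) for doc in self.documents)
        return CorpusCounts(n_sent, pos, neg, unk)

    def iter_sentences(self) -> Iterator[tuple[Document, Sentence]]:
        for doc in self.documents:
            for sent in doc.sentences:
                yield doc, sent

    def iter_pairs(self) -> Iterator[tuple[Document, Sentence, CandidatePair]]:
        for doc, sent in self.iter_sentences():
            for pair in sent.pairs:
                yield doc, sent, pair

    def validate(self) -> None:
        seen_docs: set[str] = set()
        for doc in self.documents:
            if not doc.doc_id:
                raise CorpusValidationError("empty doc_id")
            if doc.doc_id in seen_docs:
                raise CorpusValidationError(f"duplicate doc_id {doc.doc_id!r}")
            seen_docs.add(doc.doc_id)
            seen_sents: set[str] = set()
            for sent in doc.sentences:
                if sent.sent_id in seen_sents:
                    raise CorpusValidationError(
                        f"duplicate sent_id {sent.sent_id!r} in {doc.doc_id!r}"
                    )
                seen_sents.add(sent.sent_id)
                sent.validate()


# ---------------------------------------------------------------------------
# Unified interaction-corpus XML
# ---------------------------------------------------------------------------

_LABEL_TO_XML = {PairLabel.FUNCTIONAL: "True", PairLabel.NON_FUNCTIONAL: "False"}
_XML_TO_LABEL = {"True": PairLabel.FUNCTIONAL, "False": PairLabel.NON_FUNCTIONAL}


def parse_unified_xml(xml_text: str | bytes) -> Corpus:
    """Parse the unified XML dialect into a validated :class:`Corpus`.

    ``charOffset`` attributes use the inclusive start-end convention of the
    published PPI corpora and are converted to 0-based end-exclusive spans.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise CorpusValidationError(f"malformed XML: {exc}") from exc
    if root.tag != "corpus":
        raise CorpusValidationError(f"expected <corpus> root, got <{root.tag}>")

    corpus = Corpus(source=root.get("source", "cpirex"))
    for doc_el in root.findall("document"):
        doc = Document(doc_id=doc_el.get("id", ""))
        for sent_el in doc_el.findall("sentence"):
            sent = Sentence(
                sent_id=sent_el.get("id", ""), text=sent_el.get("text", "")
            )
            for ent_el in sent_el.findall("entity"):
                offs = ent_el.get("charOffset", "")
                try:
                    start_s, end_s = offs.split("-")
                    start, end_incl = int(start_s), int(end_s)
                except ValueError as exc:
                    raise CorpusValidationError(
                        f"bad charOffset {offs!r} in sentence {sent.sent_id!r}"
                    ) from exc
                sent.entities.append(
                    Entity(
                        ent_id=ent_el.get("id", ""),
                        ent_type=EntityType(ent_el.get("type", "")),
                        char_start=start,
                        char_end=end_incl + 1,
                        surface=ent_el.get("text", ""),
                        norm_id=ent_el.get("normId"),
                    )
                )
            by_id = {e.ent_id: e for e in sent.entities}
            for pair_el in sent_el.findall("pair"):
                e1, e2 = pair_el.get("e1", ""), pair_el.get("e2", "")
                ent1, ent2 = by_id.get(e1), by_id.get(e2)
                if ent1 is None or ent2 is None:
                    missing = e1 if ent1 is None else e2
                    raise CorpusValidationError(
                        f"pair {pair_el.get('id')!r} references missing entity "
                        f"{missing!r} in sentence {sent.sent_id!r}"
                    )
                if ent1.ent_type is EntityType.COMPOUND:
                    comp, prot = ent1, ent2
                else:
                    comp, prot = ent2, ent1
                verb_attr = pair_el.get("enclosesVerb")
                sent.pairs.append(
                    CandidatePair(
                        pair_id=pair_el.get("id", ""),
                        compound_ref=comp.ent_id,
                        protein_ref=prot.ent_id,
                        label=_XML_TO_LABEL.get(
                            pair_el.get("interaction", ""), PairLabel.UNKNOWN
                        ),
                        encloses_verb=(
                            None if verb_attr is None else verb_attr == "True"
                        ),
                    )
                )
            doc.sentences.append(sent)
        corpus.documents.append(doc)
    corpus.validate()
    return corpus


def write_unified_xml(corpus: Corpus) -> str:
    """Serialize a corpus; ``parse_unified_xml`` round-trips it exactly."""
    root = etree.Element("corpus", source=corpus.source)
    for doc in corpus.documents:
        doc_el = etree.SubElement(root, "document", id=doc.doc_id)
        for sent in doc.sentences:
            sent_el = etree.SubElement(
                doc_el, "sentence", id=sent.sent_id, text=sent.text
            )
            for ent in sent.entities:
                attrs = {
                    "id": ent.ent_id,
                    "type": ent.ent_type.value,
                    "charOffset": f"{ent.char_start}-{ent.char_end - 1}",
                    "text": ent.surface,
                }
                if ent.norm_id is not None:
                    attrs["normId"] = ent.norm_id
                etree.SubElement(sent_el, "entity", **attrs)
            for pair in sent.pairs:
                attrs = {
                    "id": pair.pair_id,
                    "e1": pair.compound_ref,
                    "e2": pair.protein_ref,
                }
                if pair.label in _LABEL_TO_XML:
                    attrs["interaction"] = _LABEL_TO_XML[pair.label]
                if pair.encloses_verb is not None:
                    attrs["enclosesVerb"] = "True" if pair.encloses_verb else "False"
                etree.SubElement(sent_el, "pair", **attrs)
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="utf-8"
    ).decode("utf-8")


# ---------------------------------------------------------------------------
# Candidate-pair enumeration
# ---------------------------------------------------------------------------


def generate_candidate_pairs(
    sentence: Sentence, label: PairLabel = PairLabel.UNKNOWN
) -> list[CandidatePair]:
    """Enumerate all compound x protein co-occurrences of one sentence.

    Every compound entity is paired with every protein entity exactly once;
    a long-form mention and its abbreviation are distinct entities and hence
    distinct pair members. Order is deterministic: by compound start offset,
    then protein start offset.
    """
    compounds = sorted(sentence.compounds(), key=lambda e: (e.char_start, e.ent_id))
    proteins = sorted(sentence.proteins(), key=lambda e: (e.char_start, e.ent_id))
    pairs = []
    k = 0
    for comp in compounds:
        for prot in proteins:
            pairs.append(
                CandidatePair(
                    pair_id=f"{sentence.sent_id}.p{k}",
                    compound_ref=comp.ent_id,
                    protein_ref=prot.ent_id,
                    label=label,
                )
            )
            k += 1
    return pairs


# ---------------------------------------------------------------------------
# PubTator ingest
# ---------------------------------------------------------------------------

_PUBTATOR_TYPE_MAP = {
    "chemical": EntityType.COMPOUND,
    "gene": EntityType.PROTEIN,
    "protein": EntityType.PROTEIN,
}


def parse_pubtator(text: str) -> Corpus:
    """Read PubTator pipe/tab abstracts into a corpus of unknown-label pairs.

    Title and abstract are joined with a single space, sentence-split, and the
    document-relative annotation offsets remapped to sentence-relative spans.
    Only Chemical and Gene/Protein annotations are kept; annotations whose
    span crosses a sentence boundary or falls outside the text are dropped
    with a warning. Candidate pairs are sentence-bounded.
    """
    from .preprocess import split_sentences

    blocks: list[list[str]] = [[]]
    for line in text.splitlines():
        if line.strip():
            blocks[-1].append(line)
        elif blocks[-1]:
            blocks.append([])
    if not blocks[-1]:
        blocks.pop()

    corpus = Corpus(source="pubtator")
    for block in blocks:
        title = abstract = None
        pmid = None
        annotations: list[tuple[int, int, str, str, Optional[str]]] = []
        for line in block:
            if "|t|" in line:
                pmid, _, title = line.split("|", 2)
            elif "|a|" in line:
                pmid_a, _, abstract = line.split("|", 2)
                pmid = pmid or pmid_a
            else:
                fields = line.split("\t")
                if len(fields) < 5:
                    logger.warning("skipping malformed PubTator line: %r", line)
                    continue
                norm = fields[5] if len(fields) > 5 and fields[5] else None
                annotations.append(
                    (int(fields[1]), int(fields[2]), fields[3], fields[4], norm)
                )
        if title is None:
            logger.warning("PubTator block without title line skipped (pmid=%s)", pmid)
            continue
        full_text = title if abstract is None else f"{title} {abstract}"

        doc = Document(doc_id=pmid or "")
        sent_spans = split_sentences(full_text)
        for si, (s_start, s_end) in enumerate(sent_spans):
            doc.sentences.append(
                Sentence(sent_id=f"{doc.doc_id}.s{si}", text=full_text[s_start:s_end])
            )

        for start, end, mention, ann_type, norm in annotations:
            ent_type = _PUBTATOR_TYPE_MAP.get(ann_type.lower())
            if ent_type is None:
                continue
            if not (0 <= start < end <= len(full_text)):
                logger.warning(
                    "annotation %r [%d,%d) outside text of %s; skipped",
                    mention, start, end, doc.doc_id,
                )
                continue
            placed = False
            for si, (s_start, s_end) in enumerate(sent_spans):
                if start >= s_start and end <= s_end:
                    sent = doc.sentences[si]
                    ls, le = start - s_start, end - s_start
                    if sent.text[ls:le] != mention:
                        logger.warning(
                            "annotation %r does not match text slice in %s; skipped",
                            mention, sent.sent_id,
                        )
                        break
                    sent.entities.append(
                        Entity(
                            ent_id=f"{sent.sent_id}.e{len(sent.entities)}",
                            ent_type=ent_type,
                            char_start=ls,
                            char_end=le,
                            surface=mention,
                            norm_id=norm,
                        )
                    )
                    placed = True
                    break
            if not placed:
                logger.warning(
                    "annotation %r [%d,%d) crosses a sentence boundary in %s; dropped",
                    mention, start, end, doc.doc_id,
                )

        for sent in doc.sentences:
            sent.pairs = generate_candidate_pairs(sent, label=PairLabel.UNKNOWN)
        corpus.documents.append(doc)

    corpus.validate()
    return corpus
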