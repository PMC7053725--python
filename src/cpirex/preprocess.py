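"""Linguistic preprocessing: tokens, entity alignment, blinding, parses.

The kernels operate on sentence instances in which the two candidate
entities have been *blinded*: their tokens are collapsed into the generic
placeholders ``COMPOUND_C`` / ``PROTEIN_C`` (and, optionally, every other
annotated entity into ``COMPOUND_O`` / ``PROTEIN_O``) so that the learned
model generalizes over entity identity rather than memorizing names.

Dependency parses enter through a pluggable backend contract. The built-in
``fixture`` backend deterministically returns the left-to-right token chain
(edge type ``next``); adapters for real parsers can be registered at run
time via :func:`register_parser_backend`.

No full tagger or lemmatizer is bundled: part-of-speech tags come from a
small rule/lexicon tagger (punctuation, numerals, a closed function-word
lexicon, an interaction-verb lexicon with suffix heuristics) and lemma
lookup falls back to rudimentary s/es/ed/ing suffix stripping. This is
deliberately simple, deterministic and documented; the contract allows
richer backends to be plugged in.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Optional

from .corpus import CandidatePair, Entity, EntityType, Sentence

logger = logging.getLogger(__name__)

COMPOUND_C = "COMPOUND_C"
PROTEIN_C = "PROTEIN_C"
COMPOUND_O = "COMPOUND_O"
PROTEIN_O = "PROTEIN_O"


class AlignmentError(ValueError):
    """An entity span cannot be mapped onto the token sequence."""


class ParseError(RuntimeError):
    """A dependency-parser backend failed."""


# ---------------------------------------------------------------------------
# Tokens
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Token:
    index: int
    surface: str
    char_start: int
    char_end: int
    pos: str
    is_capitalized: bool
    is_punct: bool
    is_numeral: bool


# Numbers (incl. decimals) | words with internal hyphen/slash/period | any
# other single non-space character (punctuation split off).
_TOKEN_RE = re.compile(r"\d+(?:[.,]\d+)+|\w+(?:[-/.]\w+)*|\S")
_NUMERAL_RE = re.compile(r"^\d+(?:[.,]\d+)*$")


def _is_punct(surface: str) -> bool:
    return all(unicodedata.category(ch).startswith("P") for ch in surface)


# Closed-class function words for the rule tagger.
_FUNCTION_TAGS = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "these": "DT",
    "that": "DT", "of": "IN", "in": "IN", "on": "IN", "at": "IN",
    "by": "IN", "with": "IN", "without": "IN", "from": "IN", "for": "IN",
    "via": "IN", "through": "IN", "as": "IN", "after": "IN", "before": "IN",
    "during": "IN", "between": "IN", "near": "IN", "versus": "IN",
    "and": "CC", "or": "CC", "but": "CC", "plus": "CC",
    "to": "TO", "not": "RB", "no": "DT",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD",
    "be": "VB", "been": "VBN", "being": "VBG",
    "has": "VBZ", "have": "VBP", "had": "VBD",
    "it": "PRP", "its": "PRP$", "which": "WDT", "we": "PRP",
}


def lemma_candidates(surface: str) -> set[str]:
    """Lowercased lemma guesses by rudimentary suffix stripping.

    Handles s/es/ed/ing (with e-restoration for -ed/-ing), e.g.
    ``inhibits -> inhibit``, ``induced -> induce``, ``binding -> bind``.
    """
    word = surface.lower()
    cands = {word}
    if len(word) > 3 and word.endswith("ies"):
        cands.add(word[:-3] + "y")
    if len(word) > 2 and word.endswith("es"):
        cands.add(word[:-2])
    if len(word) > 1 and word.endswith("s"):
        cands.add(word[:-1])
    if len(word) > 3 and word.endswith("ed"):
        cands.add(word[:-2])
        cands.add(word[:-1])  # induced -> induce
        cands.add(word[:-2] + "e")
    if len(word) > 4 and word.endswith("ing"):
        cands.add(word[:-3])
        cands.add(word[:-3] + "e")
    return cands


def _tag(surface: str, is_punct_flag: bool, is_numeral_flag: bool,
         verb_lemmas: frozenset[str]) -> str:
    if is_punct_flag:
        return surface if surface in {".", ",", ":", ";"} else "SYM"
    if is_numeral_flag:
        return "CD"
    lower = surface.lower()
    if lower in _FUNCTION_TAGS:
        return _FUNCTION_TAGS[lower]
    if verb_lemmas and lemma_candidates(surface) & verb_lemmas:
        if lower.endswith("ing"):
            return "VBG"
        if lower.endswith("ed"):
            return "VBD"
        if lower.endswith("s"):
            return "VBZ"
        return "VB"
    if lower.endswith("ly"):
        return "RB"
    if surface[:1].isupper():
        return "NNP"
    if lower.endswith("s"):
        return "NNS"
    return "NN"


def tokenize(text: str, verb_lemmas: Optional[frozenset[str]] = None) -> list[Token]:
    """Split a sentence into tokens with orthographic flags and POS tags.

    Punctuation is split off into separate tokens; hyphenated terms such as
    ``7-ketocholesterol`` stay single tokens; decimal numbers are single
    numeral tokens. Joining surfaces with the original whitespace
    reconstructs the input.
    """
    if verb_lemmas is None:
        verb_lemmas = default_interaction_verbs()
    tokens: list[Token] = []
    for match in _TOKEN_RE.finditer(text):
        surface = match.group()
        punct = _is_punct(surface)
        numeral = bool(_NUMERAL_RE.match(surface))
        tokens.append(
            Token(
                index=len(tokens),
                surface=surface,
                char_start=match.start(),
                char_end=match.end(),
                pos=_tag(surface, punct, numeral, verb_lemmas),
                is_capitalized=surface[:1].isalpha() and surface[:1].isupper(),
                is_punct=punct,
                is_numeral=numeral,
            )
        )
    return tokens


# ---------------------------------------------------------------------------
# Interaction-verb list
# ---------------------------------------------------------------------------

_DEFAULT_VERBS: Optional[frozenset[str]] = None


def load_verb_list(text: str) -> frozenset[str]:
    """Parse a verb list: one lemma per line, ``#`` comments allowed."""
    lemmas = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            lemmas.add(line.lower())
    return frozenset(lemmas)


def default_interaction_verbs() -> frozenset[str]:
    """The bundled curated interaction-verb lemma list."""
    global _DEFAULT_VERBS
    if _DEFAULT_VERBS is None:
        text = (
            resources.files("cpirex.data")
            .joinpath("interaction_verbs.txt")
            .read_text(encoding="utf-8")
        )
        _DEFAULT_VERBS = load_verb_list(text)
    return _DEFAULT_VERBS


# ---------------------------------------------------------------------------
# Sentence splitting (PubTator ingest)
# ---------------------------------------------------------------------------

_ABBREVIATIONS = {
    "e.g", "i.e", "et al", "fig", "figs", "ref", "refs", "vs", "cf",
    "dr", "prof", "approx", "no", "mr", "mrs", "inc", "spp", "sp",
}
_SENT_BOUNDARY_RE = re.compile(r"[.!?]+(\s+)(?=[A-Z0-9])")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Rule-based sentence spans: final punctuation + whitespace + capital.

    A guard list of common abbreviations (e.g., "et al.", "Fig.") and
    single-letter initials suppresses false boundaries.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for match in _SENT_BOUNDARY_RE.finditer(text):
        before = text[start:match.start()]
        last_word = before.rsplit(None, 1)[-1].lower() if before.split() else ""
        last_word = last_word.rstrip(".")
        if last_word in _ABBREVIATIONS or (len(last_word) == 1 and last_word.isalpha()):
            continue
        end = match.start() + len(match.group()) - len(match.group(1))
        spans.append((start, end))
        start = match.end()
    if start < len(text) and text[start:].strip():
        spans.append((start, len(text)))
    return spans


# ---------------------------------------------------------------------------
# Entity-token alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EntityTokenSpan:
    ent_id: str
    first_token: int
    last_token: int  # inclusive


def align_entities(
    entities: Iterable[Entity], tokens: list[Token]
) -> list[EntityTokenSpan]:
    """Map each entity to the minimal token range overlapping its span."""
    spans = []
    for ent in entities:
        overlapping = [
            t.index
            for t in tokens
            if t.char_start < ent.char_end and t.char_end > ent.char_start
        ]
        if not overlapping:
            raise AlignmentError(
                f"entity {ent.ent_id!r} overlaps no token "
                f"(span [{ent.char_start},{ent.char_end}))"
            )
        spans.append(EntityTokenSpan(ent.ent_id, min(overlapping), max(overlapping)))
    return spans


# ---------------------------------------------------------------------------
# Dependency parsing contract
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DependencyEdge:
    head: int
    dependent: int
    dep_type: str


def _fixture_parser(tokens: list[Token]) -> list[DependencyEdge]:
    return [
        DependencyEdge(i, i + 1, "next") for i in range(len(tokens) - 1)
    ]


ParserBackend = Callable[[list[Token]], list[DependencyEdge]]
_PARSER_BACKENDS: dict[str, ParserBackend] = {"fixture": _fixture_parser}


def register_parser_backend(name: str, backend: ParserBackend) -> None:
    _PARSER_BACKENDS[name] = backend


def available_parser_backends() -> list[str]:
    return sorted(_PARSER_BACKENDS)


def dependency_parse(
    tokens: list[Token], backend: str = "fixture"
) -> list[DependencyEdge]:
    """Typed head->dependent edges over the given tokens.

    The ``fixture`` backend returns the deterministic chain i -> i+1 with
    type ``next``, guaranteeing a connected parse for testing without an
    external parser.
    """
    if not tokens:
        raise ParseError("cannot parse an empty token list")
    try:
        parser = _PARSER_BACKENDS[backend]
    except KeyError:
        raise ParseError(f"unknown parser backend {backend!r}") from None
    try:
        edges = parser(tokens)
    except Exception as exc:  # adapter failures surface uniformly
        raise ParseError(f"parser backend {backend!r} failed: {exc}") from exc
    n = len(tokens)
    for edge in edges:
        if edge.head == edge.dependent or not (
            0 <= edge.head < n and 0 <= edge.dependent < n
        ):
            raise ParseError(f"backend {backend!r} returned invalid edge {edge}")
    return edges


@dataclass
class ParsedSentence:
    sentence: Sentence
    tokens: list[Token]
    entity_spans: dict[str, EntityTokenSpan]
    edges: list[DependencyEdge]


def parse_sentence(
    sentence: Sentence,
    verb_lemmas: Optional[frozenset[str]] = None,
    backend: str = "fixture",
) -> ParsedSentence:
    """Tokenize, align all entities and attach a dependency parse."""
    tokens = tokenize(sentence.text, verb_lemmas)
    spans = align_entities(sentence.entities, tokens)
    edges = dependency_parse(tokens, backend) if tokens else []
    return ParsedSentence(
        sentence=sentence,
        tokens=tokens,
        entity_spans={s.ent_id: s for s in spans},
        edges=edges,
    )


# ---------------------------------------------------------------------------
# Candidate blinding
# ---------------------------------------------------------------------------

@dataclass
class BlindedInstance:
    """A candidate pair's sentence after entity blinding.

    ``compound_index`` / ``protein_index`` locate the two single-token
    placeholders; ``degenerate`` marks instances whose candidate entities
    share tokens (these are excluded from kernel computation).
    """

    pair: CandidatePair
    doc_id: str
    tokens: list[Token] = field(default_factory=list)
    edges: list[DependencyEdge] = field(default_factory=list)
    compound_index: int = -1
    protein_index: int = -1
    degenerate: bool = False

    @property
    def first_placeholder(self) -> int:
        return min(self.compound_index, self.protein_index)

    @property
    def second_placeholder(self) -> int:
        return max(self.compound_index, self.protein_index)


def _placeholder_token(
    index: int, placeholder: str, head: Token
) -> Token:
    return Token(
        index=index,
        surface=placeholder,
        char_start=head.char_start,
        char_end=head.char_end,
        pos=head.pos,
        is_capitalized=True,
        is_punct=False,
        is_numeral=False,
    )


def blind_entities(
    parsed: ParsedSentence,
    pair: CandidatePair,
    blind_others: bool = True,
    doc_id: str = "",
) -> BlindedInstance:
    """Collapse candidate (and optionally other) entities to placeholders.

    Each collapsed span becomes a single placeholder token whose POS is
    inherited from the span's last (head) token. Dependency edges are
    re-indexed; edges internal to a collapsed span are dropped, as are
    duplicates created by the merge.
    """
    sent = parsed.sentence
    comp_span = parsed.entity_spans[pair.compound_ref]
    prot_span = parsed.entity_spans[pair.protein_ref]
    if (
        comp_span.first_token <= prot_span.last_token
        and prot_span.first_token <= comp_span.last_token
    ):
        logger.warning(
            "pair %s has overlapping candidate entities; instance degenerate",
            pair.pair_id,
        )
        return BlindedInstance(pair=pair, doc_id=doc_id, degenerate=True)

    # Collapse plan: (first, last, placeholder) in sentence order.
    plan = [
        (comp_span.first_token, comp_span.last_token, COMPOUND_C),
        (prot_span.first_token, prot_span.last_token, PROTEIN_C),
    ]
    if blind_others:
        candidate_ids = {pair.compound_ref, pair.protein_ref}
        taken = {(s.first_token, s.last_token) for s in (comp_span, prot_span)}
        for ent in sent.entities:
            if ent.ent_id in candidate_ids:
                continue
            span = parsed.entity_spans[ent.ent_id]
            key = (span.first_token, span.last_token)
            overlaps = any(
                span.first_token <= last and first <= span.last_token
                for first, last, _ in plan
            )
            if overlaps or key in taken:
                continue
            taken.add(key)
            ph = COMPOUND_O if ent.ent_type is EntityType.COMPOUND else PROTEIN_O
            plan.append((span.first_token, span.last_token, ph))
    plan.sort()

    collapse_of: dict[int, int] = {}  # old token index -> plan slot
    for slot, (first, last, _) in enumerate(plan):
        for old in range(first, last + 1):
            collapse_of[old] = slot

    new_tokens: list[Token] = []
    old_to_new: dict[int, int] = {}
    slot_new_index: dict[int, int] = {}
    comp_index = prot_index = -1
    for tok in parsed.tokens:
        slot = collapse_of.get(tok.index)
        if slot is None:
            old_to_new[tok.index] = len(new_tokens)
            new_tokens.append(
                Token(
                    index=len(new_tokens),
                    surface=tok.surface,
                    char_start=tok.char_start,
                    char_end=tok.char_end,
                    pos=tok.pos,
                    is_capitalized=tok.is_capitalized,
                    is_punct=tok.is_punct,
                    is_numeral=tok.is_numeral,
                )
            )
        else:
            if slot not in slot_new_index:
                first, last, placeholder = plan[slot]
                new_index = len(new_tokens)
                slot_new_index[slot] = new_index
                new_tokens.append(
                    _placeholder_token(new_index, placeholder, parsed.tokens[last])
                )
                if placeholder == COMPOUND_C:
                    comp_index = new_index
                elif placeholder == PROTEIN_C:
                    prot_index = new_index
            old_to_new[tok.index] = slot_new_index[slot]

    new_edges: list[DependencyEdge] = []
    seen: set[tuple[int, int, str]] = set()
    for edge in parsed.edges:
        h, d = old_to_new[edge.head], old_to_new[edge.dependent]
        if h == d:
            continue
        key = (h, d, edge.dep_type)
        if key in seen:
            continue
        seen.add(key)
        new_edges.append(DependencyEdge(h, d, edge.dep_type))

    return BlindedInstance(
        pair=pair,
        doc_id=doc_id,
        tokens=new_tokens,
        edges=new_edges,
        compound_index=comp_index,
        protein_index=prot_index,
    )


# ---------------------------------------------------------------------------
# Enclosed interaction verbs
# ---------------------------------------------------------------------------


def detect_enclosed_interaction_verb(
    parsed: ParsedSentence,
    pair: CandidatePair,
    verbs: Optional[frozenset[str]] = None,
) -> bool:
    """True iff an interaction verb lies strictly between the pair's entities.

    Enclosure is defined on surface token order (exclusive on both sides) and
    is symmetric in entity order. A match requires a verbal POS tag and a
    lemma (suffix-stripping fallback) in the verb set.
    """
    if verbs is None:
        verbs = default_interaction_verbs()
    span_a = parsed.entity_spans[pair.compound_ref]
    span_b = parsed.entity_spans[pair.protein_ref]
    left, right = sorted(
        (span_a, span_b), key=lambda s: (s.first_token, s.last_token)
    )
    for tok in parsed.tokens[left.last_token + 1 : right.first_token]:
        if tok.pos.startswith("V") and lemma_candidates(tok.surface) & verbs:
            return True
    return False
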