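"""Shallow linguistic kernel: global + local context similarity.

The kernel between two blinded candidate-pair instances is the sum of

* a **global context kernel** — cosine similarities of bag-of-n-gram vectors
  over three surface patterns relative to the two candidate placeholders:
  fore-between (tokens before the first placeholder plus the tokens between),
  between, and between-after — the placeholders themselves excluded; and
* a **local context kernel** — cosine similarities of indicator vectors over
  ordered windows (size ``w``) left and right of each placeholder, with
  surface, part-of-speech and orthographic (capitalisation / punctuation /
  numeral) features keyed by relative position.

Each of the five sub-kernels (fb, b, ba, left, right) is cosine-normalized
separately (0 for empty patterns), so the full kernel of an instance with
itself is at most 5. All sub-kernels are explicit sparse dot products, which
keeps the Gram-matrix computation a single sparse matrix product per block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._linalg import block_gram, normdot
from .preprocess import BlindedInstance, Token

logger = logging.getLogger(__name__)

_SEP = "\x1f"  # unit separator inside composite feature keys

BLOCKS = ("fb", "b", "ba", "left", "right")


@dataclass(frozen=True)
class SLParams:
    """n: max n-gram length; w: local window size (paper grid: 1..3 each)."""

    n: int = 3
    w: int = 1

    def __post_init__(self) -> None:
        if self.n < 1 or self.w < 1:
            raise ValueError("n and w must be >= 1")
        if self.n > 3 or self.w > 3:
            logger.warning("SLParams outside the evaluated 1..3 grid: %s", self)


@dataclass(frozen=True)
class GlobalContexts:
    fb: tuple[str, ...]
    b: tuple[str, ...]
    ba: tuple[str, ...]


def extract_global_contexts(inst: BlindedInstance) -> GlobalContexts:
    """Fore-between / between / between-after token patterns (lowercased).

    First/second placeholder are determined by surface position, not entity
    type, so the extraction is symmetric in entity order. Placeholders are
    excluded from all three patterns.
    """
    lo, hi = inst.first_placeholder, inst.second_placeholder
    surfaces = [t.surface.lower() for t in inst.tokens]
    before = surfaces[:lo]
    between = surfaces[lo + 1 : hi]
    after = surfaces[hi + 1 :]
    return GlobalContexts(
        fb=tuple(before + between), b=tuple(between), ba=tuple(between + after)
    )


def ngram_vector(tokens: Sequence[str], n: int) -> dict[str, int]:
    """Counts of all contiguous k-grams, k = 1..n (order kept within a gram)."""
    vec: dict[str, int] = {}
    for k in range(1, n + 1):
        for i in range(len(tokens) - k + 1):
            key = _SEP.join(tokens[i : i + k])
            vec[key] = vec.get(key, 0) + 1
    return vec


def global_kernel(g1: GlobalContexts, g2: GlobalContexts, n: int) -> float:
    """Sum of per-pattern cosine similarities of n-gram vectors (0..3)."""
    return sum(
        normdot(ngram_vector(getattr(g1, p), n), ngram_vector(getattr(g2, p), n))
        for p in ("fb", "b", "ba")
    )


def _token_features(tok: Token) -> list[tuple[str, str]]:
    return [
        ("surface", tok.surface.lower()),
        ("pos", tok.pos),
        ("cap", str(tok.is_capitalized)),
        ("punct", str(tok.is_punct)),
        ("num", str(tok.is_numeral)),
    ]


def extract_local_contexts(inst: BlindedInstance, w: int) -> dict[str, int]:
    """Position-indexed window features around both candidate placeholders.

    Keys are (side, entity, relative position, kind, value) tuples joined
    into strings; entity 1/2 is by surface position. Windows truncate at the
    sentence boundaries.
    """
    vec: dict[str, int] = {}
    anchors = [(1, inst.first_placeholder), (2, inst.second_placeholder)]
    for ent_no, anchor in anchors:
        for offset in range(-w, w + 1):
            if offset == 0:
                continue
            pos = anchor + offset
            if not (0 <= pos < len(inst.tokens)):
                continue
            side = "left" if offset < 0 else "right"
            for kind, value in _token_features(inst.tokens[pos]):
                key = _SEP.join((side, str(ent_no), str(offset), kind, value))
                vec[key] = 1
    return vec


def _split_sides(local_vec: dict[str, int]) -> tuple[dict[str, int], dict[str, int]]:
    left = {k: v for k, v in local_vec.items() if k.startswith("left" + _SEP)}
    right = {k: v for k, v in local_vec.items() if k.startswith("right" + _SEP)}
    return left, right


def local_kernel(l1: dict[str, int], l2: dict[str, int]) -> float:
    """Cosine similarity of left windows plus cosine of right windows (0..2)."""
    left1, right1 = _split_sides(l1)
    left2, right2 = _split_sides(l2)
    return normdot(left1, left2) + normdot(right1, right2)


def sl_features(inst: BlindedInstance, params: SLParams) -> dict[str, dict[str, int]]:
    """All five sparse feature blocks of one instance."""
    contexts = extract_global_contexts(inst)
    local = extract_local_contexts(inst, params.w)
    left, right = _split_sides(local)
    return {
        "fb": ngram_vector(contexts.fb, params.n),
        "b": ngram_vector(contexts.b, params.n),
        "ba": ngram_vector(contexts.ba, params.n),
        "left": left,
        "right": right,
    }


def sl_gram(
    feats_a: Sequence[dict[str, dict[str, int]]],
    feats_b: Sequence[dict[str, dict[str, int]]] | None = None,
) -> np.ndarray:
    """Kernel matrix between two featurized instance lists (sum of 5 blocks)."""
    out = None
    for block in BLOCKS:
        rows_a = [f[block] for f in feats_a]
        rows_b = None if feats_b is None else [f[block] for f in feats_b]
        g = block_gram(rows_a, rows_b)
        out = g if out is None else out + g
    return out


def sl_kernel_value(
    f1: dict[str, dict[str, int]], f2: dict[str, dict[str, int]]
) -> float:
    return sum(normdot(f1[block], f2[block]) for block in BLOCKS)


def sl_kernel_matrix(
    instances: Sequence[BlindedInstance], params: SLParams
) -> np.ndarray:
    """Symmetric PSD kernel matrix; diagonal 5.0 when all patterns non-empty."""
    if not instances:
        raise ValueError("need at least one instance")
    feats = [sl_features(inst, params) for inst in instances]
    gram = sl_gram(feats)
    return (gram + gram.T) / 2.0  # enforce exact symmetry
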