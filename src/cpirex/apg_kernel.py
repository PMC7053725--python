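"""All-paths graph kernel over weighted dependency graphs.

Each blinded candidate-pair instance becomes a vertex-labeled weighted graph:
vertices are the (blinded) tokens, labels are the lowercased surface (or
placeholder), the part-of-speech tag (``pos:TAG``) and the type of the
token's incoming dependency (``dep:TYPE``); every dependency edge is
inserted in both orientations. Edges on a shortest undirected path between
the two candidate entities receive the emphasis weight ``w_sp``; all other
edges the background weight ``w_other`` (both < 1 so the walk series
converges).

Summing the adjacency-matrix powers gives the total weight of all directed
walks of every length >= 1 between each vertex pair; with spectral radius
below 1 this is the closed-form Neumann sum (I - W)^-1 - I, otherwise the
series is truncated at ``d_max`` and flagged. Projecting through the binary
label-allocation matrix L gives the feature matrix G = L^T M L — the total
path weight between each ordered *label* pair — and the kernel between two
instances is the Frobenius inner product of their feature matrices over the
union label alphabet, cosine-normalized to a unit diagonal.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from ._linalg import block_gram, dot
from .preprocess import BlindedInstance, DependencyEdge, EntityTokenSpan

logger = logging.getLogger(__name__)

_SEP = "\x1f"


class DegenerateInstanceError(ValueError):
    """Instance unusable for the graph kernel (e.g. fewer than 2 vertices)."""


@dataclass(frozen=True)
class APGParams:
    """c: RLS regularization trade-off (paper grid 0.25..2.0); w_sp / w_other:
    shortest-path and background edge weights; d_max: series truncation used
    when the walk series diverges (default 2x vertex count); dep_labels:
    include incoming-dependency-type vertex labels."""

    c: float = 0.25
    w_sp: float = 0.9
    w_other: float = 0.3
    d_max: Optional[int] = None
    dep_labels: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.w_other <= self.w_sp < 1):
            raise ValueError("require 0 < w_other <= w_sp < 1")
        if self.c <= 0:
            raise ValueError("c must be positive")
        if self.d_max is not None and self.d_max < 1:
            raise ValueError("d_max must be >= 1")


@dataclass
class WeightedGraph:
    W: np.ndarray  # square non-negative adjacency, W[i, j] = weight of i -> j


@dataclass
class LabelAllocation:
    L: np.ndarray  # |vertices| x |labels| binary
    labels: list[str]


@dataclass
class APGFeatureMatrix:
    G: np.ndarray  # |labels| x |labels|
    labels: list[str]


def shortest_path_edges(
    edges: Sequence[DependencyEdge],
    span1: EntityTokenSpan,
    span2: EntityTokenSpan,
) -> set[tuple[int, int]]:
    """Undirected edges on any minimal-length path between the two spans.

    Edges are unit-length and undirected for this purpose; the minimum is
    taken over all (token of span1, token of span2) endpoint combinations.
    Returns the empty set if the spans are disconnected.
    """
    graph = nx.Graph()
    for edge in edges:
        graph.add_edge(edge.head, edge.dependent)
    sources = range(span1.first_token, span1.last_token + 1)
    targets = range(span2.first_token, span2.last_token + 1)
    best = None
    best_pairs: list[tuple[int, int]] = []
    for s, t in itertools.product(sources, targets):
        if s not in graph or t not in graph:
            continue
        try:
            d = nx.shortest_path_length(graph, s, t)
        except nx.NetworkXNoPath:
            continue
        if best is None or d < best:
            best, best_pairs = d, [(s, t)]
        elif d == best:
            best_pairs.append((s, t))
    result: set[tuple[int, int]] = set()
    for s, t in best_pairs:
        for path in nx.all_shortest_paths(graph, s, t):
            for u, v in zip(path, path[1:]):
                result.add((min(u, v), max(u, v)))
    return result


def vertex_labels(
    inst: BlindedInstance, index: int, dep_labels: bool = True
) -> set[str]:
    """Label set of one vertex: surface/placeholder, POS, incoming dep type."""
    tok = inst.tokens[index]
    labels = {tok.surface if tok.surface.endswith("_C") or tok.surface.endswith("_O")
              else tok.surface.lower(),
              f"pos:{tok.pos}"}
    if dep_labels:
        for edge in inst.edges:
            if edge.dependent == index:
                labels.add(f"dep:{edge.dep_type}")
                break
    return labels


def build_weighted_graph(
    inst: BlindedInstance, params: APGParams
) -> tuple[WeightedGraph, LabelAllocation]:
    """Adjacency (both orientations per dependency) and label allocation."""
    n = len(inst.tokens)
    if n < 2:
        raise DegenerateInstanceError(
            f"instance {inst.pair.pair_id!r} has {n} vertices"
        )
    sp_edges = shortest_path_edges(
        inst.edges,
        EntityTokenSpan("c", inst.compound_index, inst.compound_index),
        EntityTokenSpan("p", inst.protein_index, inst.protein_index),
    )
    W = np.zeros((n, n))
    for edge in inst.edges:
        key = (min(edge.head, edge.dependent), max(edge.head, edge.dependent))
        weight = params.w_sp if key in sp_edges else params.w_other
        W[edge.head, edge.dependent] = weight
        W[edge.dependent, edge.head] = weight

    label_sets = [vertex_labels(inst, i, params.dep_labels) for i in range(n)]
    alphabet = sorted(set().union(*label_sets))
    index_of = {lab: j for j, lab in enumerate(alphabet)}
    L = np.zeros((n, len(alphabet)))
    for i, labs in enumerate(label_sets):
        for lab in labs:
            L[i, index_of[lab]] = 1.0
    return WeightedGraph(W=W), LabelAllocation(L=L, labels=alphabet)


def all_paths_matrix(
    W: np.ndarray, d_max: Optional[int] = None
) -> tuple[np.ndarray, bool]:
    """Total walk weights of all lengths >= 1 between vertex pairs.

    Returns ``(M, truncated)``. With spectral radius below 1 the closed-form
    Neumann sum (I - W)^-1 - I is used; otherwise the series is truncated at
    ``d_max`` terms (default 2x the vertex count) and flagged.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if (W < 0).any():
        raise ValueError("W must be non-negative")
    n = W.shape[0]
    if d_max is None:
        d_max = 2 * n
    rho = max(abs(np.linalg.eigvals(W))) if n else 0.0
    if rho <= 1.0 - 1e-6:
        M = np.linalg.inv(np.eye(n) - W) - np.eye(n)
        return np.maximum(M, 0.0), False
    logger.debug(
        "walk series diverges (spectral radius %.4f); truncating at %d", rho, d_max
    )
    M = np.zeros_like(W)
    power = np.eye(n)
    for _ in range(d_max):
        power = power @ W
        M += power
    return M, True


def feature_matrix(alloc: LabelAllocation, M: np.ndarray) -> APGFeatureMatrix:
    """G = L^T M L: total path weight between each ordered label pair."""
    L = alloc.L
    if L.shape[0] != M.shape[0]:
        raise ValueError("label allocation and path matrix dimensions differ")
    return APGFeatureMatrix(G=L.T @ M @ L, labels=list(alloc.labels))


def _flatten(fm: APGFeatureMatrix) -> dict[str, float]:
    out: dict[str, float] = {}
    for i, la in enumerate(fm.labels):
        row = fm.G[i]
        for j, lb in enumerate(fm.labels):
            if row[j] != 0.0:
                out[la + _SEP + lb] = float(row[j])
    return out


def apg_kernel_value(fm1: APGFeatureMatrix, fm2: APGFeatureMatrix) -> float:
    """Frobenius inner product over the union label alphabet (unnormalized)."""
    return dot(_flatten(fm1), _flatten(fm2))


def apg_features(inst: BlindedInstance, params: APGParams) -> dict[str, float]:
    """Flattened sparse feature matrix of one instance."""
    graph, alloc = build_weighted_graph(inst, params)
    M, truncated = all_paths_matrix(graph.W, params.d_max)
    if truncated:
        logger.debug("instance %s used truncated walk series", inst.pair.pair_id)
    return _flatten(feature_matrix(alloc, M))


def apg_gram(
    feats_a: Sequence[dict[str, float]],
    feats_b: Sequence[dict[str, float]] | None = None,
) -> np.ndarray:
    return block_gram(feats_a, feats_b)


def apg_kernel_matrix(
    instances: Sequence[BlindedInstance], params: APGParams
) -> tuple[np.ndarray, list[str]]:
    """Cosine-normalized kernel matrix (unit diagonal, symmetric, PSD).

    Degenerate instances (overlapping candidates or < 2 vertices) are
    excluded; their pair ids are logged and returned alongside the matrix,
    which covers the remaining instances in input order.
    """
    kept, excluded = [], []
    for inst in instances:
        if inst.degenerate or len(inst.tokens) < 2:
            excluded.append(inst.pair.pair_id)
        else:
            kept.append(inst)
    if excluded:
        logger.warning("excluded degenerate instances: %s", ", ".join(excluded))
    if not kept:
        raise DegenerateInstanceError("no non-degenerate instances")
    feats = [apg_features(inst, params) for inst in kept]
    gram = apg_gram(feats)
    return (gram + gram.T) / 2.0, excluded
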