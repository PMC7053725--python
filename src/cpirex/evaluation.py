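"""Evaluation: metrics, document-wise CV, stratification, kernel combination.

Cross-validation is *document-wise*: folds partition documents (abstracts),
never splitting one document's candidate pairs across train and test, since
instance-wise splitting leaks near-duplicate sentences and produces
overoptimistic estimates. Decision scores of all test folds are pooled into
a single report (scores are comparable across folds because both kernels are
cosine-normalized to a unit diagonal).

The co-occurrence baseline labels every candidate pair positive (recall
100%, specificity 0%); kernel results can be stratified by whether the pair
encloses an interaction verb, the dependence of label and verb presence
tested with a Pearson chi-squared (1 df, no continuity correction), and two
kernels combined by conjunction — a pair is positive only when both models
say so — compared fairly against single kernels recalibrated to the same
precision via a threshold scan.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2, rankdata

from . import classifiers
from .apg_kernel import APGParams, apg_features, apg_gram
from .corpus import Corpus, PairLabel
from .preprocess import (
    BlindedInstance,
    blind_entities,
    default_interaction_verbs,
    detect_enclosed_interaction_verb,
    parse_sentence,
)
from .sl_kernel import SLParams, sl_features, sl_gram

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def round_half_up(x: float, ndigits: int = 1) -> float:
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts plus derived percentage metrics.

    Undefined ratios (zero denominators) are ``None``, never 0 by
    convention. All derived values are kept at full precision; rounding
    (half-up, one decimal) happens only at presentation via :meth:`rounded`.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    auc: Optional[float] = None

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def recall(self) -> Optional[float]:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else None

    @property
    def specificity(self) -> Optional[float]:
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else None

    @property
    def precision(self) -> Optional[float]:
        d = self.tp + self.fp
        return 100.0 * self.tp / d if d else None

    @property
    def accuracy(self) -> Optional[float]:
        return 100.0 * (self.tp + self.tn) / self.total if self.total else None

    @property
    def f1(self) -> Optional[float]:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return None
        return 2.0 * p * r / (p + r)

    def rounded(self) -> dict[str, Optional[float]]:
        out = {}
        for name in ("recall", "specificity", "precision", "accuracy", "f1", "auc"):
            value = getattr(self, name)
            out[name] = None if value is None else round_half_up(value)
        return out


def metrics(tp: int, fp: int, tn: int, fn: int,
            auc: Optional[float] = None) -> EvaluationReport:
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer")
    if tp + fp + tn + fn == 0:
        raise ValueError("at least one count must be positive")
    return EvaluationReport(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn), auc=auc)


def baseline_cooccurrence(n_pos: int, n_neg: int) -> EvaluationReport:
    """Every co-occurring pair called positive: recall 100%, specificity 0%."""
    return metrics(tp=n_pos, fp=n_neg, tn=0, fn=0)


def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve as a percentage (Mann-Whitney statistic).

    Equals the fraction of (positive, negative) pairs ranked correctly, ties
    counting one half.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = labels > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)  # average ranks handle ties as 0.5 wins
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return 100.0 * u / (n_pos * n_neg)


# ---------------------------------------------------------------------------
# Document-wise cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVSplit:
    k: int
    assignment: dict[str, int]  # doc_id -> fold
    seed: int


def document_folds(corpus: Corpus, k: int, seed: int) -> CVSplit:
    """Shuffle documents with a seeded RNG and deal them round-robin."""
    doc_ids = [doc.doc_id for doc in corpus.documents]
    if len(doc_ids) < k:
        raise ValueError(f"need at least {k} documents, have {len(doc_ids)}")
    rng = random.Random(seed)
    rng.shuffle(doc_ids)
    return CVSplit(
        k=k, assignment={d: i % k for i, d in enumerate(doc_ids)}, seed=seed
    )


@dataclass
class PreparedPair:
    doc_id: str
    pair_id: str
    label: PairLabel
    encloses_verb: bool
    instance: BlindedInstance

    @property
    def y(self) -> int:
        return 1 if self.label is PairLabel.FUNCTIONAL else -1


def prepare_corpus(
    corpus: Corpus,
    verbs: Optional[frozenset[str]] = None,
    parser_backend: str = "fixture",
    blind_others: bool = True,
) -> list[PreparedPair]:
    """Parse, blind and verb-flag every candidate pair of a corpus."""
    if verbs is None:
        verbs = default_interaction_verbs()
    prepared = []
    for doc, sent in corpus.iter_sentences():
        if not sent.pairs:
            continue
        parsed = parse_sentence(sent, verbs, parser_backend)
        for pair in sent.pairs:
            inst = blind_entities(parsed, pair, blind_others, doc_id=doc.doc_id)
            flag = (
                pair.encloses_verb
                if pair.encloses_verb is not None
                else detect_enclosed_interaction_verb(parsed, pair, verbs)
            )
            prepared.append(
                PreparedPair(
                    doc_id=doc.doc_id,
                    pair_id=pair.pair_id,
                    label=pair.label,
                    encloses_verb=flag,
                    instance=inst,
                )
            )
    return prepared


def featurize(
    prepared: Sequence[PreparedPair], kernel_kind: str, kernel_params
) -> list:
    if kernel_kind == "sl":
        params = kernel_params if isinstance(kernel_params, SLParams) else SLParams(
            **(kernel_params or {})
        )
        return [sl_features(p.instance, params) for p in prepared]
    if kernel_kind == "apg":
        params = kernel_params if isinstance(kernel_params, APGParams) else APGParams(
            **(kernel_params or {})
        )
        return [apg_features(p.instance, params) for p in prepared]
    raise ValueError(f"unknown kernel kind {kernel_kind!r}")


def gram_fn(kernel_kind: str):
    return sl_gram if kernel_kind == "sl" else apg_gram


def default_classifier(kernel_kind: str, kernel_params, clf_params) -> dict:
    """SL pairs with the SVC, APG with RLS, unless overridden."""
    clf = dict(clf_params or {})
    clf.setdefault("kind", "svc" if kernel_kind == "sl" else "rls")
    if clf["kind"] == "rls" and "c" not in clf:
        c = getattr(kernel_params, "c", None)
        if c is None and isinstance(kernel_params, dict):
            c = kernel_params.get("c")
        clf["c"] = c if c is not None else 0.25
    if clf["kind"] == "svc":
        clf.setdefault("C", 1.0)
    return clf


def _train(kind_params: dict, K: np.ndarray, y: np.ndarray, ids: list[str]):
    if kind_params["kind"] == "svc":
        return classifiers.svc_train(K, y, C=kind_params["C"], instance_ids=ids)
    return classifiers.rls_train(K, y, c=kind_params["c"], instance_ids=ids)


@dataclass(frozen=True)
class ScoredPair:
    pair_id: str
    doc_id: str
    label: int  # +/-1
    score: Optional[float]  # None: unscored (degenerate / skipped fold)
    fold: int
    encloses_verb: bool


def _cv_pool(
    prepared: Sequence[PreparedPair],
    K: np.ndarray,
    usable: Sequence[int],
    clf: dict,
    fold_of: dict[str, int],
) -> list[ScoredPair]:
    """Score every pair once by a model trained on the other folds."""
    scores: dict[int, float] = {}
    folds = sorted(set(fold_of.values()))
    for f in folds:
        train_idx = [i for i in usable if fold_of[prepared[i].doc_id] != f]
        test_idx = [i for i in usable if fold_of[prepared[i].doc_id] == f]
        if not test_idx:
            continue
        y_train = np.array([prepared[i].y for i in train_idx])
        if len(set(y_train.tolist())) < 2:
            logger.warning("fold %d skipped: single-class training data", f)
            continue
        model = _train(
            clf, K[np.ix_(train_idx, train_idx)], y_train,
            [prepared[i].pair_id for i in train_idx],
        )
        fold_scores = classifiers.predict(model, K[np.ix_(train_idx, test_idx)])
        for i, s in zip(test_idx, fold_scores):
            scores[i] = float(s)
    return [
        ScoredPair(
            pair_id=p.pair_id,
            doc_id=p.doc_id,
            label=p.y,
            score=scores.get(i),
            fold=fold_of.get(p.doc_id, -1),
            encloses_verb=p.encloses_verb,
        )
        for i, p in enumerate(prepared)
    ]


def cross_validate(
    corpus: Corpus,
    kernel_kind: str,
    kernel_params=None,
    clf_params: Optional[dict] = None,
    split: Optional[CVSplit] = None,
    *,
    verbs: Optional[frozenset[str]] = None,
    parser_backend: str = "fixture",
    blind_others: bool = True,
    prepared: Optional[Sequence[PreparedPair]] = None,
) -> list[ScoredPair]:
    """Pooled document-wise CV scores: every labeled pair scored exactly once.

    Degenerate instances and pairs in skipped single-class folds come back
    with ``score=None``; all others carry the decision score of the model
    trained on the complement of their document's fold.
    """
    if split is None:
        raise ValueError("a CVSplit is required (see document_folds)")
    if prepared is None:
        prepared = prepare_corpus(corpus, verbs, parser_backend, blind_others)
    unknown = [p.pair_id for p in prepared if p.label is PairLabel.UNKNOWN]
    if unknown:
        raise ValueError(f"cross-validation requires labeled pairs; unknown: {unknown[:5]}")
    usable = [i for i, p in enumerate(prepared) if not p.instance.degenerate]
    if len(usable) < len(prepared):
        logger.warning("%d degenerate pairs left unscored", len(prepared) - len(usable))
    feats_all = featurize([prepared[i] for i in usable], kernel_kind, kernel_params)
    K_usable = gram_fn(kernel_kind)(feats_all)
    # Re-embed into full index space for bookkeeping simplicity.
    K = np.zeros((len(prepared), len(prepared)))
    K[np.ix_(usable, usable)] = K_usable
    clf = default_classifier(kernel_kind, kernel_params, clf_params)
    return _cv_pool(prepared, K, usable, clf, split.assignment)


def evaluate_pooled(
    scored: Sequence[ScoredPair], threshold: float = 0.0, with_auc: bool = True
) -> EvaluationReport:
    """Confusion counts and pooled AUC at a decision threshold (score > t)."""
    usable = [s for s in scored if s.score is not None]
    if not usable:
        raise ValueError("no scored pairs to evaluate")
    tp = fp = tn = fn = 0
    for s in usable:
        pred_pos = s.score > threshold
        if pred_pos and s.label > 0:
            tp += 1
        elif pred_pos:
            fp += 1
        elif s.label > 0:
            fn += 1
        else:
            tn += 1
    auc_value = None
    if with_auc:
        labels = [s.label for s in usable]
        if len(set(labels)) == 2:
            auc_value = auc(labels, [s.score for s in usable])
    return metrics(tp, fp, tn, fn, auc=auc_value)


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------


def nested_cv(
    corpus: Corpus,
    kernel_kind: str,
    param_grid: Sequence,
    split: CVSplit,
    clf_params: Optional[dict] = None,
    *,
    verbs: Optional[frozenset[str]] = None,
    parser_backend: str = "fixture",
    blind_others: bool = True,
) -> tuple[list[ScoredPair], dict[int, object]]:
    """Outer CV with per-fold grid selection by inner document-wise CV AUC.

    For each outer fold, an inner (k-1)-fold document-wise CV on the outer
    training documents picks the grid point with the highest pooled inner
    AUC (ties: first in grid order); a model with that setting, trained on
    the full outer training set, scores the outer test fold. Returns the
    pooled outer scores and the chosen grid point per fold.
    """
    if not param_grid:
        raise ValueError("empty parameter grid")
    prepared = prepare_corpus(corpus, verbs, parser_backend, blind_others)
    usable = [i for i, p in enumerate(prepared) if not p.instance.degenerate]
    fold_of = split.assignment

    # Featurize once per grid point over all usable instances.
    grams = {}
    for gi, params in enumerate(param_grid):
        feats = featurize([prepared[i] for i in usable], kernel_kind, params)
        K_usable = gram_fn(kernel_kind)(feats)
        K = np.zeros((len(prepared), len(prepared)))
        K[np.ix_(usable, usable)] = K_usable
        grams[gi] = K

    chosen: dict[int, object] = {}
    pooled: dict[int, float] = {}
    folds = sorted(set(fold_of.values()))
    for f in folds:
        outer_train = [i for i in usable if fold_of[prepared[i].doc_id] != f]
        outer_test = [i for i in usable if fold_of[prepared[i].doc_id] == f]
        if not outer_test:
            continue
        train_docs = sorted({prepared[i].doc_id for i in outer_train})
        inner_k = min(split.k - 1, len(train_docs))
        rng = random.Random(split.seed * 1009 + f)
        shuffled = list(train_docs)
        rng.shuffle(shuffled)
        inner_fold_of = {d: i % inner_k for i, d in enumerate(shuffled)}

        best_gi, best_auc = 0, -math.inf
        for gi, params in enumerate(param_grid):
            clf = default_classifier(kernel_kind, params, clf_params)
            inner_scored = _cv_pool(
                prepared, grams[gi], outer_train, clf,
                {d: inner_fold_of[d] for d in train_docs},
            )
            inner_used = [
                s for s in inner_scored
                if s.score is not None and s.doc_id in inner_fold_of
            ]
            labels = [s.label for s in inner_used]
            if len(set(labels)) < 2:
                continue
            inner_auc = auc(labels, [s.score for s in inner_used])
            if inner_auc > best_auc + 1e-12:
                best_gi, best_auc = gi, inner_auc
        chosen[f] = param_grid[best_gi]

        clf = default_classifier(kernel_kind, param_grid[best_gi], clf_params)
        K = grams[best_gi]
        y_train = np.array([prepared[i].y for i in outer_train])
        model = _train(
            clf, K[np.ix_(outer_train, outer_train)], y_train,
            [prepared[i].pair_id for i in outer_train],
        )
        fold_scores = classifiers.predict(model, K[np.ix_(outer_train, outer_test)])
        for i, s in zip(outer_test, fold_scores):
            pooled[i] = float(s)

    scored = [
        ScoredPair(
            pair_id=p.pair_id, doc_id=p.doc_id, label=p.y,
            score=pooled.get(i), fold=fold_of[p.doc_id],
            encloses_verb=p.encloses_verb,
        )
        for i, p in enumerate(prepared)
    ]
    return scored, chosen


# ---------------------------------------------------------------------------
# Stratification, independence, combination
# ---------------------------------------------------------------------------


def stratify_by_verb(
    scored: Sequence[ScoredPair], threshold: float = 0.0
) -> tuple[Optional[EvaluationReport], Optional[EvaluationReport]]:
    """Recompute the pooled report separately for verb-enclosing pairs (IV)
    and the remainder (NIV); either report is None if its subset is empty."""
    iv = [s for s in scored if s.encloses_verb]
    niv = [s for s in scored if not s.encloses_verb]
    report_iv = evaluate_pooled(iv, threshold) if any(
        s.score is not None for s in iv
    ) else None
    report_niv = evaluate_pooled(niv, threshold) if any(
        s.score is not None for s in niv
    ) else None
    return report_iv, report_niv


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int  # positive, verb
    b: int  # positive, no verb
    c: int  # negative, verb
    d: int  # negative, no verb

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def chi_squared_independence(t: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) and its p-value."""
    a, b, c, d = t.a, t.b, t.c, t.d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if t.n <= 0 or any(m == 0 for m in margins):
        raise ValueError("chi-squared undefined: zero marginal")
    stat = t.n * (a * d - b * c) ** 2 / math.prod(margins)
    return stat, float(chi2.sf(stat, df=1))


def verb_label_table(pairs: Sequence) -> ContingencyTable2x2:
    """Label x verb-presence table from scored or prepared pairs."""
    signs = [getattr(p, "y", None) or p.label for p in pairs]
    flags = [p.encloses_verb for p in pairs]
    a = sum(1 for y, v in zip(signs, flags) if y > 0 and v)
    b = sum(1 for y, v in zip(signs, flags) if y > 0 and not v)
    c = sum(1 for y, v in zip(signs, flags) if y < 0 and v)
    d = sum(1 for y, v in zip(signs, flags) if y < 0 and not v)
    return ContingencyTable2x2(a, b, c, d)


def combine_and(labels_a: Sequence[int], labels_b: Sequence[int]) -> np.ndarray:
    """Conjunction of two +/-1 label vectors: +1 only where both are +1."""
    la = np.asarray(labels_a)
    lb = np.asarray(labels_b)
    if la.shape != lb.shape:
        raise ValueError("label vectors must have equal length")
    return np.where((la > 0) & (lb > 0), 1, -1)


def combine_scored(
    scored_a: Sequence[ScoredPair],
    scored_b: Sequence[ScoredPair],
    threshold_a: float = 0.0,
    threshold_b: float = 0.0,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Align two pooled score lists by pair_id and combine by conjunction.

    Returns (pair ids, true labels, combined predicted labels). Misaligned
    id universes are a contract error.
    """
    by_id_a = {s.pair_id: s for s in scored_a if s.score is not None}
    by_id_b = {s.pair_id: s for s in scored_b if s.score is not None}
    if set(by_id_a) != set(by_id_b):
        missing = set(by_id_a) ^ set(by_id_b)
        raise ValueError(f"pair-id universes differ; e.g. {sorted(missing)[:5]}")
    ids = sorted(by_id_a)
    truth = np.array([by_id_a[i].label for i in ids])
    preds_a = classifiers.threshold_labels(
        [by_id_a[i].score for i in ids], threshold_a
    )
    preds_b = classifiers.threshold_labels(
        [by_id_b[i].score for i in ids], threshold_b
    )
    return ids, truth, combine_and(preds_a, preds_b)


def report_from_predictions(
    truth: Sequence[int], predicted: Sequence[int]
) -> EvaluationReport:
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    tp = int(((truth > 0) & (predicted > 0)).sum())
    fp = int(((truth < 0) & (predicted > 0)).sum())
    tn = int(((truth < 0) & (predicted < 0)).sum())
    fn = int(((truth > 0) & (predicted < 0)).sum())
    return metrics(tp, fp, tn, fn)


def matched_precision_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    target_precision: float,
) -> float:
    """Lowest threshold (most positive predictions) reaching a precision target.

    Candidate thresholds are midpoints between consecutive distinct sorted
    scores plus +/-inf; among candidates whose precision (on score > t) is
    defined and >= target, the one yielding the largest number of positive
    predictions is returned. If no threshold achieves the target, +inf is
    returned with a warning (no positive predictions).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need both classes")
    distinct = np.unique(scores)
    candidates = [-math.inf]
    candidates += [
        (lo + hi) / 2.0 for lo, hi in zip(distinct, distinct[1:])
    ]
    for t in candidates:  # ascending threshold = descending positive count
        pred_pos = scores > t
        n_pos = int(pred_pos.sum())
        if n_pos == 0:
            continue
        precision = 100.0 * (labels[pred_pos] > 0).sum() / n_pos
        if precision >= target_precision:
            return t
    logger.warning(
        "no threshold reaches precision %.1f%%; returning +inf", target_precision
    )
    return math.inf
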