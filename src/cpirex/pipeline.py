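"""Whole-corpus training and prediction with portable model files.

A pipeline model bundles everything needed to score new candidate pairs:
kernel kind and parameters, the trained dual-form classifier, the training
instances' sparse feature vectors (required to evaluate the precomputed
kernel against new instances), and a preprocessing fingerprint (verb-list
hash, parser backend, blinding mode, kernel parameters). Prediction refuses
to run when the fingerprint does not match the requested preprocessing, so a
model can never silently be applied under different conventions than it was
trained with.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import classifiers
from .apg_kernel import APGParams
from .corpus import Corpus, PairLabel
from .evaluation import (
    default_classifier,
    featurize,
    gram_fn,
    prepare_corpus,
    _train,
)
from .preprocess import default_interaction_verbs
from .sl_kernel import SLParams

logger = logging.getLogger(__name__)

FORMAT = "cpirex-pipeline-model"
VERSION = 1


def _params_obj(kernel_kind: str, kernel_params):
    if isinstance(kernel_params, (SLParams, APGParams)):
        return kernel_params
    cls = SLParams if kernel_kind == "sl" else APGParams
    return cls(**(kernel_params or {}))


def verb_list_hash(verbs: frozenset[str]) -> str:
    payload = "\n".join(sorted(verbs)).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()


def make_fingerprint(
    kernel_kind: str,
    kernel_params,
    verbs: frozenset[str],
    parser_backend: str,
    blind_others: bool,
) -> dict:
    params = _params_obj(kernel_kind, kernel_params)
    return {
        "kernel_kind": kernel_kind,
        "kernel_params": dataclasses.asdict(params),
        "verb_list_sha256": verb_list_hash(verbs),
        "parser_backend": parser_backend,
        "blind_others": blind_others,
    }


@dataclass
class PipelineModel:
    fingerprint: dict
    classifier: classifiers.TrainedModel
    train_features: list  # sparse feature vectors of the training instances

    @property
    def kernel_kind(self) -> str:
        return self.fingerprint["kernel_kind"]

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "format": FORMAT,
                    "version": VERSION,
                    "fingerprint": self.fingerprint,
                    "classifier": self.classifier.to_dict(),
                    "train_features": self.train_features,
                },
                fh,
            )

    @classmethod
    def load(cls, path: str) -> "PipelineModel":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        if data.get("format") != FORMAT:
            raise ValueError(f"{path} is not a {FORMAT} file")
        return cls(
            fingerprint=data["fingerprint"],
            classifier=classifiers.TrainedModel.from_dict(data["classifier"]),
            train_features=data["train_features"],
        )


def train_model(
    corpus: Corpus,
    kernel_kind: str,
    kernel_params=None,
    clf_params: Optional[dict] = None,
    *,
    verbs: Optional[frozenset[str]] = None,
    parser_backend: str = "fixture",
    blind_others: bool = True,
    threshold: float = 0.0,
) -> PipelineModel:
    """Train one model on every labeled, non-degenerate pair of the corpus."""
    if verbs is None:
        verbs = default_interaction_verbs()
    prepared = prepare_corpus(corpus, verbs, parser_backend, blind_others)
    labeled = [
        p for p in prepared
        if p.label is not PairLabel.UNKNOWN and not p.instance.degenerate
    ]
    if not labeled:
        raise ValueError("no labeled, non-degenerate pairs to train on")
    if len(labeled) < len(prepared):
        logger.warning(
            "%d of %d pairs unusable for training (unlabeled or degenerate)",
            len(prepared) - len(labeled), len(prepared),
        )
    params = _params_obj(kernel_kind, kernel_params)
    feats = featurize(labeled, kernel_kind, params)
    K = gram_fn(kernel_kind)(feats)
    clf = default_classifier(kernel_kind, params, clf_params)
    model = _train(
        clf, K, np.array([p.y for p in labeled]), [p.pair_id for p in labeled]
    )
    model.threshold = threshold
    return PipelineModel(
        fingerprint=make_fingerprint(
            kernel_kind, params, verbs, parser_backend, blind_others
        ),
        classifier=model,
        train_features=feats,
    )


@dataclass(frozen=True)
class PredictionRecord:
    doc_id: str
    sent_id: str
    pair_id: str
    compound_surface: str
    compound_norm_id: Optional[str]
    protein_surface: str
    protein_norm_id: Optional[str]
    score: Optional[float]
    predicted: Optional[int]  # +/-1; None for degenerate pairs
    encloses_verb: bool


def predict_corpus(
    model: PipelineModel,
    corpus: Corpus,
    *,
    verbs: Optional[frozenset[str]] = None,
    parser_backend: Optional[str] = None,
    allow_fixture_parses: bool = False,
) -> list[PredictionRecord]:
    """Score every candidate pair of a corpus at the model's threshold.

    The preprocessing fingerprint (verb list, parser backend, blinding,
    kernel parameters) must match the model's; mismatches are hard errors.
    The fixture chain parser is refused in prediction mode unless explicitly
    allowed, to prevent silently degraded graph-kernel predictions.
    """
    if verbs is None:
        verbs = default_interaction_verbs()
    fp = model.fingerprint
    backend = parser_backend if parser_backend is not None else fp["parser_backend"]
    if backend != fp["parser_backend"]:
        raise ValueError(
            f"parser backend {backend!r} does not match model fingerprint "
            f"{fp['parser_backend']!r}"
        )
    if verb_list_hash(verbs) != fp["verb_list_sha256"]:
        raise ValueError("interaction-verb list does not match model fingerprint")
    if backend == "fixture" and not allow_fixture_parses:
        raise ValueError(
            "refusing fixture parses in prediction mode "
            "(pass allow_fixture_parses=True to override)"
        )

    prepared = prepare_corpus(corpus, verbs, backend, fp["blind_others"])
    usable = [p for p in prepared if not p.instance.degenerate]
    scores: dict[str, float] = {}
    if usable:
        feats = featurize(usable, fp["kernel_kind"], fp["kernel_params"])
        K_cross = gram_fn(fp["kernel_kind"])(model.train_features, feats)
        values = classifiers.predict(model.classifier, K_cross)
        scores = {p.pair_id: float(v) for p, v in zip(usable, values)}

    sent_of = {}
    ent_of = {}
    for doc, sent in corpus.iter_sentences():
        for pair in sent.pairs:
            sent_of[pair.pair_id] = (doc.doc_id, sent.sent_id)
            ent_of[pair.pair_id] = (
                sent.entity_by_id(pair.compound_ref),
                sent.entity_by_id(pair.protein_ref),
            )

    records = []
    t = model.classifier.threshold
    for p in prepared:
        doc_id, sent_id = sent_of[p.pair_id]
        comp, prot = ent_of[p.pair_id]
        score = scores.get(p.pair_id)
        records.append(
            PredictionRecord(
                doc_id=doc_id,
                sent_id=sent_id,
                pair_id=p.pair_id,
                compound_surface=comp.surface,
                compound_norm_id=comp.norm_id,
                protein_surface=prot.surface,
                protein_norm_id=prot.norm_id,
                score=score,
                predicted=None if score is None else (1 if score > t else -1),
                encloses_verb=p.encloses_verb,
            )
        )
    return records
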