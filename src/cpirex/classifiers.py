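"""Binary classifiers on precomputed kernel matrices.

Two dual-form learners share one trained-model representation: a
soft-margin support-vector classifier (used with the shallow linguistic
kernel; libsvm via scikit-learn's precomputed-kernel interface) and a
regularized least squares (RLS) classifier (used with the all-paths graph
kernel), whose dual coefficients solve (K + lambda*I) a = y in closed form.

``dual_coefficients`` stores the *signed* weights, so prediction is uniform
for both kinds: score(x) = sum_i coef_i * k(x_i, x) + bias. The RLS
regularization is parameterized as lambda = 1/c so that a larger c means
weaker regularization (the direction of the evaluated c grid); the mapping
is explicit in ``rls_train`` and can be bypassed by passing lambda directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
from sklearn.svm import SVC


class TrainingError(ValueError):
    pass


@dataclass
class TrainedModel:
    kind: str  # "svc" | "rls"
    dual_coefficients: np.ndarray  # signed: alpha_i*y_i (svc) or a_i (rls)
    bias: float
    training_instance_ids: list[str]
    params: dict = field(default_factory=dict)
    threshold: float = 0.0

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "dual_coefficients": self.dual_coefficients.tolist(),
            "bias": self.bias,
            "training_instance_ids": list(self.training_instance_ids),
            "params": self.params,
            "threshold": self.threshold,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TrainedModel":
        return cls(
            kind=data["kind"],
            dual_coefficients=np.asarray(data["dual_coefficients"], dtype=float),
            bias=float(data["bias"]),
            training_instance_ids=list(data["training_instance_ids"]),
            params=dict(data["params"]),
            threshold=float(data["threshold"]),
        )


def _check_kernel(K: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise TrainingError("kernel matrix must be square")
    if not np.allclose(K, K.T, atol=1e-8):
        raise TrainingError("kernel matrix must be symmetric")
    if y.shape != (K.shape[0],):
        raise TrainingError("label vector length must match kernel dimension")
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise TrainingError("labels must be +/-1")
    return K, y


def svc_train(
    K: np.ndarray,
    y: Sequence[int],
    C: float = 1.0,
    instance_ids: Optional[Sequence[str]] = None,
) -> TrainedModel:
    """Soft-margin SVC on a precomputed kernel (libsvm dual solution).

    The returned coefficients are alpha_i * y_i with 0 <= alpha_i <= C and
    sum_i alpha_i y_i = 0; the decision score of an instance x is
    sum_i alpha_i y_i K(x_i, x) + bias.
    """
    K, y = _check_kernel(K, np.asarray(y))
    if len(set(y.tolist())) < 2:
        raise TrainingError("svc training requires both classes")
    svc = SVC(kernel="precomputed", C=C)
    svc.fit(K, y)
    coef = np.zeros(K.shape[0])
    coef[svc.support_] = svc.dual_coef_[0]
    ids = list(instance_ids) if instance_ids is not None else [
        str(i) for i in range(K.shape[0])
    ]
    return TrainedModel(
        kind="svc",
        dual_coefficients=coef,
        bias=float(svc.intercept_[0]),
        training_instance_ids=ids,
        params={"C": C},
    )


def rls_train(
    K: np.ndarray,
    y: Sequence[int],
    c: float = 0.25,
    instance_ids: Optional[Sequence[str]] = None,
    lam: Optional[float] = None,
) -> TrainedModel:
    """Regularized least squares: dual coefficients a = (K + lambda*I)^-1 y.

    ``lam`` defaults to 1/c; pass it explicitly to use a different mapping.
    Single-class label vectors are legal here (warned about upstream).
    """
    K, y = _check_kernel(K, np.asarray(y))
    if lam is None:
        lam = 1.0 / c
    if lam <= 0:
        raise TrainingError("regularization must be positive")
    a = scipy.linalg.solve(
        K + lam * np.eye(K.shape[0]), y, assume_a="sym"
    )
    ids = list(instance_ids) if instance_ids is not None else [
        str(i) for i in range(K.shape[0])
    ]
    return TrainedModel(
        kind="rls",
        dual_coefficients=a,
        bias=0.0,
        training_instance_ids=ids,
        params={"c": c, "lambda": lam},
    )


def predict(model: TrainedModel, K_cross: np.ndarray) -> np.ndarray:
    """Decision scores for test instances.

    ``K_cross[i, j] = k(train_i, test_j)``; scores are deterministic given
    the model and the cross-kernel block.
    """
    K_cross = np.atleast_2d(np.asarray(K_cross, dtype=float))
    if K_cross.shape[0] != len(model.training_instance_ids):
        raise ValueError(
            f"cross-kernel has {K_cross.shape[0]} rows, expected "
            f"{len(model.training_instance_ids)} training instances"
        )
    return model.dual_coefficients @ K_cross + model.bias


def threshold_labels(scores: Sequence[float], t: float = 0.0) -> np.ndarray:
    """+1 iff score > t (strict; ties are negative)."""
    return np.where(np.asarray(scores, dtype=float) > t, 1, -1)


def save_model(model: TrainedModel, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"format": "cpirex-model", "version": 1, **model.to_dict()}, fh)


def load_model(path: str) -> TrainedModel:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if data.get("format") != "cpirex-model":
        raise ValueError(f"{path} is not a cpirex model file")
    return TrainedModel.from_dict(data)
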