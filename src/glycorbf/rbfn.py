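"""Gaussian radial-basis-function network classifier.

Every training vector is a center (k hidden nodes for k training instances)
with one fixed bandwidth sigma (default 5).  Each of the two output nodes
computes a linear combination of the Gaussian activations

    c_j(x) = sum_i  w_ji * exp(-||x - mu_i||^2 / (2 sigma^2)),

and the weights solve the regularized least-squares problem
(Phi^T Phi + lambda I) W = Phi^T Y against one-hot class targets.  With
lambda = 0 and distinct training points the network interpolates its targets
exactly; fitting is deterministic linear algebra with no randomness.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = "glycorbf-rbfn-1"

#: Output-node order: column 0 scores the negative class, column 1 the positive.
CLASS_ORDER = ("negative", "positive")


def kernel(x: np.ndarray, center: np.ndarray, sigma: float) -> float:
    """Gaussian activation exp(-||x - center||^2 / (2 sigma^2)), in (0, 1]."""
    x = np.asarray(x, dtype=float)
    center = np.asarray(center, dtype=float)
    if x.shape != center.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {center.shape}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d2 = float(np.sum((x - center) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def _design_matrix(X: np.ndarray, centers: np.ndarray, sigma: float) -> np.ndarray:
    d2 = cdist(X, centers, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


@dataclass
class FeatureSchema:
    """What a feature vector means: window half-width and ordered SAAP list."""

    n: int
    saap_list: tuple = ()

    @property
    def length(self) -> int:
        return (2 * self.n + 1) * 21 + len(self.saap_list)


@dataclass
class RBFNModel:
    centers: np.ndarray  # k x d
    sigma: float
    ridge_lambda: float
    weights: np.ndarray  # k x 2, columns in CLASS_ORDER
    feature_schema: FeatureSchema | None = None

    def __post_init__(self) -> None:
        if self.centers.ndim != 2 or self.centers.shape[0] < 1:
            raise ValueError("centers must be a non-empty k x d matrix")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")


def _has_conflicting_duplicates(X: np.ndarray, y: np.ndarray) -> bool:
    seen: dict[bytes, bool] = {}
    for row, label in zip(X, y):
        key = row.tobytes()
        if key in seen and seen[key] != bool(label):
            return True
        seen[key] = bool(label)
    return False


def fit(
    train_vectors: Sequence[Sequence[float]] | np.ndarray,
    train_labels: Sequence[bool] | np.ndarray,
    sigma: float = 5.0,
    ridge_lambda: float = 0.0,
    feature_schema: FeatureSchema | None = None,
) -> RBFNModel:
    """Train an RBFN with all training vectors as centers.

    ``train_labels`` is boolean (True = positive).  Duplicate identical
    vectors carrying conflicting labels make the interpolation problem
    singular at lambda = 0; this is detected, logged, and resolved with an
    automatic fallback ridge of 1e-8.
    """
    X = np.asarray(train_vectors, dtype=float)
    y = np.asarray(train_labels, dtype=bool)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("train_vectors and train_labels disagree in length")
    if not np.all(np.isfinite(X)):
        raise ValueError("training vectors must be finite")
    if y.all() or not y.any():
        raise ValueError("need at least one instance of each class")
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be nonnegative")

    lam = ridge_lambda
    if lam == 0.0 and _has_conflicting_duplicates(X, y):
        logger.warning(
            "identical training vectors with conflicting labels make the "
            "interpolation singular; falling back to ridge lambda = 1e-8"
        )
        lam = 1e-8

    phi = _design_matrix(X, X, sigma)
    Y = np.zeros((X.shape[0], 2))
    Y[~y, 0] = 1.0
    Y[y, 1] = 1.0
    if lam == 0.0:
        W, *_ = scipy.linalg.lstsq(phi, Y)
    else:
        A = phi.T @ phi + lam * np.eye(phi.shape[0])
        W = scipy.linalg.solve(A, phi.T @ Y, assume_a="pos")
    return RBFNModel(
        centers=X,
        sigma=float(sigma),
        ridge_lambda=float(lam),
        weights=W,
        feature_schema=feature_schema,
    )


def predict_scores_batch(model: RBFNModel, X: np.ndarray) -> np.ndarray:
    """Output-node values for many inputs: rows of (score_neg, score_pos)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.centers.shape[1]:
        raise ValueError(
            f"input length {X.shape[1]} does not match model schema "
            f"length {model.centers.shape[1]}"
        )
    return _design_matrix(X, model.centers, model.sigma) @ model.weights


def predict_scores(model: RBFNModel, x: Sequence[float]) -> tuple[float, float]:
    """The two output-node values for one input: (score_positive, score_negative)."""
    out = predict_scores_batch(model, np.asarray(x, dtype=float)[None, :])[0]
    return float(out[1]), float(out[0])


def predict_class(
    model: RBFNModel, x: Sequence[float], threshold: float = 0.0
) -> str:
    """Class decision: positive iff score_positive - score_negative > threshold."""
    s_pos, s_neg = predict_scores(model, x)
    return "positive" if s_pos - s_neg > threshold else "negative"


def save_model(model: RBFNModel, path: str | Path) -> None:
    """Serialize a model to a portable JSON archive with a format version."""
    schema = model.feature_schema
    payload = {
        "format": MODEL_FORMAT_VERSION,
        "sigma": model.sigma,
        "ridge_lambda": model.ridge_lambda,
        "centers": model.centers.tolist(),
        "weights": model.weights.tolist(),
        "schema": None
        if schema is None
        else {
            "n": schema.n,
            "saaps": [
                {
                    "anchor_pos": s.anchor_pos,
                    "anchor_res": s.anchor_res,
                    "partner_pos": s.partner_pos,
                    "partner_set": list(s.partner_set),
                    "fscore": s.fscore,
                }
                for s in schema.saap_list
            ],
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path) -> RBFNModel:
    from .saap_discovery import SAAP

    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("format")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model archive format {version!r} does not match this package's "
            f"{MODEL_FORMAT_VERSION!r}"
        )
    schema = None
    if payload["schema"] is not None:
        saaps = tuple(
            SAAP(
                s["anchor_pos"],
                s["anchor_res"],
                s["partner_pos"],
                tuple(s["partner_set"]),
                s["fscore"],
            )
            for s in payload["schema"]["saaps"]
        )
        schema = FeatureSchema(n=payload["schema"]["n"], saap_list=saaps)
    return RBFNModel(
        centers=np.array(payload["centers"], dtype=float),
        sigma=payload["sigma"],
        ridge_lambda=payload["ridge_lambda"],
        weights=np.array(payload["weights"], dtype=float),
        feature_schema=schema,
    )
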