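"""Fusing per-ROI predictions into one mass-level decision.

Three parameter-free voting rules (majority, soft, max) treat every ROI
equally; stacked generalization instead trains a meta-classifier (SVM
with RBF/linear/polynomial kernel, or a random forest) on the vector of
per-ROI malignant probabilities, learning how much each ROI position
contributes.  The stack vector keeps only the malignant-class probability
per ROI — the benign one is redundant (p_benign = 1 - p_malignant) — and
its order follows the ROISet order, which is therefore part of the
contract.

Ties (equal class support) resolve to malignant: the decision rule is
"benign iff p_benign > p_malignant", which routes exact ties to the
positive class, the preferable failure mode in screening.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datatypes import Label

__all__ = [
    "majority_vote", "soft_vote", "max_vote",
    "fit_stacker", "predict_stacked", "STACKER_KINDS", "make_stacker",
]

STACKER_KINDS = ("svm_rbf", "svm_linear", "svm_poly", "random_forest")

#: CLI-style aliases for fusion rules.
FUSION_RULES = (
    "majority", "soft", "max",
    "stack-rbf", "stack-linear", "stack-poly", "stack-rf",
)

_ALIAS = {
    "stack-rbf": "svm_rbf",
    "stack-linear": "svm_linear",
    "stack-poly": "svm_poly",
    "stack-rf": "random_forest",
}


def _as_prob_array(probs: Sequence) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] == 0:
        raise ValueError(f"expected non-empty (n, 2) probability pairs, got {p.shape}")
    if (p < -1e-9).any() or (p > 1 + 1e-9).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return p


def majority_vote(labels: Sequence[int]) -> Label:
    """Label with strictly more votes; ties go to malignant."""
    arr = np.asarray([int(v) for v in labels])
    if arr.size == 0:
        raise ValueError("cannot vote on an empty label sequence")
    n_malig = int((arr == Label.MALIGNANT).sum())
    n_benign = arr.size - n_malig
    return Label.BENIGN if n_benign > n_malig else Label.MALIGNANT


def soft_vote(probs: Sequence) -> tuple[Label, np.ndarray]:
    """Average the per-ROI probability pairs; benign iff its average is
    strictly larger.  Returns (label, averaged pair)."""
    p = _as_prob_array(probs)
    mean = p.mean(axis=0)
    label = Label.BENIGN if mean[0] > mean[1] else Label.MALIGNANT
    return label, mean


def max_vote(probs: Sequence) -> tuple[Label, np.ndarray]:
    """Per-class maxima over ROIs; benign iff its maximum is strictly
    larger.  Returns (label, pair of maxima)."""
    p = _as_prob_array(probs)
    mx = p.max(axis=0)
    label = Label.BENIGN if mx[0] > mx[1] else Label.MALIGNANT
    return label, mx


def vote(rule: str, probs: Sequence) -> Label:
    """Apply a named voting rule to (n, 2) probability pairs."""
    if rule == "majority":
        p = _as_prob_array(probs)
        return majority_vote((p[:, 1] >= p[:, 0]).astype(int))
    if rule == "soft":
        return soft_vote(probs)[0]
    if rule == "max":
        return max_vote(probs)[0]
    raise ValueError(f"unknown voting rule {rule!r}")


def make_stacker(kind: str, seed: int = 0, C: float = 1.0, degree: int = 3):
    """Untrained meta-classifier pipeline (feature standardization + model)."""
    kind = _ALIAS.get(kind, kind)
    if kind == "random_forest":
        clf = RandomForestClassifier(n_estimators=100, random_state=seed)
    elif kind in ("svm_rbf", "svm_linear", "svm_poly"):
        kernel = kind.split("_", 1)[1]
        clf = SVC(
            kernel=kernel, C=C, degree=degree, gamma="scale",
            probability=True, random_state=seed,
        )
    else:
        raise ValueError(f"unknown stacker kind {kind!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _as_stack_matrix(vectors: Sequence) -> np.ndarray:
    x = np.asarray(vectors, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError(f"expected (n_samples, n_rois) stack vectors, got {x.shape}")
    if (x < -1e-9).any() or (x > 1 + 1e-9).any():
        raise ValueError("stack-vector entries must be probabilities in [0, 1]")
    return x


def fit_stacker(
    vectors: Sequence, labels: Sequence[int], kind: str = "svm_rbf", seed: int = 0
):
    """Train the stacking meta-classifier on per-ROI malignant-probability
    vectors (ROISet order) from the training + validation regions."""
    x = _as_stack_matrix(vectors)
    y = np.asarray([int(v) for v in labels])
    if np.unique(y).size < 2:
        raise ValueError("stacker training needs both classes")
    if np.bincount(y, minlength=2).min() < 2:
        raise ValueError("stacker training needs >= 2 samples per class")
    model = make_stacker(kind, seed=seed)
    model.fit(x, y)
    model.n_features_ = x.shape[1]
    return model


def predict_stacked(model, vectors: Sequence) -> np.ndarray:
    """Labels (0/1 array) for one or more stack vectors."""
    x = np.asarray(vectors, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    expected = getattr(model, "n_features_", x.shape[1])
    if x.shape[1] != expected:
        raise ValueError(
            f"stack vector length {x.shape[1]} does not match training length {expected}"
        )
    pred = model.predict(x)
    return pred[0] if single else pred
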