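"""The context-ensemble mass classifier as a scikit-learn estimator.

``ContextEnsembleClassifier`` wires the whole method together: augmented
fine-tuning of one CNN backbone, test-time extraction of several
context-diverse ROIs per mass, per-ROI scoring by the backbone, and
fusion of the per-ROI probabilities into one benign/malignant decision
(voting or SVM/random-forest stacking).

``X`` is a sequence of :class:`~masscontext.datatypes.MassRegion`; ``y``
defaults to the labels carried by the regions.  The estimator follows
scikit-learn conventions (``get_params``/``set_params``, fitted
attributes with trailing underscores, ``classes_``) and composes with
sklearn model-selection tooling.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from . import backbone as bb
from .augmentation import AugmentationPlan, build_training_set
from .datatypes import Label, MassRegion, ROISet, as_labels
from .enhancement import EnhancementConfig, enhance
from .fusion import FUSION_RULES, fit_stacker, predict_stacked, vote
from .roi_context import extract_rois, n_rois

_VOTING = ("majority", "soft", "max")
_STACKING = ("stack-rbf", "stack-linear", "stack-poly", "stack-rf")


class ContextEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Benign/malignant mass classifier with test-time context ensembling.

    Parameters
    ----------
    scheme : str
        Test-time ROI extraction scheme: ``"single"``, ``"MS1"``/``"MS2"``/
        ``"MS3"`` (scale-based) or ``"MC1"``/``"MC2"`` (translation-based;
        MC2 is the 11-ROI scheme and the recommended default).
    variant : str
        Backbone: ``"base"`` (ResNet-50), ``"DI"``–``"DIV"`` (density-
        specific variants) or ``"tiny"`` (reduced-depth, CPU-friendly).
    fusion : str
        ``"none"`` (argmax of the first ROI), ``"majority"``, ``"soft"``,
        ``"max"``, or ``"stack-rbf"``/``"stack-linear"``/``"stack-poly"``/
        ``"stack-rf"``.
    enhancement : EnhancementConfig or None
        Contrast enhancement applied to every ROI (train and test).
        ``None`` disables it.
    augmentation_plan : AugmentationPlan or None
        Training-set augmentation; ``None`` uses the default plan
        (10-px sliding windows, 4 rotations x flips, 5%/10% expansions).
    learning_rate : float or None
        ``None`` selects 1e-4 for the deep variants (a fine-tuning rate)
        and 1e-2 for ``tiny`` (trained from scratch).
    epochs, patience, batch_size, momentum, validation_fraction
        Backbone training schedule; the validation split (stratified,
        90:10 by default) controls early stopping and supplies extra
        stacker training data.
    random_state : int
        Seed for every stochastic component.
    """

    def __init__(
        self,
        scheme: str = "MC2",
        variant: str = "tiny",
        fusion: str = "stack-rbf",
        enhancement: Optional[EnhancementConfig] = None,
        augmentation_plan: Optional[AugmentationPlan] = None,
        learning_rate: Optional[float] = None,
        momentum: float = 0.9,
        batch_size: int = 64,
        epochs: int = 10,
        patience: int = 5,
        validation_fraction: float = 0.10,
        random_state: int = 0,
    ) -> None:
        self.scheme = scheme
        self.variant = variant
        self.fusion = fusion
        self.enhancement = enhancement
        self.augmentation_plan = augmentation_plan
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- configuration ---------------------------------------------------
    def _validate_config(self) -> None:
        if self.fusion not in FUSION_RULES + ("none",):
            raise ValueError(f"unknown fusion rule {self.fusion!r}")
        if self.scheme == "single" and self.fusion != "none":
            raise ValueError(
                "scheme 'single' yields one ROI; fusion requires more than "
                "one (use fusion='none')"
            )
        n_rois(self.scheme)  # raises on unknown scheme

    def _input_channels(self) -> int:
        return 1 if self.variant == "tiny" else 3

    def _lr(self) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return 1e-2 if self.variant == "tiny" else 1e-4

    # -- ROI plumbing ----------------------------------------------------
    def _region_rois(self, region: MassRegion) -> ROISet:
        rois = extract_rois(region, self.scheme)
        if self.enhancement is not None and self.enhancement.enabled:
            for r in rois:
                r.pixels = enhance(r.pixels, self.enhancement)
        return rois

    def _roi_prob_matrix(self, regions: Sequence[MassRegion]) -> np.ndarray:
        """(n_regions, n_rois, 2) per-ROI probabilities, ROISet order."""
        stacks = [self._region_rois(r).pixel_stack() for r in regions]
        flat = np.concatenate(stacks, axis=0)
        probs = bb.predict_proba(self.backbone_, flat, batch_size=self.batch_size)
        k = stacks[0].shape[0]
        return probs.reshape(len(regions), k, 2)

    # -- sklearn API -----------------------------------------------------
    def fit(self, X: Sequence[MassRegion], y=None) -> "ContextEnsembleClassifier":
        self._validate_config()
        regions = list(X)
        if not regions:
            raise ValueError("no training regions")
        if y is None:
            if any(r.label is None for r in regions):
                raise ValueError("unlabeled region and no y given")
            y = [int(r.label) for r in regions]
        y = as_labels(y)
        if np.unique(y).size < 2:
            raise ValueError("training data must contain both classes")

        # region-level 90:10 train/validation split
        idx_train, idx_val = train_test_split(
            np.arange(len(regions)),
            test_size=self.validation_fraction,
            stratify=y,
            random_state=self.random_state,
        )
        train_regions = [regions[i] for i in idx_train]
        val_regions = [regions[i] for i in idx_val]

        # backbone fine-tuning on augmented training ROIs; the validation
        # regions' test-time ROI sets control early stopping
        plan = self.augmentation_plan or AugmentationPlan(seed=self.random_state)
        labeled = [
            r if r.label is not None else _with_label(r, int(yy))
            for r, yy in zip(train_regions, y[idx_train])
        ]
        samples = build_training_set(labeled, plan)
        x_aug = np.stack(
            [self._maybe_enhance(s.roi.pixels) for s in samples]
        ).astype(np.float32)
        y_aug = np.array([s.label for s in samples])

        val_stack = np.concatenate(
            [self._region_rois(r).pixel_stack() for r in val_regions], axis=0
        ).astype(np.float32)
        val_labels = np.repeat(y[idx_val], n_rois(self.scheme))

        self.arch_spec_, self.backbone_ = bb.build_backbone(
            self.variant, seed=self.random_state,
            input_channels=self._input_channels(),
        )
        cfg = bb.TrainConfig(
            learning_rate=self._lr(), momentum=self.momentum,
            batch_size=self.batch_size, epochs=self.epochs,
            patience=self.patience,
            validation_fraction=self.validation_fraction,
            seed=self.random_state,
        )
        self.train_log_ = bb.finetune(
            self.backbone_, x_aug, y_aug, cfg, validation=(val_stack, val_labels)
        )

        # stacker fitted on backbone predictions over train+val regions
        self.stacker_ = None
        if self.fusion in _STACKING:
            stack_regions = train_regions + val_regions
            stack_y = np.concatenate([y[idx_train], y[idx_val]])
            mat = self._roi_prob_matrix(stack_regions)
            self.stacker_ = fit_stacker(
                mat[:, :, 1], stack_y, kind=self.fusion, seed=self.random_state
            )
        self.classes_ = np.array([0, 1])
        self.n_rois_ = n_rois(self.scheme)
        return self

    def _maybe_enhance(self, pixels: np.ndarray) -> np.ndarray:
        if self.enhancement is not None and self.enhancement.enabled:
            return enhance(pixels, self.enhancement)
        return np.asarray(pixels, dtype=float)

    def predict_proba(self, X: Sequence[MassRegion]) -> np.ndarray:
        """Fused (benign, malignant) probability per region.

        Soft voting returns the averaged pair; majority voting the vote
        shares; max voting the renormalized per-class maxima; stacking the
        meta-classifier's probabilities.
        """
        self._check_fitted()
        regions = list(X)
        if not regions:
            raise ValueError("no regions to predict")
        mat = self._roi_prob_matrix(regions)
        out = np.empty((len(regions), 2))
        if self.fusion in _STACKING:
            out[:] = self.stacker_.predict_proba(mat[:, :, 1])
        elif self.fusion == "soft":
            out[:] = mat.mean(axis=1)
        elif self.fusion == "max":
            mx = mat.max(axis=1)
            out[:] = mx / mx.sum(axis=1, keepdims=True)
        elif self.fusion == "majority":
            votes = (mat[:, :, 1] >= mat[:, :, 0]).mean(axis=1)
            out[:, 1] = votes
            out[:, 0] = 1 - votes
        else:  # "none"
            out[:] = mat[:, 0, :]
        return out

    def predict(self, X: Sequence[MassRegion]) -> np.ndarray:
        """Fused 0/1 labels (ties resolve to malignant)."""
        self._check_fitted()
        regions = list(X)
        mat = self._roi_prob_matrix(regions)
        if self.fusion in _STACKING:
            return predict_stacked(self.stacker_, mat[:, :, 1])
        if self.fusion in _VOTING:
            return np.array(
                [int(vote(self.fusion, mat[i])) for i in range(len(regions))]
            )
        return (mat[:, 0, 1] >= mat[:, 0, 0]).astype(int)

    def score(self, X: Sequence[MassRegion], y=None) -> float:
        regions = list(X)
        if y is None:
            y = [int(r.label) for r in regions]
        return float((self.predict(regions) == as_labels(y)).mean())

    def roi_probabilities(self, X: Sequence[MassRegion]) -> np.ndarray:
        """Audit hook: raw per-ROI probabilities ``(n, n_rois, 2)``."""
        self._check_fitted()
        return self._roi_prob_matrix(list(X))

    def _check_fitted(self) -> None:
        if not hasattr(self, "backbone_"):
            raise RuntimeError("estimator is not fitted")


def _with_label(region: MassRegion, label: int) -> MassRegion:
    return MassRegion(
        image=region.image, bbox=region.bbox, label=Label(label),
        density=region.density, region_id=region.region_id,
    )
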