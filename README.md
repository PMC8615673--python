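# masscontext

Benign/malignant classification of segmented mammographic masses by
**fusing one CNN's predictions over multiple context-diverse ROIs** of
the same lesion.

Masses are an early mammographic sign of breast cancer, and telling
benign from malignant ones is hard: both share texture patterns, and a
single-crop CNN decision is sensitive to exactly how the crop around
the lesion was taken. This package implements a context-ensemble
classifier for researchers in computer-aided mammography: instead of
training many networks, it extracts several ROIs of one mass with
differing amounts of surrounding tissue, scores each with a single
backbone (ResNet-50 or one of four breast-density-specific variants),
and fuses the per-ROI probabilities — by majority/soft/max voting or by
stacked generalization with an SVM meta-classifier — into one decision.

Core ingredients:

* **ROI schemes** — scale-based (bbox expanded by `p%` per edge over a
  scale set) and translation-based (isotropic rescale of the crop to a
  256-px smaller side, then corner/center 224×224 windows plus
  horizontal flips plus the whole crop: 11 ROIs).
* **Backbones** — bottleneck ResNet-50 with a 2-neuron head, and the
  density-specific variants DI–DIV that perform surgery on the last
  residual block and fuse GAP/GMP and projection-shortcut features so
  exactly 2048 channels enter the classifier. Architectures are
  declarative graphs with validated channel contracts, executed by a
  compact NumPy NN engine (forward + backprop); a reduced-depth
  `tiny` backbone trains from scratch in CPU-minutes.
* **Fusion** — majority vote, soft vote (per-class means), max vote
  (per-class maxima), each with the rule *benign iff p₁ > p₂* (ties →
  malignant), or stacking: the vector of per-ROI malignant
  probabilities fed to an SVM (RBF/linear/poly) or random forest.
* **Metrics** — sensitivity, specificity, accuracy, Cohen's kappa
  `(Po−Pe)/(1−Pe)`, F1 and trapezoidal AUC, with malignant the
  positive class, plus a reconstruction tool that inverts printed
  Sen/Spe percentages and class counts back to the integer confusion
  matrix for auditing published result rows.
* **Synthetic phantoms** — textured backgrounds with one inserted
  lesion (smooth sharp-margined ellipses vs blurred spiculated blobs),
  so every stage runs and is tested without downloading any dataset.

See `docs/methods.md` for the model details and design conventions.

## Worked example

```python
import numpy as np
from masscontext import ContextEnsembleClassifier
from masscontext.augmentation import AugmentationPlan
from masscontext.metrics import compute_metrics, confusion_from_predictions, roc_auc
from masscontext.synthetic import SyntheticConfig, generate_dataset

ds = generate_dataset(SyntheticConfig(n_per_class=40, seed=42))
plan = AugmentationPlan(stride=20, angles=(0, 180), scale_percents=(5, 10), seed=42)
clf = ContextEnsembleClassifier(scheme="MC2", variant="tiny", fusion="stack-rbf",
                                augmentation_plan=plan, epochs=8, random_state=42)
clf.fit(ds.train)

y = np.array([int(r.label) for r in ds.test])
pred = clf.predict(ds.test)
report = compute_metrics(confusion_from_predictions(y, pred))
report.auc = roc_auc(clf.predict_proba(ds.test)[:, 1], y)
```

Output (a few CPU-minutes; all numbers are percentages except AUC):

```
test regions: 24
sensitivity: 100.0
specificity: 100.0
accuracy:    100.0
kappa:       100.0
f1:          100.0
auc:         1.0
```

The phantom classes are separable by construction (margin sharpness and
spiculation), so a perfect score on this small set says the ensemble
machinery — 11-ROI extraction, backbone training, stacked fusion — is
wired correctly, not that clinical performance would be perfect.

The same flow is available from the shell:

```bash
masscontext generate-synthetic --out data --n-per-class 40 --seed 42
masscontext train --manifest data/train/manifest.csv --out bundle --scheme MC2 --fusion stack-rbf
masscontext eval --bundle bundle --manifest data/test/manifest.csv --out results
```

Auditing a published-style result row from its printed sensitivity,
specificity and class counts:

```bash
$ masscontext reconstruct-table --n-malignant 132 --n-benign 182 \
      --sensitivity 99.24 --specificity 87.36
{
 "tp": 131, "fn": 1, "tn": 159, "fp": 23,
 "accuracy": 92.36, "kappa": 84.67, "f1": 91.61, ...
}
```

## Real data

`masscontext` reads PNG or DICOM images with a CSV manifest
(`image_path, row_min, col_min, row_max, col_max, label, density`);
bounding boxes are 0-based half-open pixel intervals. Benchmarks on
CBIS-DDSM/INbreast additionally require the datasets themselves and
ImageNet-pretrained weights, which are not bundled.
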