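"""Backbone CNNs: ResNet-50 and its four density-specific variants.

The base backbone is a standard 5-group bottleneck ResNet-50 whose
1000-way classifier is replaced by a 2-neuron benign/malignant head.  The
density-specific variants (``DI``–``DIV``, one per BI-RADS density class)
perform surgery on the last bottleneck of group 5 and fuse local and
global features so that exactly 2048 channels enter the classifier, the
same width as the base model:

* **DI** — drop the last block's final 1x1 conv (and its ReLU and the
  identity shortcut) so the block ends at 512 channels; pool those with
  GAP and GMP in parallel (512+512) and concatenate a projection shortcut
  taken from the first group-5 block's ReLU through a 1x1 conv with 1024
  filters and a 7x7 max pool (1024).  512+512+1024 = 2048.
* **DII** — replace the final 1x1 conv with 1024 filters, drop the
  shortcut; GAP (1024) in parallel with a projection block (1x1 conv,
  1024 filters, then 7x7 max pool; 1024).  1024+1024 = 2048.
* **DIII** — replace the final 1x1 conv with 512 filters, drop the
  shortcut; GAP ∥ GMP (512+512) plus a projection from group-4 block-6's
  ReLU through a 1x1 conv (1024 filters) and a 14x14 max pool (1024).
* **DIV** — replace the final 1x1 conv with 1024 filters, drop the
  shortcut; GAP ∥ GMP after the block ReLU (1024+1024).

A reduced-depth ``tiny`` variant with the same input contract is provided
for CPU-scale training experiments.

Grayscale ROIs are replicated to the 3 input channels expected by
ImageNet-style models (a 1-channel first conv is available via
``input_channels=1`` for from-scratch work).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ROI_SIZE, ROISet
from .nn.graph import ArchSpec, GraphModel, LayerSpec
from .nn.train import SGD, softmax, softmax_cross_entropy

VARIANTS = ("base", "DI", "DII", "DIII", "DIV", "tiny")

#: (n_blocks, mid_channels, out_channels, first_stride) for groups G2..G5.
_GROUPS = (
    (3, 64, 256, 1),
    (4, 128, 512, 2),
    (6, 256, 1024, 2),
    (3, 512, 2048, 2),
)


def _conv_bn(
    layers: list[LayerSpec],
    name: str,
    inp: str,
    in_ch: int,
    out_ch: int,
    kernel: int,
    stride: int = 1,
    pad: int = 0,
) -> str:
    """Conv block = convolution + batch norm; returns the BN node name."""
    layers.append(
        LayerSpec(
            name, "conv", [inp],
            {"in_channels": in_ch, "out_channels": out_ch, "kernel": kernel,
             "stride": stride, "pad": pad},
            out_channels=out_ch,
        )
    )
    layers.append(
        LayerSpec(f"{name}_bn", "bn", [name], {"channels": out_ch}, out_channels=out_ch)
    )
    return f"{name}_bn"


def _relu(layers: list[LayerSpec], name: str, inp: str) -> str:
    layers.append(LayerSpec(name, "relu", [inp]))
    return name


def _bottleneck(
    layers: list[LayerSpec],
    name: str,
    inp: str,
    in_ch: int,
    mid: int,
    out_ch: int,
    stride: int,
    project: bool,
) -> str:
    """Standard bottleneck: 1x1 -> 3x3 -> 1x1 with identity or projection
    shortcut; returns the block's final ReLU node."""
    x = _conv_bn(layers, f"{name}_c1", inp, in_ch, mid, 1)
    x = _relu(layers, f"{name}_relu1", x)
    x = _conv_bn(layers, f"{name}_c2", x, mid, mid, 3, stride=stride, pad=1)
    x = _relu(layers, f"{name}_relu2", x)
    x = _conv_bn(layers, f"{name}_c3", x, mid, out_ch, 1)
    if project:
        sc = _conv_bn(layers, f"{name}_proj", inp, in_ch, out_ch, 1, stride=stride)
    else:
        sc = inp
    layers.append(LayerSpec(f"{name}_add", "add", [x, sc], out_channels=out_ch))
    return _relu(layers, f"{name}_relu", f"{name}_add")


def _trunk(input_channels: int) -> tuple[list[LayerSpec], str, int]:
    """Input through group 5 block 2 (the part shared by every variant).

    Returns (layers, name of g5b2's ReLU, its channel count)."""
    layers: list[LayerSpec] = [LayerSpec("input", "input")]
    x = _conv_bn(layers, "g1", "input", input_channels, 64, 7, stride=2, pad=3)
    x = _relu(layers, "g1_relu", x)
    layers.append(
        LayerSpec("g2_pool", "maxpool", [x], {"kernel": 3, "stride": 2, "pad": 1})
    )
    x = "g2_pool"
    in_ch = 64
    for gi, (n_blocks, mid, out_ch, stride) in enumerate(_GROUPS, start=2):
        for b in range(1, n_blocks + 1):
            last_of_g5 = gi == 5 and b == 3
            if last_of_g5:
                break
            x = _bottleneck(
                layers, f"g{gi}b{b}", x, in_ch, mid, out_ch,
                stride=stride if b == 1 else 1, project=b == 1,
            )
            in_ch = out_ch
    return layers, x, in_ch


def _head(layers: list[LayerSpec], inp: str, width: int, num_classes: int) -> None:
    layers.append(
        LayerSpec("fc", "fc", [inp],
                  {"in_features": width, "out_features": num_classes},
                  out_channels=num_classes)
    )


def build_arch_spec(
    variant: str, input_channels: int = 3, num_classes: int = 2
) -> ArchSpec:
    """Declarative graph for one backbone variant (validated)."""
    if variant == "tiny":
        return _tiny_spec(input_channels, num_classes)
    if variant not in VARIANTS:
        raise ValueError(f"unknown backbone variant {variant!r}")

    layers, x, in_ch = _trunk(input_channels)  # x = g5b2_relu, 2048 ch

    if variant == "base":
        x = _bottleneck(layers, "g5b3", x, 2048, 512, 2048, stride=1, project=False)
        layers.append(LayerSpec("gap", "gap", [x], out_channels=2048))
        _head(layers, "gap", 2048, num_classes)
        return ArchSpec(variant, layers, 2048, num_classes, input_channels)

    # shared prefix of the modified last block: 1x1(512) -> 3x3(512)
    c1 = _conv_bn(layers, "g5b3_c1", x, 2048, 512, 1)
    r1 = _relu(layers, "g5b3_relu1", c1)
    c2 = _conv_bn(layers, "g5b3_c2", r1, 512, 512, 3, pad=1)
    r2 = _relu(layers, "g5b3_relu2", c2)

    if variant == "DI":
        # final conv, its ReLU and the shortcut removed: block ends at 512 ch
        layers.append(LayerSpec("gap", "gap", [r2], out_channels=512))
        layers.append(LayerSpec("gmp", "gmp", [r2], out_channels=512))
        p = _conv_bn(layers, "proj", "g5b1_relu", 2048, 1024, 1)
        layers.append(
            LayerSpec("proj_pool", "maxpool", [p], {"kernel": 7}, out_channels=1024)
        )
        layers.append(
            LayerSpec("cat", "concat", ["gap", "gmp", "proj_pool"], out_channels=2048)
        )
    elif variant == "DII":
        c3 = _conv_bn(layers, "g5b3_c3", r2, 512, 1024, 1)
        r3 = _relu(layers, "g5b3_relu", c3)
        layers.append(LayerSpec("gap", "gap", [r3], out_channels=1024))
        p = _conv_bn(layers, "proj", r3, 1024, 1024, 1)
        layers.append(
            LayerSpec("proj_pool", "maxpool", [p], {"kernel": 7}, out_channels=1024)
        )
        layers.append(
            LayerSpec("cat", "concat", ["gap", "proj_pool"], out_channels=2048)
        )
    elif variant == "DIII":
        c3 = _conv_bn(layers, "g5b3_c3", r2, 512, 512, 1)
        r3 = _relu(layers, "g5b3_relu", c3)
        layers.append(LayerSpec("gap", "gap", [r3], out_channels=512))
        layers.append(LayerSpec("gmp", "gmp", [r3], out_channels=512))
        p = _conv_bn(layers, "proj", "g4b6_relu", 1024, 1024, 1)
        layers.append(
            LayerSpec("proj_pool", "maxpool", [p], {"kernel": 14}, out_channels=1024)
        )
        layers.append(
            LayerSpec("cat", "concat", ["gap", "gmp", "proj_pool"], out_channels=2048)
        )
    elif variant == "DIV":
        c3 = _conv_bn(layers, "g5b3_c3", r2, 512, 1024, 1)
        r3 = _relu(layers, "g5b3_relu", c3)
        layers.append(LayerSpec("gap", "gap", [r3], out_channels=1024))
        layers.append(LayerSpec("gmp", "gmp", [r3], out_channels=1024))
        layers.append(LayerSpec("cat", "concat", ["gap", "gmp"], out_channels=2048))

    _head(layers, "cat", 2048, num_classes)
    return ArchSpec(variant, layers, 2048, num_classes, input_channels)


def _tiny_spec(input_channels: int, num_classes: int) -> ArchSpec:
    """Reduced-depth backbone for CPU-scale training; same 224x224 input
    contract, GAP ∥ GMP head in the spirit of the density variants."""
    layers: list[LayerSpec] = [LayerSpec("input", "input")]
    x = _conv_bn(layers, "c1", "input", input_channels, 8, 7, stride=4, pad=3)
    x = _relu(layers, "relu1", x)
    layers.append(LayerSpec("pool1", "maxpool", [x], {"kernel": 2}))
    x = _conv_bn(layers, "c2", "pool1", 8, 16, 3, stride=2, pad=1)
    x = _relu(layers, "relu2", x)
    layers.append(LayerSpec("gap", "gap", [x], out_channels=16))
    layers.append(LayerSpec("gmp", "gmp", [x], out_channels=16))
    layers.append(LayerSpec("cat", "concat", ["gap", "gmp"], out_channels=32))
    _head(layers, "cat", 32, num_classes)
    return ArchSpec("tiny", layers, 32, num_classes, input_channels)


def build_backbone(
    variant: str, seed: int = 0, input_channels: int = 3, num_classes: int = 2
) -> tuple[ArchSpec, GraphModel]:
    """Build and materialize a backbone with He-initialized weights."""
    spec = build_arch_spec(variant, input_channels, num_classes)
    return spec, GraphModel(spec, seed=seed)


# ---------------------------------------------------------------------------
# inference and fine-tuning
# ---------------------------------------------------------------------------

def preprocess_rois(pixel_stack: np.ndarray, input_channels: int = 3) -> np.ndarray:
    """Standardize each ROI to zero mean / unit variance and replicate the
    grayscale plane across the model's input channels."""
    x = np.asarray(pixel_stack, dtype=np.float32)
    if x.ndim != 3 or x.shape[1:] != (ROI_SIZE, ROI_SIZE):
        raise ValueError(
            f"expected stack of {ROI_SIZE}x{ROI_SIZE} ROIs, got {x.shape}"
        )
    mean = x.mean(axis=(1, 2), keepdims=True)
    std = x.std(axis=(1, 2), keepdims=True)
    x = (x - mean) / (std + 1e-6)
    return np.repeat(x[:, None, :, :], input_channels, axis=1)


def predict_proba(
    model: GraphModel, rois: ROISet | np.ndarray, batch_size: int = 8
) -> np.ndarray:
    """Per-ROI class probabilities ``(n, 2)`` in ROISet order."""
    stack = rois.pixel_stack() if isinstance(rois, ROISet) else np.asarray(rois)
    if stack.size == 0:
        raise ValueError("empty ROI set")
    x = preprocess_rois(stack, model.spec.input_channels)
    return softmax(model.predict_logits(x, batch_size=batch_size))


@dataclass
class TrainConfig:
    """Fine-tuning configuration (SGD with momentum)."""

    learning_rate: float = 1e-4
    momentum: float = 0.9
    batch_size: int = 64
    epochs: int = 30
    patience: int = 5
    validation_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if min(self.learning_rate, self.momentum, self.batch_size) < 0:
            raise ValueError("training hyper-parameters must be non-negative")


@dataclass
class TrainingLog:
    """Per-epoch record of the fine-tuning run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1


def finetune(
    model: GraphModel,
    pixels: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig | None = None,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainingLog:
    """Fine-tune ``model`` on a stack of labeled 224x224 ROIs.

    Unless an explicit ``validation`` (pixels, labels) pair is given, the
    data are split 90:10 into train/validation stratified by label; the
    parameters of the best-validation-loss epoch are restored at the end.
    With ``epochs=0`` the model is returned untouched.  Fully
    deterministic for a fixed config seed.
    """
    from sklearn.model_selection import train_test_split

    config = config or TrainConfig()
    labels = np.asarray(labels, dtype=int)
    if pixels.shape[0] != labels.shape[0]:
        raise ValueError("pixels and labels disagree in length")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")

    log = TrainingLog()
    if config.epochs == 0:
        return log

    x = preprocess_rois(pixels, model.spec.input_channels)
    if validation is not None:
        x_train, y_train = x, labels
        x_val = preprocess_rois(validation[0], model.spec.input_channels)
        y_val = np.asarray(validation[1], dtype=int)
    else:
        idx_train, idx_val = train_test_split(
            np.arange(labels.size),
            test_size=config.validation_fraction,
            stratify=labels,
            random_state=config.seed,
        )
        x_train, y_train = x[idx_train], labels[idx_train]
        x_val, y_val = x[idx_val], labels[idx_val]

    rng = np.random.default_rng(config.seed)
    opt = SGD(model.parameters(), lr=config.learning_rate, momentum=config.momentum)
    best_state, best_val = None, np.inf

    for epoch in range(config.epochs):
        order = rng.permutation(x_train.shape[0])
        losses = []
        for i in range(0, order.size, config.batch_size):
            batch = order[i : i + config.batch_size]
            logits = model.forward(x_train[batch], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y_train[batch])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_logits = model.predict_logits(x_val, batch_size=config.batch_size)
        val_loss, _ = softmax_cross_entropy(val_logits, y_val)
        val_acc = float((val_logits.argmax(axis=1) == y_val).mean())
        log.train_loss.append(float(np.mean(losses)))
        log.val_loss.append(val_loss)
        log.val_accuracy.append(val_acc)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            log.best_epoch = epoch
        elif epoch - log.best_epoch >= config.patience:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    return log


def save_model(path, model: GraphModel) -> None:
    """Serialize weights (npz) next to a JSON graph sidecar."""
    import os

    np.savez_compressed(path, **model.state_dict())
    side = os.fspath(path)
    side = side[: -len(".npz")] if side.endswith(".npz") else side
    with open(side + ".archspec.json", "w") as fh:
        fh.write(model.spec.to_json())


def load_model(path) -> GraphModel:
    import os

    side = os.fspath(path)
    side = side[: -len(".npz")] if side.endswith(".npz") else side
    with open(side + ".archspec.json") as fh:
        spec = ArchSpec.from_json(fh.read())
    model = GraphModel(spec, seed=0)
    with np.load(os.fspath(path)) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
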