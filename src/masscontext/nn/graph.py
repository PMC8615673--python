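"""Declarative network graphs with channel contracts.

An :class:`ArchSpec` is a pure-data description of a directed acyclic
computational graph: each :class:`LayerSpec` names its operation, its
hyper-parameters and its input layers.  The spec can be validated (acyclic,
channel arithmetic consistent with each node's declared output channels)
and serialized to JSON without instantiating any weights; a
:class:`GraphModel` materializes it into the layers of
:mod:`masscontext.nn.layers` and runs forward/backward passes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any, Optional

import numpy as np

from . import layers as L

_KINDS = {
    "input", "conv", "bn", "relu", "maxpool", "gap", "gmp",
    "fc", "add", "concat",
}


@dataclass
class LayerSpec:
    """One node of the graph: operation kind, inputs, hyper-parameters."""

    name: str
    kind: str
    inputs: list[str] = field(default_factory=list)
    params: dict[str, Any] = field(default_factory=dict)
    out_channels: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r} in {self.name!r}")


@dataclass
class ArchSpec:
    """A named backbone architecture as a validated DAG of layer specs."""

    variant: str
    layers: list[LayerSpec]
    feature_width: int
    num_classes: int = 2
    input_channels: int = 3
    input_size: int = 224

    def __post_init__(self) -> None:
        self._by_name = {l.name: l for l in self.layers}
        if len(self._by_name) != len(self.layers):
            raise ValueError("duplicate layer names")

    def topo_order(self) -> list[LayerSpec]:
        """Topological order; raises on cycles or dangling references."""
        order: list[LayerSpec] = []
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(name: str) -> None:
            if name not in self._by_name:
                raise ValueError(f"unknown layer reference {name!r}")
            s = state.get(name)
            if s == 1:
                return
            if s == 0:
                raise ValueError(f"cycle through {name!r}")
            state[name] = 0
            for parent in self._by_name[name].inputs:
                visit(parent)
            state[name] = 1
            order.append(self._by_name[name])

        for l in self.layers:
            visit(l.name)
        return order

    def propagate_channels(self) -> dict[str, int]:
        """Infer every node's channel count and check declared contracts.

        ``concat`` sums its inputs, ``add`` requires equal inputs, ``conv``
        and ``fc`` set the count from their filters/features; everything
        else passes channels through.  Raises on any mismatch with a
        declared ``out_channels``.
        """
        ch: dict[str, int] = {}
        for l in self.topo_order():
            ins = [ch[p] for p in l.inputs]
            if l.kind == "input":
                c = self.input_channels
            elif l.kind == "conv":
                if ins[0] != l.params["in_channels"]:
                    raise ValueError(
                        f"{l.name}: expects {l.params['in_channels']} input "
                        f"channels, receives {ins[0]}"
                    )
                c = l.params["out_channels"]
            elif l.kind == "fc":
                if ins[0] != l.params["in_features"]:
                    raise ValueError(
                        f"{l.name}: expects {l.params['in_features']} input "
                        f"features, receives {ins[0]}"
                    )
                c = l.params["out_features"]
            elif l.kind == "add":
                if len(set(ins)) != 1:
                    raise ValueError(f"{l.name}: add inputs differ in channels: {ins}")
                c = ins[0]
            elif l.kind == "concat":
                c = sum(ins)
            else:  # bn, relu, maxpool, gap, gmp
                c = ins[0]
            if l.out_channels is not None and l.out_channels != c:
                raise ValueError(
                    f"{l.name}: declared {l.out_channels} channels, inferred {c}"
                )
            ch[l.name] = c
        return ch

    def validate(self) -> None:
        """Full contract check: DAG, channel arithmetic, head widths."""
        ch = self.propagate_channels()
        heads = [l for l in self.layers if l.kind == "fc"]
        if not heads:
            raise ValueError("graph has no classifier head")
        head = heads[-1]
        if head.params["out_features"] != self.num_classes:
            raise ValueError("classifier width does not match num_classes")
        if head.params["in_features"] != self.feature_width:
            raise ValueError(
                f"classifier input {head.params['in_features']} != declared "
                f"feature_width {self.feature_width}"
            )
        feed = ch[head.inputs[0]]
        if feed != self.feature_width:
            raise ValueError(
                f"features entering classifier ({feed}) != feature_width "
                f"({self.feature_width})"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "variant": self.variant,
                "feature_width": self.feature_width,
                "num_classes": self.num_classes,
                "input_channels": self.input_channels,
                "input_size": self.input_size,
                "layers": [asdict(l) for l in self.layers],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ArchSpec":
        d = json.loads(text)
        d["layers"] = [LayerSpec(**l) for l in d.pop("layers")]
        return cls(**d)


def _materialize(spec: LayerSpec, rng: np.random.Generator) -> L.Layer | None:
    p = spec.params
    if spec.kind == "input":
        return None
    if spec.kind == "conv":
        return L.Conv2d(
            p["in_channels"], p["out_channels"], p["kernel"],
            stride=p.get("stride", 1), pad=p.get("pad", 0),
            bias=p.get("bias", False), rng=rng, name=spec.name,
        )
    if spec.kind == "bn":
        return L.BatchNorm2d(p["channels"], name=spec.name)
    if spec.kind == "relu":
        return L.ReLU()
    if spec.kind == "maxpool":
        return L.MaxPool2d(p["kernel"], stride=p.get("stride"), pad=p.get("pad", 0))
    if spec.kind == "gap":
        return L.GlobalAvgPool()
    if spec.kind == "gmp":
        return L.GlobalMaxPool()
    if spec.kind == "fc":
        return L.Linear(p["in_features"], p["out_features"], rng=rng, name=spec.name)
    if spec.kind == "add":
        return L.Add()
    if spec.kind == "concat":
        return L.Concat()
    raise ValueError(spec.kind)


class GraphModel:
    """Executable network materialized from an :class:`ArchSpec`."""

    def __init__(self, spec: ArchSpec, seed: int = 0) -> None:
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self._order = spec.topo_order()
        self.layers: dict[str, L.Layer | None] = {
            l.name: _materialize(l, rng) for l in self._order
        }
        self._output_name = self._order[-1].name
        out_kinds = [l for l in self._order if l.kind == "fc"]
        self._output_name = out_kinds[-1].name

    # -- parameters ------------------------------------------------------
    def parameters(self) -> list[L.Param]:
        out = []
        for l in self._order:
            layer = self.layers[l.name]
            if layer is not None:
                out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for p in self.parameters():
            out[p.name] = p.value.copy()
        for name, layer in self.layers.items():
            if isinstance(layer, L.BatchNorm2d):
                out[f"{name}.running_mean"] = layer.running_mean.copy()
                out[f"{name}.running_var"] = layer.running_var.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.value[...] = state[p.name]
        for name, layer in self.layers.items():
            if isinstance(layer, L.BatchNorm2d):
                layer.running_mean[...] = state[f"{name}.running_mean"]
                layer.running_var[...] = state[f"{name}.running_var"]

    # -- execution -------------------------------------------------------
    def forward(
        self, x: np.ndarray, train: bool = False, return_activations: bool = False
    ):
        values: dict[str, np.ndarray] = {}
        for spec in self._order:
            layer = self.layers[spec.name]
            if spec.kind == "input":
                values[spec.name] = np.asarray(x, dtype=np.float32)
                continue
            ins = [values[p] for p in spec.inputs]
            arg = ins if spec.kind in ("add", "concat") else ins[0]
            values[spec.name] = layer.forward(arg, train=train)
        self._values_keys = None
        if return_activations:
            return values[self._output_name], values
        return values[self._output_name]

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate from the classifier logits; accumulates into
        ``Param.grad``.  Requires a preceding ``forward(train=True)``."""
        grads: dict[str, np.ndarray] = {self._output_name: dlogits}
        for spec in reversed(self._order):
            if spec.kind == "input" or spec.name not in grads:
                continue
            layer = self.layers[spec.name]
            g = layer.backward(grads.pop(spec.name))
            gs = g if isinstance(g, list) else [g]
            for parent, gp in zip(spec.inputs, gs):
                if parent in grads:
                    grads[parent] = grads[parent] + gp
                else:
                    grads[parent] = gp

    def predict_logits(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        outs = []
        for i in range(0, x.shape[0], batch_size):
            outs.append(self.forward(x[i : i + batch_size], train=False))
        return np.concatenate(outs, axis=0)
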