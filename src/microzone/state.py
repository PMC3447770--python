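"""In-memory network state: layers, projections, and the assembled network.

Activations are stored as 2-D arrays of shape ``(batch, n_units)`` so that a
whole pattern set can be settled in one vectorized pass; online training uses
batch size 1.  Weights are stored in ``[0, 1]``; the sign of a projection
(excitatory/inhibitory) is applied at net-input time, never to the stored
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .params import ChannelSet, DynamicsParams, LearningParams

EXCITATORY = 1
INHIBITORY = -1


@dataclass
class LayerState:
    """A named group of units and their dynamic state.

    ``k`` is the k-winners-take-all count; layers with ``kwta=False`` (e.g.
    Purkinje cells, whose inhibition comes from explicitly modeled basket
    cells) skip layer-level competition.  ``lesioned`` marks permanently
    removed units: their activation is pinned to zero, they contribute nothing
    to net input, and they are excluded from the kWTA count.
    """

    name: str
    n: int
    role: str = "hidden"  # input | hidden | output
    k: int = 1
    kwta: bool = True
    subgroups: int = 1
    bias: np.ndarray = None
    lesioned: np.ndarray = None
    v_m: Optional[np.ndarray] = None
    y: Optional[np.ndarray] = None
    y_minus: Optional[np.ndarray] = None
    y_plus: Optional[np.ndarray] = None
    act_fraction: float = 0.5  # expected activity used for net-input scaling

    def __post_init__(self) -> None:
        if self.bias is None:
            self.bias = np.zeros(self.n, dtype=np.float64)
        if self.lesioned is None:
            self.lesioned = np.zeros(self.n, dtype=bool)

    @property
    def n_alive(self) -> int:
        return int(self.n - self.lesioned.sum())

    @property
    def k_effective(self) -> int:
        """kWTA count clamped to the number of non-lesioned units."""
        return min(self.k, self.n_alive)

    def copy(self) -> "LayerState":
        out = LayerState(
            name=self.name, n=self.n, role=self.role, k=self.k, kwta=self.kwta,
            subgroups=self.subgroups, bias=self.bias.copy(),
            lesioned=self.lesioned.copy(), act_fraction=self.act_fraction,
        )
        for attr in ("v_m", "y", "y_minus", "y_plus"):
            val = getattr(self, attr)
            setattr(out, attr, None if val is None else val.copy())
        return out


@dataclass
class ProjectionState:
    """A full or masked weight matrix between two layers.

    ``weights`` has shape ``(n_source, n_target)`` with entries in [0, 1].
    ``mask`` (optional boolean, same shape) restricts connectivity, e.g. the
    block-diagonal climbing-fiber -> Purkinje wiring.  ``divisor`` is the
    per-target net-input normalizer, fixed at build time (fan-in times the
    source layer's expected activity), so that removing source cells reduces
    drive instead of being renormalized away.
    """

    source: str
    target: str
    sign: int  # EXCITATORY or INHIBITORY
    strength: float = 1.0
    lrate: float = 0.0
    plastic: bool = True
    weights: np.ndarray = None
    mask: Optional[np.ndarray] = None
    divisor: np.ndarray = None

    def copy(self) -> "ProjectionState":
        return ProjectionState(
            source=self.source, target=self.target, sign=self.sign,
            strength=self.strength, lrate=self.lrate, plastic=self.plastic,
            weights=self.weights.copy(),
            mask=None if self.mask is None else self.mask,
            divisor=self.divisor.copy(),
        )


@dataclass
class NetworkState:
    """Layers, projections and shared parameters of one microzone."""

    layers: Dict[str, LayerState]
    projections: List[ProjectionState]
    channels: ChannelSet = field(default_factory=ChannelSet)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    learning: LearningParams = field(default_factory=LearningParams)
    dtype: np.dtype = np.float32
    meta: dict = field(default_factory=dict)

    def layer(self, name: str) -> LayerState:
        return self.layers[name]

    def incoming(self, name: str) -> List[ProjectionState]:
        return [p for p in self.projections if p.target == name]

    def outgoing(self, name: str) -> List[ProjectionState]:
        return [p for p in self.projections if p.source == name]

    @property
    def input_layers(self) -> List[str]:
        return [l.name for l in self.layers.values() if l.role == "input"]

    @property
    def output_layer(self) -> str:
        outs = [l.name for l in self.layers.values() if l.role == "output"]
        if len(outs) != 1:
            raise ValueError(f"expected exactly one output layer, found {outs}")
        return outs[0]

    def copy(self) -> "NetworkState":
        return NetworkState(
            layers={k: v.copy() for k, v in self.layers.items()},
            projections=[p.copy() for p in self.projections],
            channels=self.channels, dynamics=self.dynamics,
            learning=self.learning, dtype=self.dtype, meta=dict(self.meta),
        )

    def weight_snapshot(self) -> dict:
        """Weights and biases keyed by projection/layer, for checkpointing."""
        snap = {f"{p.source}->{p.target}": p.weights.copy() for p in self.projections}
        snap["__bias__"] = {name: l.bias.copy() for name, l in self.layers.items()}
        return snap

    def restore_weights(self, snap: dict) -> None:
        for p in self.projections:
            p.weights = snap[f"{p.source}->{p.target}"].copy()
        for name, b in snap["__bias__"].items():
            self.layers[name].bias = b.copy()
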