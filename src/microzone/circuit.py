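"""Declarative construction of the cerebellar microzone network.

One microzone comprises two input fiber systems (mossy, climbing), four
intrinsic cortical cell types (granule, Golgi, basket, Purkinje) and the deep
cerebellar neurons as output.  Counts, wiring, connection signs and relative
strengths are carried by :class:`MicrozoneConfig`; :func:`default_config`
returns the canonical circuit:

=================  =====  ======================================
group              count  notes
=================  =====  ======================================
mossy_fibers          24  input; excitatory
climbing_fibers        3  input; one per Purkinje subgroup
granule             3300  sparse code (5% kWTA)
golgi                300  inhibits granule cells
basket               130  inhibits Purkinje cells
purkinje              15  3 subgroups of 5; no layer kWTA
deep_nuclei            2  output; one-hot conditioned response
=================  =====  ======================================

The climbing-fiber -> Purkinje connection is ~26,000 times as strong as the
baseline connection, mossy -> granule four times as strong; Golgi -> granule,
basket -> Purkinje and Purkinje -> deep nuclei are inhibitory, everything
else excitatory.  An excitatory climbing-fiber collateral onto the deep
nuclei gives the output layer a teaching-aligned source of positive drive
(its only other afferent, the Purkinje projection, is inhibitory); the
``include_nuclear_collaterals`` flag removes it, and a mossy collateral can
be added through the configuration file.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import List, Optional

import numpy as np
import yaml

from .params import ChannelSet, DynamicsParams, LearningParams
from .state import EXCITATORY, INHIBITORY, LayerState, NetworkState, ProjectionState

GROUPS_CANONICAL = (
    "mossy_fibers", "climbing_fibers", "granule", "golgi", "basket",
    "purkinje", "deep_nuclei",
)


class ConfigError(ValueError):
    """Invalid microzone configuration."""


class InvalidScaleError(ValueError):
    """Invalid group-scaling factor."""


@dataclass
class CellGroupSpec:
    name: str
    count: int
    role: str = "hidden"  # input | hidden | output
    subgroups: int = 1
    k_fraction: Optional[float] = None  # None -> role/layer defaults
    kwta: bool = True
    # expected activity mass used to normalize this group's outgoing net
    # input (the sparse-activity correction); None derives it from the kWTA
    # fraction (hidden), 0.5 (inputs), or 1 (non-competing layers)
    act_scale: Optional[float] = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ConfigError(f"group {self.name!r}: count must be >= 1")
        if self.role not in ("input", "hidden", "output"):
            raise ConfigError(f"group {self.name!r}: unknown role {self.role!r}")
        if self.count % self.subgroups:
            raise ConfigError(
                f"group {self.name!r}: {self.count} units do not divide into "
                f"{self.subgroups} equal subgroups"
            )


@dataclass
class ConnectionSpec:
    """One projection between cell groups.

    ``fan_in`` restricts each target cell to a random sample of that many
    source cells (mossy -> granule uses 4, the classic sparse sampling that
    gives the granule layer its combinatorial expansion); ``None`` means
    all-to-all.
    """

    source: str
    target: str
    sign: str = "excitatory"  # excitatory | inhibitory
    strength: float = 1.0
    subgroup_aligned: bool = False
    fan_in: Optional[int] = None
    plastic: bool = True

    def __post_init__(self) -> None:
        if self.sign not in ("excitatory", "inhibitory"):
            raise ConfigError(f"{self.source}->{self.target}: bad sign {self.sign!r}")
        if self.strength <= 0:
            raise ConfigError(f"{self.source}->{self.target}: strength must be > 0")
        if self.fan_in is not None and self.fan_in < 1:
            raise ConfigError(f"{self.source}->{self.target}: fan_in must be >= 1")


@dataclass
class StimulusParams:
    """Conditioning-task generation parameters (see :mod:`microzone.stimuli`)."""

    n_samples: int = 140
    slow_change_bound: float = 0.15
    sample_dt: float = 0.25  # seconds of conditioning time per training sample
    table_order: bool = False  # plain binary counting instead of gray code


@dataclass
class MicrozoneConfig:
    groups: List[CellGroupSpec] = field(default_factory=list)
    connections: List[ConnectionSpec] = field(default_factory=list)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    learning: LearningParams = field(default_factory=LearningParams)
    stimuli: StimulusParams = field(default_factory=StimulusParams)
    include_nuclear_collaterals: bool = True
    weight_init: tuple = (0.25, 0.75)
    dtype: str = "float32"

    def group(self, name: str) -> CellGroupSpec:
        for g in self.groups:
            if g.name == name:
                return g
        raise ConfigError(f"unknown group {name!r}")

    def validate(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate group names")
        inputs = {g.name for g in self.groups if g.role == "input"}
        for c in self.connections:
            if c.source not in names or c.target not in names:
                raise ConfigError(f"connection {c.source}->{c.target} references unknown group")
            if c.source == c.target:
                raise ConfigError(f"self-projection on {c.source!r}")
            if c.target in inputs:
                raise ConfigError(f"input group {c.target!r} cannot receive projections")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "groups": [asdict(g) for g in self.groups],
            "connections": [asdict(c) for c in self.connections],
            "dynamics": asdict(self.dynamics),
            "learning": asdict(self.learning),
            "stimuli": asdict(self.stimuli),
            "flags": {"include_nuclear_collaterals": self.include_nuclear_collaterals},
            "weight_init": list(self.weight_init),
            "dtype": self.dtype,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MicrozoneConfig":
        cfg = cls(
            groups=[CellGroupSpec(**g) for g in d.get("groups", [])],
            connections=[ConnectionSpec(**c) for c in d.get("connections", [])],
            dynamics=DynamicsParams(**d.get("dynamics", {})),
            learning=LearningParams(**d.get("learning", {})),
            stimuli=StimulusParams(**d.get("stimuli", {})),
            include_nuclear_collaterals=d.get("flags", {}).get(
                "include_nuclear_collaterals", True
            ),
            weight_init=tuple(d.get("weight_init", (0.25, 0.75))),
            dtype=d.get("dtype", "float32"),
        )
        cfg.validate()
        return cfg

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "MicrozoneConfig":
        with open(path) as fh:
            if str(path).endswith(".json"):
                d = json.load(fh)
            else:
                d = yaml.safe_load(fh)
        return cls.from_dict(d)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_config() -> MicrozoneConfig:
    """The canonical microzone: counts, wiring, signs and strengths."""
    cfg = MicrozoneConfig(
        groups=[
            CellGroupSpec("mossy_fibers", 24, role="input"),
            CellGroupSpec("climbing_fibers", 3, role="input"),
            # 5% of granule cells win the competition at roughly half
            # activation, so their outgoing activity mass is ~0.025
            CellGroupSpec("granule", 3300, k_fraction=0.05, act_scale=0.025),
            # Golgi and basket cells receive dense, near-homogeneous granule
            # input; rank-based competition degenerates there (all drives
            # tie at the inhibition boundary).  They act as feedforward
            # inhibitory gain controls instead.
            CellGroupSpec("golgi", 300, kwta=False),
            CellGroupSpec("basket", 130, kwta=False),
            # Purkinje inhibition comes from basket cells, not lateral kWTA;
            # layer competition would mask the per-subgroup climbing-fiber code.
            CellGroupSpec("purkinje", 15, subgroups=3, kwta=False),
            # a 2-unit output under 10% kWTA would round to k=0 and silence
            # itself; the deep nuclei are instead sculpted by the learned
            # Purkinje inhibition.
            CellGroupSpec("deep_nuclei", 2, role="output", kwta=False),
        ],
        connections=[
            ConnectionSpec("mossy_fibers", "granule", "excitatory", 4.0, fan_in=4),
            ConnectionSpec("granule", "golgi", "excitatory", 1.0),
            # interneuron inhibition is a fixed gain control: the circuit's
            # plasticity lives at the parallel-fiber and nuclear synapses,
            # and unconstrained Hebbian drift on feedforward inhibition
            # would silence the parallel-fiber pathway
            # a granule cell is inhibited by the few Golgi cells sharing its
            # glomeruli, so Golgi-layer composition matters per cell
            ConnectionSpec("golgi", "granule", "inhibitory", 1.0, plastic=False,
                           fan_in=10),
            # each Purkinje/basket cell samples a tenth of the parallel
            # fibers, so the granule-layer composition (not just its total
            # activity) shapes the drive each target receives
            ConnectionSpec("granule", "basket", "excitatory", 1.0, fan_in=330),
            ConnectionSpec("granule", "purkinje", "excitatory", 1.0, fan_in=330),
            ConnectionSpec("basket", "purkinje", "inhibitory", 1.0, plastic=False),
            ConnectionSpec("climbing_fibers", "purkinje", "excitatory", 26000.0,
                           subgroup_aligned=True),
            ConnectionSpec("purkinje", "deep_nuclei", "inhibitory", 1.0),
            # the nuclear collateral carries the teaching signal's excitatory
            # drive; a direct mossy shortcut would let the readout bypass the
            # cerebellar cortex entirely
            ConnectionSpec("climbing_fibers", "deep_nuclei", "excitatory", 1.0),
        ],
    )
    cfg.validate()
    return cfg


def derive_k(spec: CellGroupSpec) -> int:
    """kWTA count for a group: 10% of units by default, 5% for granule cells."""
    if not spec.kwta or spec.role == "input":
        return spec.count
    frac = spec.k_fraction
    if frac is None:
        frac = 0.05 if spec.name == "granule" else 0.10
    return max(1, int(round(frac * spec.count)))


def scale_group(config: MicrozoneConfig, name: str, factor: float) -> MicrozoneConfig:
    """Return a new config with one group's cell count scaled by ``factor``.

    Wiring is preserved; the kWTA count is re-derived from the new size at
    build time (k is stored as a fraction).  The scaled count is rounded to
    the nearest integer and must remain >= 1.
    """
    if factor <= 0:
        raise InvalidScaleError(f"scale factor must be > 0, got {factor}")
    cfg = copy.deepcopy(config)
    spec = cfg.group(name)
    new_count = int(round(spec.count * factor))
    if new_count < 1:
        raise InvalidScaleError(
            f"scaling {name!r} by {factor} yields {new_count} cells (< 1)"
        )
    if spec.subgroups > 1:
        per = max(1, int(round(new_count / spec.subgroups)))
        new_count = per * spec.subgroups
    ratio = new_count / spec.count
    spec.count = new_count
    for c in cfg.connections:
        if c.source == name and c.fan_in is not None:
            c.fan_in = max(1, int(round(c.fan_in * ratio)))
    return cfg


def _subgroup_mask(n_src: int, n_tgt: int, subgroups: int) -> np.ndarray:
    """Block mask: source fiber g connects only to target subgroup g."""
    if n_src != subgroups:
        raise ConfigError(
            f"subgroup-aligned projection needs {subgroups} source fibers, got {n_src}"
        )
    mask = np.zeros((n_src, n_tgt), dtype=bool)
    per = n_tgt // subgroups
    for g in range(subgroups):
        mask[g, g * per:(g + 1) * per] = True
    return mask


def build_microzone(config: MicrozoneConfig, seed: int = 0) -> NetworkState:
    """Instantiate layers and weight matrices from a configuration.

    Connectivity is all-to-all within each connection spec except
    subgroup-aligned ones (climbing fibers -> Purkinje), which get a
    block-diagonal mask.  Initial weights are uniform in ``weight_init``
    per-projection seeded, so two builds with the same seed are bit-identical.
    Net-input divisors (fan-in x expected source activity) are frozen here;
    they deliberately do not shrink when cells are later lesioned.
    """
    config.validate()
    dtype = np.dtype(config.dtype)
    layers = {}
    for g in config.groups:
        layers[g.name] = LayerState(
            name=g.name, n=g.count, role=g.role, k=derive_k(g),
            kwta=(g.kwta and g.role != "input"), subgroups=g.subgroups,
        )
        if g.act_scale is not None:
            layers[g.name].act_fraction = g.act_scale
        elif g.role == "input":
            layers[g.name].act_fraction = 0.5
        else:
            layers[g.name].act_fraction = max(derive_k(g) / g.count, 1e-6)

    connections = list(config.connections)
    if not config.include_nuclear_collaterals:
        connections = [
            c for c in connections
            if not (c.target == "deep_nuclei" and c.sign == "excitatory")
        ]

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(connections))
    projections = []
    for c, child in zip(connections, children):
        src, tgt = layers[c.source], layers[c.target]
        rng = np.random.Generator(np.random.PCG64(child))
        lo, hi = config.weight_init
        w = rng.uniform(lo, hi, size=(src.n, tgt.n)).astype(dtype)
        mask = None
        if c.subgroup_aligned:
            mask = _subgroup_mask(src.n, tgt.n, tgt.subgroups)
        elif c.fan_in is not None and c.fan_in < src.n:
            mask = np.zeros((src.n, tgt.n), dtype=bool)
            for j in range(tgt.n):
                mask[rng.choice(src.n, size=c.fan_in, replace=False), j] = True
        if mask is not None:
            w = w * mask
            fan_in = mask.sum(axis=0).astype(np.float64)
        else:
            fan_in = np.full(tgt.n, src.n, dtype=np.float64)
        divisor = np.maximum(fan_in * src.act_fraction, 1e-12).astype(dtype)
        projections.append(ProjectionState(
            source=c.source, target=c.target,
            sign=EXCITATORY if c.sign == "excitatory" else INHIBITORY,
            strength=c.strength, lrate=config.learning.lrate if c.plastic else 0.0,
            plastic=c.plastic, weights=w, mask=mask, divisor=divisor,
        ))

    net = NetworkState(
        layers=layers, projections=projections,
        channels=ChannelSet(), dynamics=config.dynamics,
        learning=config.learning, dtype=dtype,
        meta={"config_hash": config.hash(),
              "build_seed": int(seed) if isinstance(seed, (int, np.integer)) else repr(seed)},
    )
    return net
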