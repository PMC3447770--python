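"""Parameter containers for the point-neuron dynamics and learning rules.

All potentials are expressed in normalized units: the membrane potential and
every reversal potential live on an abstract [0, 1]-ish scale, ordered
``E_inhib <= E_leak < E_excit``.  Conductances are non-negative and
dimensionless; the products ``g_c * g_bar_c`` set the relative pull of each
channel on the membrane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping


@dataclass(frozen=True)
class ChannelParams:
    """A single ionic channel: its maximal conductance and reversal potential.

    Parameters
    ----------
    name:
        One of ``"excitatory"``, ``"inhibitory"`` or ``"leak"``.
    g_bar:
        Maximal conductance; a constant scale on the time-varying conductance.
        Must be non-negative.
    e_rev:
        Reversal (driving) potential in normalized potential units.
    """

    name: str
    g_bar: float
    e_rev: float

    def __post_init__(self) -> None:
        if self.g_bar < 0:
            raise ValueError(f"channel {self.name!r}: g_bar must be >= 0, got {self.g_bar}")


@dataclass(frozen=True)
class ChannelSet:
    """The three channels driving every unit: excitation, inhibition, leak.

    Invariant: ``E_inhib <= E_leak < E_excit``.  The membrane potential is
    confined to ``[E_inhib, E_excit]`` (the extreme reversal potentials).
    """

    excitatory: ChannelParams = ChannelParams("excitatory", 1.0, 1.0)
    inhibitory: ChannelParams = ChannelParams("inhibitory", 1.0, 0.15)
    leak: ChannelParams = ChannelParams("leak", 0.1, 0.30)

    def __post_init__(self) -> None:
        if not (self.inhibitory.e_rev <= self.leak.e_rev < self.excitatory.e_rev):
            raise ValueError(
                "reversal potentials must satisfy E_inhib <= E_leak < E_excit, got "
                f"{self.inhibitory.e_rev}, {self.leak.e_rev}, {self.excitatory.e_rev}"
            )

    @property
    def e_min(self) -> float:
        return min(self.excitatory.e_rev, self.inhibitory.e_rev, self.leak.e_rev)

    @property
    def e_max(self) -> float:
        return max(self.excitatory.e_rev, self.inhibitory.e_rev, self.leak.e_rev)


@dataclass
class DynamicsParams:
    """Integration and activation parameters shared by all layers.

    tau:
        Euler step size of the membrane update (the calcium-kinetics time
        constant of the point-neuron model).  Must be positive.
    cycles:
        Number of settling cycles per phase (>= 1).
    gain:
        Slope of the rate-code activation function above threshold.
    threshold:
        Membrane potential at which a unit starts firing; activation is
        exactly zero at or below it.
    kwta_pt:
        Placement of the k-winners-take-all inhibition between the k-th and
        (k+1)-th strongest drives (0 puts it on the (k+1)-th, 1 on the k-th).
    update_mode:
        ``"per_pattern"`` applies weight deltas after every pattern (online);
        ``"per_epoch"`` accumulates them over an epoch and applies them once.
    abort_activation:
        Settling aborts with an error when any activation magnitude exceeds
        this bound or becomes non-finite.
    """

    tau: float = 0.2
    cycles: int = 30
    gain: float = 50.0
    threshold: float = 0.5
    kwta_pt: float = 0.25
    update_mode: str = "per_epoch"
    abort_activation: float = 1e3
    # settling stops early once no activation moves more than this between
    # consecutive cycles (0 disables; purely a numerical shortcut)
    settle_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.cycles < 1:
            raise ValueError(f"cycles must be >= 1, got {self.cycles}")
        if self.gain <= 0:
            raise ValueError(f"gain must be > 0, got {self.gain}")
        if self.update_mode not in ("per_pattern", "per_epoch"):
            raise ValueError(f"unknown update_mode {self.update_mode!r}")


@dataclass
class LearningParams:
    """Learning-rule parameters.

    lrate:
        Base learning rate epsilon.  A projection's effective rate is
        ``lrate * min(strength, lrate_cap)`` so that stronger connections
        adapt faster without diverging.
    hebb:
        Mixing proportion lambda of the Hebbian (CPCA) delta; the remainder
        ``1 - hebb`` weights the error-driven (GeneRec) delta.
    cpca_correction:
        Multiplicative renormalization of the Hebbian delta compensating for
        sparse expected activity (1.0 = off).
    bias_lrate:
        Learning rate of the per-unit bias (error-driven only).
    err_tol:
        Per-output tolerance of the association-error statistic: absolute
        deviations strictly below it count as zero, the neural-simulator
        convention that makes "error reached exactly 0%" a well-defined
        stopping rule for analog outputs.  A deviation of exactly 0.5 (an
        output halfway to the wrong target) still counts in full.
    criterion:
        Training stops when the epoch error percentage falls below this
        value; 5e-7 operationalizes "zero to six significant figures".
    """

    lrate: float = 0.2
    lrate_cap: float = 10.0
    hebb: float = 0.01
    cpca_correction: float = 1.0
    bias_lrate: float = 0.2
    err_tol: float = 0.5
    criterion: float = 5e-7
    max_epochs: int = 2000
    shuffle: bool = False

    def __post_init__(self) -> None:
        if self.lrate < 0 or self.bias_lrate < 0:
            raise ValueError("learning rates must be >= 0")
        if not 0.0 <= self.hebb <= 1.0:
            raise ValueError(f"hebb mixing must be in [0,1], got {self.hebb}")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


def params_to_dict(obj) -> Mapping:
    return asdict(obj)
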