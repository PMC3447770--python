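"""Synthetic eyeblink (puff/buzz) conditioning stimuli.

The training stream emulates the sensory statistics of the two cerebellar
input systems during classical conditioning of the rabbit eyeblink:

* **Mossy fibers** carry slowly varying contextual signals.  Each of the 24
  channels is an independent bounded random walk on [0, 1] that reflects at
  the edges, so consecutive values differ by at most ``slow_change_bound``
  while the long-run marginal distribution is uniform on [0, 1].
* **Climbing fibers** carry strong, discrete teaching signals.  The 3 binary
  channels step through the reflected Gray sequence cyclically, so exactly
  one bit changes between consecutive samples and all 8 patterns appear once
  per period of 8.
* **Deep-nuclei targets** encode the conditioned response one-hot: ``(1, 0)``
  while the first climbing bit is 0 and ``(0, 1)`` once it is 1.

A training set of 140 samples of 24 + 3 inputs and 2 targets (3780 scalar
training points) is the default.  For inter-stimulus-interval experiments the
climbing stream (and with it the targets) can be delayed relative to the
mossy stream in multiples of ``sample_dt`` seconds by a cyclic shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd


class ParameterError(ValueError):
    pass


class EncodingError(ValueError):
    pass


@dataclass
class TrainingSet:
    """Ordered conditioning samples: mossy context, climbing teacher, target."""

    mossy: np.ndarray      # (n_samples, n_mossy) floats in [0, 1]
    climbing: np.ndarray   # (n_samples, n_climbing) values in {0, 1}
    targets: np.ndarray    # (n_samples, n_out) one-hot
    seed: Optional[int] = None
    isi_seconds: float = 0.0
    sample_dt: float = 0.25

    def __post_init__(self) -> None:
        n = len(self.mossy)
        if not (len(self.climbing) == len(self.targets) == n):
            raise ParameterError("mossy/climbing/target lengths differ")

    def __len__(self) -> int:
        return len(self.mossy)

    @property
    def inputs_per_sample(self) -> int:
        return self.mossy.shape[1] + self.climbing.shape[1]

    def copy(self) -> "TrainingSet":
        return TrainingSet(self.mossy.copy(), self.climbing.copy(),
                           self.targets.copy(), self.seed, self.isi_seconds,
                           self.sample_dt)

    # -- CSV interchange mirroring the tabular layout ----------------------

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for i in range(self.mossy.shape[1]):
            cols[f"MF_{i + 1}"] = self.mossy[:, i]
        for i in range(self.climbing.shape[1]):
            cols[f"CF_{i + 1}"] = self.climbing[:, i].astype(int)
        for i in range(self.targets.shape[1]):
            cols[f"DN_{i + 1}"] = self.targets[:, i].astype(int)
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.8g")

    @classmethod
    def from_csv(cls, path, sample_dt: float = 0.25) -> "TrainingSet":
        df = pd.read_csv(path)
        mf = [c for c in df.columns if c.startswith("MF_")]
        cf = [c for c in df.columns if c.startswith("CF_")]
        dn = [c for c in df.columns if c.startswith("DN_")]
        return cls(
            mossy=df[mf].to_numpy(dtype=float),
            climbing=df[cf].to_numpy(dtype=float),
            targets=df[dn].to_numpy(dtype=float),
            sample_dt=sample_dt,
        )


def generate_mossy_stream(
    n_samples: int,
    n_fibers: int = 24,
    slow_change_bound: float = 0.15,
    seed=None,
) -> np.ndarray:
    """Bounded, slowly varying mossy-fiber stream.

    Each fiber performs an independent random walk with uniform increments in
    ``[-slow_change_bound, +slow_change_bound]``, reflecting at 0 and 1.
    Reflection never enlarges a step, so consecutive values always differ by
    at most the bound, and the stationary marginal is uniform on [0, 1].
    """
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    if not 0 < slow_change_bound <= 1:
        raise ParameterError(
            f"slow_change_bound must be in (0, 1], got {slow_change_bound}"
        )
    rng = np.random.default_rng(seed)
    x = np.empty((n_samples, n_fibers))
    x[0] = rng.uniform(0.0, 1.0, size=n_fibers)
    steps = rng.uniform(-slow_change_bound, slow_change_bound,
                        size=(n_samples - 1, n_fibers)) if n_samples > 1 else None
    for t in range(1, n_samples):
        nxt = x[t - 1] + steps[t - 1]
        nxt = np.where(nxt > 1.0, 2.0 - nxt, nxt)
        nxt = np.where(nxt < 0.0, -nxt, nxt)
        x[t] = nxt
    return x


def _gray_codes(n_bits: int) -> np.ndarray:
    """All 2**n reflected Gray codes, one bit flipped between neighbors."""
    n = 1 << n_bits
    codes = np.arange(n) ^ (np.arange(n) >> 1)
    bits = ((codes[:, None] >> np.arange(n_bits - 1, -1, -1)) & 1).astype(float)
    return bits


def generate_climbing_stream(
    n_samples: int, n_fibers: int = 3, table_order: bool = False
) -> np.ndarray:
    """Binary climbing-fiber stream cycling the reflected Gray sequence.

    Consecutive rows differ in exactly one position (including across the
    period wrap), and each period of ``2**n_fibers`` rows contains every
    pattern once.  ``table_order=True`` instead emits plain binary counting
    (000, 001, 010, ...), the literal tabular ordering, which does not keep
    the one-bit-change property.
    """
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    if table_order:
        n = 1 << n_fibers
        codes = np.arange(n)
        period = ((codes[:, None] >> np.arange(n_fibers - 1, -1, -1)) & 1).astype(float)
    else:
        period = _gray_codes(n_fibers)
    reps = -(-n_samples // len(period))
    return np.tile(period, (reps, 1))[:n_samples]


def derive_targets(climbing: np.ndarray) -> np.ndarray:
    """One-hot conditioned-response targets from the climbing pattern.

    The first climbing bit is the unconditioned-stimulus flag: target is
    ``(1, 0)`` when it is 0 and ``(0, 1)`` when it is 1.
    """
    cf = np.asarray(climbing, dtype=float)
    if cf.ndim != 2 or cf.shape[1] < 1:
        raise EncodingError("climbing rows must be a 2-D binary matrix")
    if not np.isin(cf, (0.0, 1.0)).all():
        raise EncodingError("climbing values must be binary (0 or 1)")
    lead = cf[:, 0]
    return np.stack([1.0 - lead, lead], axis=1)


def generate_training_set(config=None, seed=None, n_samples: Optional[int] = None) -> TrainingSet:
    """The full conditioning set: mossy + climbing inputs and one-hot targets.

    ``config`` may be a :class:`microzone.circuit.MicrozoneConfig` (input and
    output widths and stimulus parameters are read from it) or ``None`` for
    the canonical 24/3/2 widths.  Only the mossy stream is stochastic; the
    climbing sequence and targets are deterministic.
    """
    n_mossy, n_climbing = 24, 3
    bound, dt, table_order = 0.15, 0.25, False
    if config is not None:
        n_mossy = config.group("mossy_fibers").count
        n_climbing = config.group("climbing_fibers").count
        bound = config.stimuli.slow_change_bound
        dt = config.stimuli.sample_dt
        table_order = config.stimuli.table_order
        if n_samples is None:
            n_samples = config.stimuli.n_samples
    if n_samples is None:
        n_samples = 140
    mossy = generate_mossy_stream(n_samples, n_mossy, bound, seed)
    climbing = generate_climbing_stream(n_samples, n_climbing, table_order)
    targets = derive_targets(climbing)
    return TrainingSet(mossy=mossy, climbing=climbing, targets=targets,
                       seed=int(seed) if isinstance(seed, (int, np.integer)) else None,
                       sample_dt=dt)


def shift_stimuli(tset: TrainingSet, isi_seconds: float) -> TrainingSet:
    """Delay the climbing stream (and its targets) relative to the mossy one.

    The delay is ``round(isi_seconds / sample_dt)`` samples, applied as a
    cyclic shift so the set length is preserved; shifting by a full period
    returns the original set.  ``isi_seconds`` must lie in [0, 3] seconds.
    """
    if not 0.0 <= isi_seconds <= 3.0:
        raise ParameterError(f"isi must be within [0, 3] s, got {isi_seconds}")
    shift = int(round(isi_seconds / tset.sample_dt))
    out = tset.copy()
    out.isi_seconds = isi_seconds
    if shift % len(tset) == 0:
        return out
    out.climbing = np.roll(tset.climbing, shift, axis=0)
    out.targets = np.roll(tset.targets, shift, axis=0)
    return out
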