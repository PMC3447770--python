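"""In-silico neurodegeneration: permanent removal of cells from a trained net.

Cell death is modeled by marking units as lesioned in the trained network:
their activation is pinned to zero, they contribute nothing to any net input,
and they are excluded from the kWTA count.  Removal is permanent — no
recovery or retraining follows — and the association error is re-measured on
the very set the network was trained on (the quantity of interest is the loss
of the *trained* association; there is no held-out task).

Two degeneration regimes are provided:

* per-cell-type schedules: cumulative removal in 1% increments of the group
  up to 30%, except the small groups where whole cells are removed one at a
  time (mossy fibers to 8 of 24, climbing fibers a single cell of 3,
  Purkinje cells to 5 of 15);
* size-weighted random degeneration: cells are drawn without replacement
  from the pooled intrinsic population (granule + Golgi + basket + Purkinje,
  3745 cells in the canonical circuit), so the chance of a given type being
  hit tracks its share of the pool (granule cells: 3300/3745 ~ 88%).

Every curve is averaged over independently seeded trials; a fresh weight
seed, mossy-stream seed and removal-order seed are derived per trial from the
base seed via ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .circuit import MicrozoneConfig, build_microzone
from .state import NetworkState
from .stimuli import TrainingSet, generate_training_set
from .training import epoch_error, train_to_criterion

RANDOM = "RANDOM"
INTRINSIC_POOL = ("granule", "golgi", "basket", "purkinje")


class LesionError(ValueError):
    pass


class ScheduleError(ValueError):
    pass


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class LesionSchedule:
    """Cumulative removal counts for one target group (or the random pool)."""

    group: str
    cumulative_counts: List[int]
    max_fraction: float
    pool_size: int

    def __post_init__(self) -> None:
        c = self.cumulative_counts
        if any(b <= a for a, b in zip(c, c[1:])):
            raise ScheduleError(f"{self.group}: cumulative counts must strictly increase")
        if not 0 < self.max_fraction <= 1:
            raise ScheduleError(f"{self.group}: max fraction must be in (0, 1]")

    @property
    def fractions(self) -> np.ndarray:
        """Removed fraction per step, including the intact step 0."""
        return np.array([0.0] + [c / self.pool_size for c in self.cumulative_counts])

    @property
    def increments(self) -> List[int]:
        prev = 0
        out = []
        for c in self.cumulative_counts:
            out.append(c - prev)
            prev = c
        return out


@dataclass
class DegradationCurve:
    """Per-step removed fraction -> association error, per trial and averaged."""

    group: str
    fractions: np.ndarray            # (n_steps + 1,), step 0 = intact
    trial_errors: np.ndarray         # (n_trials, n_steps + 1); NaN where unmeasured
    seeds: List[int] = field(default_factory=list)
    excluded_trials: int = 0

    @property
    def n_trials(self) -> int:
        return self.trial_errors.shape[0]

    @property
    def mean_errors(self) -> np.ndarray:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.trial_errors, axis=0)

    @property
    def final_mean_error(self) -> float:
        return float(self.mean_errors[-1])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in range(self.n_trials):
            for s, f in enumerate(self.fractions):
                e = self.trial_errors[t, s]
                if np.isfinite(e):
                    rows.append((self.group, float(f), t, float(e)))
        return pd.DataFrame(rows, columns=["group", "fraction_removed", "trial", "error_pct"])

    def means_frame(self) -> pd.DataFrame:
        m = self.mean_errors
        keep = np.isfinite(m)
        return pd.DataFrame({
            "group": self.group,
            "fraction_removed": self.fractions[keep],
            "mean_error_pct": m[keep],
        })


# ---------------------------------------------------------------------------
# removal primitives
# ---------------------------------------------------------------------------

def remove_cells(net: NetworkState, group: str, count: int, seed=None) -> NetworkState:
    """Permanently lesion ``count`` uniformly chosen live cells of a group.

    ``seed`` may be an int, a Generator, or None.  The network is modified in
    place (and returned); weights are never retrained afterwards.
    """
    layer = net.layer(group)
    alive = np.flatnonzero(~layer.lesioned)
    if count < 0 or count > alive.size:
        raise LesionError(
            f"cannot remove {count} cells from {group!r}: {alive.size} available"
        )
    if count == 0:
        return net
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(alive, size=count, replace=False)
    layer.lesioned[chosen] = True
    return net


def build_schedule(group: str, config: MicrozoneConfig, mode: str = "percent") -> LesionSchedule:
    """The removal schedule for one cell type.

    Large groups (granule, Golgi, basket) lose 1% of their cells per step up
    to 30%; mossy fibers lose one cell per step up to 8; climbing fibers lose
    a single cell; Purkinje cells lose one per step up to 5.  ``mode="table"``
    substitutes the literal printed removal total where it disagrees with the
    percentage arithmetic (basket cells: 29 instead of 39).
    """
    if mode not in ("percent", "table"):
        raise ScheduleError(f"unknown schedule mode {mode!r}")
    try:
        n = config.group(group).count
    except Exception as exc:
        raise ScheduleError(f"unknown group {group!r}") from exc
    if group == "mossy_fibers":
        counts, max_frac = list(range(1, 9)), 8 / n if n else 0.32
    elif group == "climbing_fibers":
        counts, max_frac = [1], 1 / n
    elif group == "purkinje":
        counts, max_frac = list(range(1, 6)), 5 / n
    elif group in ("granule", "golgi", "basket"):
        raw = [_round_half_up(i * 0.01 * n) for i in range(1, 31)]
        counts = sorted({c for c in raw if c >= 1})
        max_frac = 0.30
        if mode == "table" and group == "basket":
            literal = 29
            counts = [c for c in counts if c < literal] + [literal]
    else:
        raise ScheduleError(f"no schedule defined for group {group!r}")
    return LesionSchedule(group=group, cumulative_counts=counts,
                          max_fraction=max_frac, pool_size=n)


def random_pool_schedule(config: MicrozoneConfig,
                         eligible: Sequence[str] = INTRINSIC_POOL) -> LesionSchedule:
    """1%-of-pool steps up to 30% over the pooled intrinsic cell types."""
    pool = sum(config.group(g).count for g in eligible)
    raw = [_round_half_up(i * 0.01 * pool) for i in range(1, 31)]
    counts = sorted({c for c in raw if c >= 1})
    return LesionSchedule(group=RANDOM, cumulative_counts=counts,
                          max_fraction=0.30, pool_size=pool)


def _trial_seeds(base_seed: int, trial: int) -> Tuple:
    """Deterministic (weights, mossy, removal) seed sequences for one trial."""
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=(int(trial),))
    return tuple(ss.spawn(3))


def degrade_trained(
    net: NetworkState,
    tset: TrainingSet,
    schedule: LesionSchedule,
    rng: np.random.Generator,
    measure_steps: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Walk one removal schedule on a copy of a trained network.

    Returns the association error at every step (step 0 = intact network);
    steps not listed in ``measure_steps`` are NaN.  The incremental removal
    order is drawn from ``rng``; measuring only the final step is
    statistically identical to measuring every step, because cumulative
    uniform increments compose into a uniform subset.
    """
    work = net.copy()
    n_steps = len(schedule.cumulative_counts)
    steps = range(n_steps + 1) if measure_steps is None else set(measure_steps)
    errors = np.full(n_steps + 1, np.nan)
    if 0 in steps or measure_steps is None:
        errors[0] = epoch_error(work, tset)
    if schedule.group == RANDOM:
        pools = {g: np.flatnonzero(~work.layer(g).lesioned) for g in INTRINSIC_POOL}
        flat = np.concatenate([
            np.stack([np.full(idx.size, gi), idx], axis=1)
            for gi, (g, idx) in enumerate(pools.items())
        ])
        order = rng.permutation(flat.shape[0])
        names = list(pools)
        prev = 0
        for s, cum in enumerate(schedule.cumulative_counts, start=1):
            for row in flat[order[prev:cum]]:
                work.layer(names[int(row[0])]).lesioned[int(row[1])] = True
            prev = cum
            if s in steps or measure_steps is None:
                errors[s] = epoch_error(work, tset)
    else:
        for s, inc in enumerate(schedule.increments, start=1):
            remove_cells(work, schedule.group, inc, seed=rng)
            if s in steps or measure_steps is None:
                errors[s] = epoch_error(work, tset)
    return errors


def prepare_trial(
    config: MicrozoneConfig, base_seed: int, trial: int,
    max_epochs: Optional[int] = None,
):
    """Build, generate stimuli and train one trial's network.

    Returns ``(result, tset, removal_rng)`` where ``result`` is the
    :class:`~microzone.training.TrainingResult`.
    """
    w_ss, m_ss, r_ss = _trial_seeds(base_seed, trial)
    net = build_microzone(config, seed=w_ss)
    tset = generate_training_set(config, seed=np.random.default_rng(m_ss))
    result = train_to_criterion(net, tset, max_epochs=max_epochs)
    removal_rng = np.random.default_rng(r_ss)
    return result, tset, removal_rng


def run_degradation(
    config: MicrozoneConfig,
    group: str,
    n_trials: int,
    base_seed: int,
    schedule_mode: str = "percent",
    measure_steps: Optional[Sequence[int]] = None,
    max_epochs: Optional[int] = None,
) -> DegradationCurve:
    """Full Monte-Carlo degradation experiment for one cell type.

    Per trial: build the network with a fresh weight seed, generate the
    training set with a fresh mossy seed, train to criterion, then walk the
    removal schedule measuring the association error.  Trials that fail to
    converge are recorded as excluded and do not enter the mean.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    schedule = (random_pool_schedule(config) if group == RANDOM
                else build_schedule(group, config, mode=schedule_mode))
    n_steps = len(schedule.cumulative_counts)
    rows, excluded = [], 0
    for trial in range(n_trials):
        result, tset, rng = prepare_trial(config, base_seed, trial, max_epochs)
        if not result.converged:
            excluded += 1
            rows.append(np.full(n_steps + 1, np.nan))
            continue
        rows.append(degrade_trained(result.network, tset, schedule, rng,
                                    measure_steps=measure_steps))
    return DegradationCurve(
        group=group, fractions=schedule.fractions,
        trial_errors=np.vstack(rows), seeds=[int(base_seed), n_trials],
        excluded_trials=excluded,
    )


def run_random_degeneration(
    config: MicrozoneConfig, n_trials: int, base_seed: int,
    measure_steps: Optional[Sequence[int]] = None,
    max_epochs: Optional[int] = None,
) -> DegradationCurve:
    """Size-weighted random degeneration over the pooled intrinsic cells."""
    return run_degradation(config, RANDOM, n_trials, base_seed,
                           measure_steps=measure_steps, max_epochs=max_epochs)


def curve_roughness(curve: DegradationCurve) -> float:
    """Maximum absolute second difference of the trial-mean curve."""
    m = curve.mean_errors
    m = m[np.isfinite(m)]
    if m.size < 3:
        return 0.0
    return float(np.abs(np.diff(m, n=2)).max())
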