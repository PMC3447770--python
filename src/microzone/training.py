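"""Two-phase training of the microzone and the association-error statistic.

Each pattern is presented in two settling phases: an *expectation* (minus)
phase with the inputs clamped and the output free, and an *outcome* (plus)
phase with the target additionally clamped onto the deep nuclei.  Weight
deltas combine the error-driven and Hebbian rules (see
:mod:`microzone.dynamics`); by default all patterns of an epoch settle as
one batch and the epoch-mean delta is applied once (``update_mode``
selects the per-pattern online variant instead).

The association error of a network on a pattern set is the averaged sum
squared error of the expectation-phase outputs, expressed as a percentage:

    error% = 100 * sum_p sum_o (target - y_minus)^2 / (N_patterns * N_outputs)

with per-output deviations below ``err_tol`` (0.5 by default) counting as
zero — the simulator convention that makes "the error reached exactly 0%"
well defined for analog outputs.  Training terminates when the epoch error
drops below 5e-7 % (zero to six significant figures), corresponding to the
animal having fully mastered the puff/buzz association.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, List, Optional

import numpy as np
import pandas as pd

from . import dynamics
from .state import NetworkState
from .stimuli import TrainingSet


@dataclass
class TrainingRecord:
    epoch: int
    error_pct: float
    max_weight_change: float


@dataclass
class TrainingResult:
    network: NetworkState
    records: List[TrainingRecord]
    converged: bool

    @property
    def epochs(self) -> int:
        return len(self.records)

    def __iter__(self):  # (network, records) unpacking convenience
        yield self.network
        yield self.records

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.epoch, r.error_pct, r.max_weight_change) for r in self.records],
            columns=["epoch", "error_pct", "max_weight_change"],
        )

    def write_log(self, csv_path, meta_path=None, extra_meta: dict = None) -> None:
        self.log_frame().to_csv(csv_path, index=False, float_format="%.8g")
        if meta_path is not None:
            meta = {
                "epochs": self.epochs,
                "converged": self.converged,
                "final_error_pct": self.records[-1].error_pct if self.records else None,
            }
            meta.update(self.network.meta)
            meta.update(extra_meta or {})
            with open(meta_path, "w") as fh:
                json.dump(meta, fh, indent=2, sort_keys=True, default=str)


def association_error(outputs: np.ndarray, targets: np.ndarray,
                      err_tol: float = 0.0) -> float:
    """Averaged sum squared error as a percentage of lost association.

    Per-output absolute deviations strictly below ``err_tol`` count as zero
    (a deviation of exactly ``err_tol`` counts in full); ``err_tol=0`` gives
    the raw statistic.
    """
    outputs = np.asarray(outputs, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if outputs.shape != targets.shape:
        raise ValueError(f"shape mismatch: outputs {outputs.shape} vs targets {targets.shape}")
    d = np.abs(targets - outputs)
    if err_tol > 0.0:
        d = np.where(d < err_tol, 0.0, d)
    return float(100.0 * np.mean(d ** 2))


def _clamps(net: NetworkState, tset: TrainingSet):
    mossy_name, climbing_name = net.input_layers[0], net.input_layers[1]
    return {mossy_name: tset.mossy, climbing_name: tset.climbing}


def epoch_error(net: NetworkState, tset: TrainingSet) -> float:
    """Association error of the expectation phase over the whole set.

    Runs minus-phase settling only (all patterns batched) and never modifies
    weights.  The output layer size must match the target width.
    """
    out_name = net.output_layer
    if net.layer(out_name).n != tset.targets.shape[1]:
        raise ValueError(
            f"output layer has {net.layer(out_name).n} units, targets have "
            f"{tset.targets.shape[1]} columns"
        )
    dynamics.settle(net, _clamps(net, tset), phase="minus")
    return association_error(net.layer(out_name).y_minus, tset.targets,
                             err_tol=net.learning.err_tol)


def _plus_phase(net: NetworkState, targets_row: np.ndarray, clamps: dict) -> None:
    """Outcome phase.  When the output layer has no efferent projections a
    clamp on it cannot influence any other layer, so the plus-phase state is
    the minus-phase state with the output replaced by the target; otherwise a
    full settle with the output clamped is run."""
    out_name = net.output_layer
    if not net.outgoing(out_name):
        for layer in net.layers.values():
            layer.y_plus = None if layer.y_minus is None else layer.y_minus.copy()
        out = net.layer(out_name)
        t = np.atleast_2d(np.asarray(targets_row, dtype=net.dtype)).copy()
        t[:, out.lesioned] = 0.0
        out.y_plus = t
    else:
        dynamics.settle(net, {**clamps, out_name: targets_row}, phase="plus")


def train_to_criterion(
    net: NetworkState,
    tset: TrainingSet,
    max_epochs: Optional[int] = None,
    seed: Optional[int] = None,
    criterion: Optional[float] = None,
    callback: Optional[Callable[[int, NetworkState], None]] = None,
) -> TrainingResult:
    """Train until the association error reaches (numerical) zero.

    Runs epochs of (minus settle, plus settle, weight update) over all
    patterns in stream order (optionally shuffled per epoch with ``seed``),
    evaluates the epoch error on frozen weights after each epoch, and stops
    as soon as it falls below the criterion.  Non-convergence within
    ``max_epochs`` is flagged on the result, not raised.  ``callback`` is
    invoked as ``callback(epoch, net)`` after each epoch's update (and once
    with epoch -1 before training), e.g. to snapshot weights.
    """
    learning = net.learning
    max_epochs = learning.max_epochs if max_epochs is None else max_epochs
    criterion = learning.criterion if criterion is None else criterion
    if max_epochs < 1:
        raise ValueError("max_epochs must be >= 1")
    mossy_name, climbing_name = net.input_layers[0], net.input_layers[1]
    rng = np.random.default_rng(seed)
    records: List[TrainingRecord] = []
    converged = False
    per_epoch = net.dynamics.update_mode == "per_epoch"
    if callback is not None:
        callback(-1, net)
    out_name = net.output_layer
    for epoch in range(max_epochs):
        if per_epoch:
            # batched epoch: settle all patterns at once, measure the
            # expectation-phase error, and update from the epoch-mean deltas.
            # At criterion the loop stops *before* updating, so the returned
            # weights are exactly the ones that achieved the recorded error.
            clamps = {mossy_name: tset.mossy, climbing_name: tset.climbing}
            dynamics.settle(net, clamps, phase="minus")
            err = association_error(net.layer(out_name).y_minus, tset.targets,
                                    err_tol=learning.err_tol)
            if err < criterion:
                records.append(TrainingRecord(epoch=epoch, error_pct=err,
                                              max_weight_change=0.0))
                if callback is not None:
                    callback(epoch, net)
                converged = True
                break
            _plus_phase(net, tset.targets, clamps)
            max_change = dynamics.apply_learning(net)
        else:
            order = np.arange(len(tset))
            if learning.shuffle:
                rng.shuffle(order)
            max_change = 0.0
            for idx in order:
                clamps = {
                    mossy_name: tset.mossy[idx], climbing_name: tset.climbing[idx],
                }
                dynamics.settle(net, clamps, phase="minus")
                _plus_phase(net, tset.targets[idx], clamps)
                change = dynamics.apply_learning(net)
                max_change = max(max_change, change)
            err = epoch_error(net, tset)
            if err < criterion:
                converged = True
        records.append(TrainingRecord(epoch=epoch, error_pct=err,
                                      max_weight_change=max_change))
        if callback is not None:
            callback(epoch, net)
        if converged:
            break
    return TrainingResult(network=net, records=records, converged=converged)


def detect_local_minimum(records: List[TrainingRecord], tolerance: float,
                         criterion: float = 5e-7) -> bool:
    """True when learning has stalled above criterion.

    A local minimum is declared when the latest epoch's maximum absolute
    weight change is strictly below ``tolerance`` while the error is still
    above the convergence criterion.
    """
    if len(records) < 2:
        raise ValueError("need at least two training records")
    last = records[-1]
    return last.max_weight_change < tolerance and last.error_pct > criterion
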