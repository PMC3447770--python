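"""Study orchestration: trend fitting, the Hull ISI test, and the full study.

*Trend fitting* classifies each degradation curve as linear or sublinear by
comparing least-squares fits of the trial-mean error against removed
fraction f:

    linear:       y = a + b * f
    logarithmic:  y = a + b * ln(1 + c * f)

with the inner scale ``c`` fixed to (number of steps) / (max fraction) so
both fits are linear in their parameters; a curve is called sublinear when
the logarithmic R^2 exceeds the linear R^2 by at least a configurable margin.

*Hull's test* probes the learned puff/buzz association as the inter-stimulus
interval (ISI) between the mossy (buzz) and climbing (puff) streams grows
from 0 to 3 s.  At training checkpoints (start / middle / end) the network is
evaluated on ISI-shifted stimuli and its association strength is compared
against a reference stimulus trace peaking near 0.25 s.  Association
strength at one ISI is the retention of the originally timed conditioned
response, rescaled so that chance-level output maps to zero:

    S(isi) = max(0, 1 - 2 * mean |target_original - output|)

*The full study* runs per-type degradation for all six lesionable cell
types, the granule-small (x0.1) variant and size-weighted random
degeneration, fits trends, machine-checks the proximity ordering, runs
Hull's test and writes all artifacts (CSV curves, summary table, JSON
manifest) to an output directory.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import dynamics
from .circuit import MicrozoneConfig, build_microzone, default_config, scale_group
from .lesions import (
    RANDOM, DegradationCurve, build_schedule, degrade_trained, prepare_trial,
    random_pool_schedule,
)
from .stimuli import generate_training_set, shift_stimuli
from .training import association_error, train_to_criterion

LESION_GROUPS = ("mossy_fibers", "climbing_fibers", "granule", "golgi",
                 "basket", "purkinje")


# ---------------------------------------------------------------------------
# trend fitting
# ---------------------------------------------------------------------------

@dataclass
class TrendFit:
    curve_id: str
    linear: Dict[str, float] = field(default_factory=dict)       # intercept, slope, r2
    logarithmic: Dict[str, float] = field(default_factory=dict)  # intercept, coef, r2, inner_scale
    classification: Optional[str] = None  # linear | sublinear | None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "curve_id": self.curve_id, "linear": self.linear,
            "logarithmic": self.logarithmic,
            "classification": self.classification, "degenerate": self.degenerate,
        }


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0
    return max(0.0, 1.0 - ss_res / ss_tot)


def fit_trend(curve: DegradationCurve, r2_margin: float = 0.02) -> TrendFit:
    """Least-squares linear and logarithmic fits of a degradation curve."""
    m = curve.mean_errors
    keep = np.isfinite(m)
    f, y = curve.fractions[keep], m[keep]
    if f.size < 4:
        raise ValueError("need at least 4 measured steps to fit a trend")
    fit = TrendFit(curve_id=curve.group)
    if np.ptp(y) < 1e-12:
        fit.degenerate = True
        return fit
    b_lin, a_lin = np.polyfit(f, y, 1)
    r2_lin = _r2(y, a_lin + b_lin * f)
    c = f.size / max(curve.fractions[-1], 1e-12)
    g = np.log1p(c * f)
    b_log, a_log = np.polyfit(g, y, 1)
    r2_log = _r2(y, a_log + b_log * g)
    fit.linear = {"intercept": float(a_lin), "slope": float(b_lin), "r2": r2_lin}
    fit.logarithmic = {"intercept": float(a_log), "coef": float(b_log),
                       "r2": r2_log, "inner_scale": float(c)}
    fit.classification = "sublinear" if r2_log - r2_lin >= r2_margin else "linear"
    return fit


# ---------------------------------------------------------------------------
# Hull's stimulus-trace test
# ---------------------------------------------------------------------------

def hull_reference_trace(isi: np.ndarray, t_peak: float = 0.25,
                         amplitude: float = 1.0) -> np.ndarray:
    """Parametric stimulus trace A * (t / t0) * exp(1 - t / t0), peak at t0."""
    t = np.asarray(isi, dtype=float)
    return amplitude * (t / t_peak) * np.exp(1.0 - t / t_peak)


@dataclass
class HullResult:
    isi_grid: np.ndarray
    strengths: np.ndarray        # (n_checkpoints, n_isi)
    reference: np.ndarray        # (n_isi,)
    checkpoints: Sequence[float]
    divergences: np.ndarray      # (n_checkpoints,), percent

    def to_dict(self) -> dict:
        return {
            "isi_grid": self.isi_grid.tolist(),
            "checkpoints": list(self.checkpoints),
            "strengths": self.strengths.tolist(),
            "reference": self.reference.tolist(),
            "divergences_pct": self.divergences.tolist(),
        }


def association_strength(net, tset, reference_targets: np.ndarray) -> float:
    """Retention of the originally timed conditioned response, in [0, 1].

    Mean absolute deviation of the expectation-phase output from the
    reference targets, rescaled so that chance-level output (deviation 0.5 on
    one-hot targets) maps to zero and a perfect response to one.
    """
    from .training import _clamps
    out_name = net.output_layer
    dynamics.settle(net, _clamps(net, tset), phase="minus")
    mae = float(np.mean(np.abs(reference_targets - net.layer(out_name).y_minus)))
    return max(0.0, 1.0 - 2.0 * mae)


def run_hull_test(
    config: MicrozoneConfig,
    isi_grid: Optional[Sequence[float]] = None,
    checkpoints: Sequence[float] = (0.0, 0.5, 1.0),
    seed: int = 0,
    reference: Optional[np.ndarray] = None,
    max_epochs: Optional[int] = None,
) -> HullResult:
    """Evaluate the model against the Hull stimulus trace across training.

    The network is trained once; weight snapshots are captured at the given
    fractions of the total training duration (0 = untrained).  At each
    checkpoint the network is evaluated on climbing-stream shifts covering
    the ISI grid (0 through 3 s inclusive), and the divergence from the
    reference trace is the mean absolute strength difference, in percent.
    """
    if isi_grid is None:
        dt = config.stimuli.sample_dt
        isi_grid = np.arange(0.0, 3.0 + 1e-9, dt)
    isi_grid = np.asarray(isi_grid, dtype=float)
    if not (math.isclose(isi_grid[0], 0.0) and math.isclose(isi_grid[-1], 3.0)):
        raise ValueError("isi grid must cover 0 through 3 seconds")
    ref = (hull_reference_trace(isi_grid) if reference is None
           else np.asarray(reference, dtype=float))

    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(7,))
    w_ss, m_ss = ss.spawn(2)
    net = build_microzone(config, seed=w_ss)
    tset = generate_training_set(config, seed=np.random.default_rng(m_ss))

    snapshots = []
    def capture(epoch, network):
        snapshots.append(network.weight_snapshot())
    result = train_to_criterion(net, tset, max_epochs=max_epochs, callback=capture)
    # snapshot i corresponds to i epochs of training (0 = untrained)
    total = len(snapshots) - 1
    picks = [min(total, int(round(c * total))) for c in checkpoints]

    strengths = np.zeros((len(checkpoints), isi_grid.size))
    for ci, pick in enumerate(picks):
        net.restore_weights(snapshots[pick])
        for ii, isi in enumerate(isi_grid):
            shifted = shift_stimuli(tset, float(isi))
            strengths[ci, ii] = association_strength(net, shifted, tset.targets)
    net.restore_weights(snapshots[-1])
    divergences = 100.0 * np.mean(np.abs(strengths - ref[None, :]), axis=1)
    return HullResult(isi_grid=isi_grid, strengths=strengths, reference=ref,
                      checkpoints=checkpoints, divergences=divergences)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

@dataclass
class ExperimentReport:
    curves: Dict[str, DegradationCurve]
    trends: Dict[str, TrendFit]
    hull: Optional[HullResult]
    ordering: dict
    summary: pd.DataFrame
    manifest: dict

    def curve_names(self) -> List[str]:
        return list(self.curves)


def check_ordering(final_errors: Dict[str, float]) -> dict:
    """Machine-check of the proximity-to-output claim at maximal removal."""
    pc = final_errors.get("purkinje", np.nan)
    others = {g: e for g, e in final_errors.items()
              if g not in ("purkinje", RANDOM, "granule_small")}
    intrinsic = {g: final_errors[g] for g in ("granule", "golgi", "basket")
                 if g in final_errors}
    out = {
        "final_errors": {k: float(v) for k, v in final_errors.items()},
        "purkinje_greatest": bool(np.all([pc > e for e in others.values()])),
        "purkinje_over_basket": bool(pc > final_errors.get("basket", np.inf)),
        "purkinje_over_granule_4x": bool(
            pc >= 4.0 * final_errors.get("granule", np.inf)),
        "granule_least_intrinsic": bool(
            "granule" in intrinsic
            and final_errors["granule"] <= min(intrinsic.values())),
    }
    return out


def run_full_study(
    config: Optional[MicrozoneConfig] = None,
    n_trials: int = 100,
    base_seed: int = 0,
    output_dir=None,
    max_epochs: Optional[int] = None,
    measure_steps: Optional[Sequence[int]] = None,
    include_hull: bool = True,
    schedule_mode: str = "percent",
) -> ExperimentReport:
    """Run every degradation experiment plus Hull's test and write artifacts.

    One network is trained per trial and shared across all damage types
    (damage is applied to independent copies), mirroring the study design of
    lesioning a single conditioned animal in multiple ways.  The
    granule-small variant (granule count scaled by 0.1) trains its own
    networks.  Trials whose training does not converge are excluded from the
    means and counted in the manifest.  ``measure_steps`` may be ``None``
    (measure every step), the string ``"final"`` (only the intact baseline
    and the maximal-removal step of each schedule), or an explicit list of
    step indices.
    """
    config = config or default_config()
    out = None
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)

    schedules = {g: build_schedule(g, config, mode=schedule_mode) for g in LESION_GROUPS}
    schedules[RANDOM] = random_pool_schedule(config)
    small_config = scale_group(config, "granule", 0.1)
    small_schedule = build_schedule("granule", small_config, mode=schedule_mode)

    def steps_for(schedule):
        if isinstance(measure_steps, str) and measure_steps == "final":
            return [0, len(schedule.cumulative_counts)]
        return measure_steps

    trial_rows = {name: [] for name in list(schedules) + ["granule_small"]}
    excluded = {name: 0 for name in trial_rows}

    for trial in range(n_trials):
        result, tset, rng = prepare_trial(config, base_seed, trial, max_epochs)
        for name, schedule in schedules.items():
            if not result.converged:
                excluded[name] += 1
                trial_rows[name].append(
                    np.full(len(schedule.cumulative_counts) + 1, np.nan))
                continue
            trial_rows[name].append(degrade_trained(
                result.network, tset, schedule, rng,
                measure_steps=steps_for(schedule)))
        # independent granule-small trials (separate architecture)
        sres, stset, srng = prepare_trial(small_config, base_seed + 10_000, trial,
                                          max_epochs)
        if not sres.converged:
            excluded["granule_small"] += 1
            trial_rows["granule_small"].append(
                np.full(len(small_schedule.cumulative_counts) + 1, np.nan))
        else:
            trial_rows["granule_small"].append(degrade_trained(
                sres.network, stset, small_schedule, srng,
                measure_steps=steps_for(small_schedule)))

    curves: Dict[str, DegradationCurve] = {}
    for name in trial_rows:
        schedule = small_schedule if name == "granule_small" else schedules[name]
        curves[name] = DegradationCurve(
            group=name, fractions=schedule.fractions,
            trial_errors=np.vstack(trial_rows[name]),
            seeds=[int(base_seed), n_trials], excluded_trials=excluded[name],
        )

    trends: Dict[str, TrendFit] = {}
    for name, curve in curves.items():
        measured = np.isfinite(curve.mean_errors).sum()
        if measured >= 4:
            trends[name] = fit_trend(curve)

    final_errors = {name: c.final_mean_error for name, c in curves.items()}
    ordering = check_ordering(final_errors)

    hull = None
    if include_hull:
        hull = run_hull_test(config, seed=base_seed, max_epochs=max_epochs)

    summary = summarize_table(config, curves, schedule_mode=schedule_mode)
    manifest = {
        "base_seed": int(base_seed), "n_trials": int(n_trials),
        "config_hash": config.hash(),
        "max_epochs": max_epochs,
        "schedule_mode": schedule_mode,
        "excluded_trials": excluded,
        "curves": {name: {"steps": len(c.fractions) - 1,
                          "final_mean_error_pct": final_errors[name]}
                   for name, c in curves.items()},
        "ordering": ordering,
        "hull_divergences_pct": None if hull is None else hull.divergences.tolist(),
    }

    report = ExperimentReport(curves=curves, trends=trends, hull=hull,
                              ordering=ordering, summary=summary,
                              manifest=manifest)
    if out is not None:
        write_report(report, out)
    return report


def summarize_table(config: MicrozoneConfig, curves: Dict[str, DegradationCurve],
                    schedule_mode: str = "percent") -> pd.DataFrame:
    """Summary shaped like the per-cell-type damage table: totals, removed,
    remaining, resulting error at maximal removal."""
    rows = []
    small_cfg = scale_group(config, "granule", 0.1)
    for name, curve in curves.items():
        if name == RANDOM:
            total = sum(config.group(g).count for g in
                        ("granule", "golgi", "basket", "purkinje"))
        elif name == "granule_small":
            total = small_cfg.group("granule").count
        else:
            total = config.group(name).count
        removed = int(round(curve.fractions[-1] * total))
        rows.append((name, total, removed, total - removed,
                     curve.final_mean_error))
    return pd.DataFrame(rows, columns=[
        "group", "total_cells", "cells_removed", "cells_left",
        "resulting_error_pct"])


def write_report(report: ExperimentReport, out: Path) -> None:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    all_rows = []
    for name, curve in report.curves.items():
        curve.to_frame().to_csv(out / f"curve_{name}.csv", index=False,
                                float_format="%.8g")
        all_rows.append(curve.means_frame())
    pd.concat(all_rows, ignore_index=True).to_csv(
        out / "curve_means.csv", index=False, float_format="%.8g")
    report.summary.to_csv(out / "summary_table.csv", index=False,
                          float_format="%.8g")
    with open(out / "trend_fits.json", "w") as fh:
        json.dump({k: v.to_dict() for k, v in report.trends.items()}, fh,
                  indent=2, sort_keys=True)
    if report.hull is not None:
        with open(out / "hull.json", "w") as fh:
            json.dump(report.hull.to_dict(), fh, indent=2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True, default=str)


def plot_report(report: ExperimentReport, out: Path) -> None:
    """Optional matplotlib plots of the degradation curves and Hull test."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out)
    fig, ax = plt.subplots(figsize=(7, 5))
    for name, curve in report.curves.items():
        m = curve.mean_errors
        keep = np.isfinite(m)
        ax.plot(100 * curve.fractions[keep], m[keep], marker="o", label=name)
    ax.set_xlabel("cells removed (%)")
    ax.set_ylabel("association error (%)")
    ax.legend(fontsize=8)
    fig.savefig(out / "degradation_curves.png", dpi=120)
    plt.close(fig)
    if report.hull is not None:
        fig, ax = plt.subplots(figsize=(7, 5))
        h = report.hull
        ax.plot(h.isi_grid, h.reference, "k--", label="reference trace")
        for ci, c in enumerate(h.checkpoints):
            ax.plot(h.isi_grid, h.strengths[ci], marker="o",
                    label=f"training fraction {c:g}")
        ax.set_xlabel("inter-stimulus interval (s)")
        ax.set_ylabel("association strength")
        ax.legend(fontsize=8)
        fig.savefig(out / "hull_test.png", dpi=120)
        plt.close(fig)
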