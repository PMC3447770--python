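"""Rate-coded point-neuron dynamics, kWTA competition, and learning rules.

The membrane potential of every unit relaxes toward the conductance-weighted
mixture of the channel reversal potentials,

    dV_m = tau * sum_c g_c(t) * g_bar_c * (E_c - V_m),

and the rate-code output is the saturating ``x / (x + 1)`` function of the
supra-threshold drive ``x = gain * (V_m - threshold)``: exactly 0 at or
below threshold, graded above it, asymptoting toward 1.  The graded region
is what lets partial cell loss shift downstream responses by partial
amounts instead of all-or-nothing flips.

Learning combines two rules applied to each plastic projection:

* CPCA Hebbian:     dw_ij = eps * y_j * (x_i - w_ij)
* GeneRec (error):  dw_ij = eps * (x_i+ * y_j+  -  x_i- * y_j-)

mixed as ``hebb * cpca + (1 - hebb) * generec``.  For inhibitory projections
the error-driven delta is applied with reversed sign, because raising an
inhibitory weight lowers the receiver's activation; the Hebbian term is
representational and keeps its sign.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional

import numpy as np

from .params import ChannelSet, DynamicsParams
from .state import EXCITATORY, LayerState, NetworkState


class NumericalStateError(RuntimeError):
    """A unit's conductance or potential became non-finite."""


class SettlingError(RuntimeError):
    """Settling diverged or produced non-finite activations."""

    def __init__(self, message: str, cycle: int):
        super().__init__(f"{message} (cycle {cycle})")
        self.cycle = cycle


# ---------------------------------------------------------------------------
# single-unit / array primitives
# ---------------------------------------------------------------------------

def step_membrane(
    v_m: np.ndarray | float,
    conductances: Mapping[str, np.ndarray | float],
    channels: ChannelSet = ChannelSet(),
    params: DynamicsParams = None,
) -> np.ndarray | float:
    """One Euler step of the membrane potential.

    ``conductances`` maps channel names (``excitatory``, ``inhibitory``,
    ``leak``) to time-varying conductances g_c(t) >= 0; missing channels count
    as zero.  The output is clipped to the reversal-potential range
    ``[E_min, E_max]``, which the continuous-time dynamics never leave.
    """
    params = params or DynamicsParams()
    v = np.asarray(v_m)
    if not np.issubdtype(v.dtype, np.floating):
        v = v.astype(np.float64)
    if not np.all(np.isfinite(v)):
        bad = np.argwhere(~np.isfinite(np.atleast_1d(v)))
        raise NumericalStateError(f"non-finite membrane potential at unit index {bad[0]}")
    g_tot = np.zeros_like(v)
    drive = np.zeros_like(v)
    for ch in (channels.excitatory, channels.inhibitory, channels.leak):
        g = conductances.get(ch.name, 0.0)
        g = np.asarray(g)
        if not np.all(np.isfinite(g)) or np.any(g < 0):
            bad = np.argwhere(~(np.isfinite(np.atleast_1d(g)) & (np.atleast_1d(g) >= 0)))
            raise NumericalStateError(
                f"invalid {ch.name} conductance at unit index {bad[0]}"
            )
        g_tot = g_tot + g * ch.g_bar
        drive = drive + g * ch.g_bar * ch.e_rev
    # dV = tau * G * (V_inf - V) with the step factor capped at 1, so very
    # large total conductances land the potential exactly on the equilibrium
    # V_inf instead of overshooting it (the continuous dynamics never do).
    out = v + np.minimum(params.tau * g_tot, 1.0) * (
        np.divide(drive, g_tot, out=v.copy(), where=g_tot > 0) - v
    )
    out = np.clip(out, channels.e_min, channels.e_max)
    return out if out.ndim else out.item()


def rate_activation(
    v_m: np.ndarray | float, params: DynamicsParams = None
) -> np.ndarray | float:
    """Saturating rate-code output in [0, 1): ``x / (x + 1)``.

    ``x = gain * (V_m - threshold)`` clipped below at zero, so the output is
    exactly 0 at or below threshold, rises gradedly and saturates toward 1
    (the classic x-over-x-plus-1 point-neuron rate function).  Monotone
    non-decreasing in V_m for any gain; for large gain a potential slightly
    above threshold drives the output arbitrarily close to 1.
    """
    params = params or DynamicsParams()
    v = np.asarray(v_m)
    if not np.all(np.isfinite(v)):
        raise NumericalStateError("non-finite membrane potential in rate_activation")
    x = np.maximum(params.gain * (v - params.threshold), 0.0)
    out = x / (x + 1.0)
    return out if out.ndim else float(out)


def kwta_inhibition(
    layer: LayerState,
    g_e: np.ndarray,
    g_i_syn: np.ndarray,
    channels: ChannelSet,
    params: DynamicsParams,
) -> np.ndarray:
    """Layer-level inhibitory conductance of the fast kWTA approximation.

    For each unit the inhibition that would hold it exactly at threshold is
    computed from its excitatory drive; the layer conductance is then placed
    between the k-th and (k+1)-th largest of these values, so that at most k
    units can exceed the activation threshold at equilibrium while the
    relative ordering of drives is preserved.  Returns one value per batch
    row (shape ``(batch, 1)``).
    """
    theta = params.threshold
    ex, ih, lk = channels.excitatory, channels.inhibitory, channels.leak
    # inhibition putting each unit exactly at threshold, net of synaptic inhibition
    num = g_e * ex.g_bar * (ex.e_rev - theta) + lk.g_bar * (lk.e_rev - theta)
    g_star = num / (ih.g_bar * (theta - ih.e_rev)) - g_i_syn
    alive = ~layer.lesioned
    n_alive = int(alive.sum())
    k = min(layer.k, n_alive)
    if n_alive == 0:
        return np.zeros((g_e.shape[0], 1), dtype=g_e.dtype)
    d = np.where(alive[None, :], g_star, -np.inf)
    if k <= 0:
        gi = d.max(axis=1, keepdims=True)  # top unit lands exactly at threshold -> all silent
        return np.maximum(gi, 0.0)
    if k >= n_alive:
        return np.zeros((g_e.shape[0], 1), dtype=g_e.dtype)
    part = np.partition(d, (-k - 1, -k), axis=1)
    d_k = part[:, -k]        # k-th largest
    d_k1 = part[:, -k - 1]   # (k+1)-th largest
    gi = d_k1 + params.kwta_pt * (d_k - d_k1)
    return np.maximum(gi, 0.0)[:, None]


# ---------------------------------------------------------------------------
# network-level net input and settling
# ---------------------------------------------------------------------------

def net_input(net: NetworkState, name: str):
    """Excitatory and synaptic-inhibitory conductances of a layer.

    Each projection contributes ``strength * (y_source @ W) / divisor`` where
    the divisor (fan-in times expected source activity) is fixed at build
    time.  Lesioned sources contribute zero through their pinned activations.
    The trainable bias adds to the excitatory conductance, which is clipped at
    zero to stay a valid conductance.
    """
    layer = net.layer(name)
    batch = 1
    for p in net.incoming(name):
        src = net.layer(p.source)
        if src.y is not None:
            batch = src.y.shape[0]
            break
    ge = np.zeros((batch, layer.n), dtype=net.dtype)
    gi = np.zeros((batch, layer.n), dtype=net.dtype)
    for p in net.incoming(name):
        src = net.layer(p.source)
        if src.y is None:
            raise RuntimeError(f"layer {p.source!r} has no activations during settling")
        contrib = (src.y @ p.weights) * (p.strength / p.divisor)
        if p.sign == EXCITATORY:
            ge += contrib
        else:
            gi += contrib
    ge = np.maximum(ge + layer.bias[None, :].astype(net.dtype), 0.0)
    return ge, gi


def settle(
    net: NetworkState,
    clamped: Dict[str, np.ndarray],
    phase: str,
    params: Optional[DynamicsParams] = None,
) -> NetworkState:
    """Run one settling phase and record the final activations.

    ``clamped`` maps layer names to activation arrays of shape ``(n,)`` or
    ``(batch, n)``; clamped layers hold those values exactly (lesioned units
    excepted, which stay at zero).  Free layers start from the leak potential
    and run ``cycles`` iterations of net-input -> kWTA -> membrane step ->
    activation, sweeping layers in their declared (roughly afferent-to-
    efferent) order within each cycle.  The final activations are stored in
    ``y_minus`` or ``y_plus`` according to ``phase``.
    """
    if phase not in ("minus", "plus"):
        raise ValueError(f"phase must be 'minus' or 'plus', got {phase!r}")
    params = params or net.dynamics
    channels = net.channels
    tau = params.tau
    ex, ih, lk = channels.excitatory, channels.inhibitory, channels.leak

    batch = 1
    for arr in clamped.values():
        a = np.atleast_2d(np.asarray(arr))
        batch = max(batch, a.shape[0])

    for name, arr in clamped.items():
        if name not in net.layers:
            raise KeyError(f"clamped group {name!r} does not exist")
        layer = net.layer(name)
        a = np.atleast_2d(np.asarray(arr, dtype=net.dtype))
        if a.shape[1] != layer.n:
            raise ValueError(
                f"clamp for {name!r} has width {a.shape[1]}, layer has {layer.n} units"
            )
        if a.shape[0] == 1 and batch > 1:
            a = np.broadcast_to(a, (batch, layer.n)).copy()
        layer.y = a.copy()
        layer.y[:, layer.lesioned] = 0.0
        layer.v_m = None

    free = [l for l in net.layers.values() if l.name not in clamped]
    for layer in free:
        layer.v_m = np.full((batch, layer.n), lk.e_rev, dtype=net.dtype)
        layer.y = np.zeros((batch, layer.n), dtype=net.dtype)

    for cycle in range(params.cycles):
        max_dy = 0.0
        for layer in free:
            ge, gi_syn = net_input(net, layer.name)
            gi = gi_syn
            if layer.kwta:
                gi = gi + kwta_inhibition(layer, ge, gi_syn, channels, params)
            v = layer.v_m
            g_tot = ge * ex.g_bar + lk.g_bar + gi * ih.g_bar
            v_inf = (
                ge * ex.g_bar * ex.e_rev + lk.g_bar * lk.e_rev
                + gi * ih.g_bar * ih.e_rev
            ) / g_tot
            v = v + np.minimum(tau * g_tot, 1.0) * (v_inf - v)
            v = np.clip(v, channels.e_min, channels.e_max)
            x = np.maximum(params.gain * (v - params.threshold), 0.0)
            y = x / (x + 1.0)
            y[:, layer.lesioned] = 0.0
            if not np.all(np.isfinite(y)) or np.any(np.abs(y) > params.abort_activation):
                raise SettlingError(
                    f"settling failure in layer {layer.name!r}", cycle=cycle
                )
            max_dy = max(max_dy, float(np.abs(y - layer.y).max(initial=0.0)))
            layer.v_m = v
            layer.y = y
        if params.settle_tol > 0 and max_dy < params.settle_tol:
            break

    attr = "y_minus" if phase == "minus" else "y_plus"
    for layer in net.layers.values():
        setattr(layer, attr, None if layer.y is None else layer.y.copy())
    return net


# ---------------------------------------------------------------------------
# learning rules
# ---------------------------------------------------------------------------

def cpca_delta(x_i, y_j, w_ij, eps, correction: float = 1.0):
    """Hebbian (CPCA) weight delta: ``eps * y_j * (x_i - w_ij)``.

    ``correction`` is the multiplicative renormalization for sparse expected
    activity (1.0 = off).  Applying the delta keeps weights within [0, 1]
    because it moves w toward x in [0, 1] with step size ``eps * y <= 1``.
    """
    return correction * eps * np.asarray(y_j) * (np.asarray(x_i) - np.asarray(w_ij))


def generec_delta(x_minus, y_minus, x_plus, y_plus, eps):
    """Error-driven (GeneRec) weight delta.

    ``eps * (x+ y+ - x- y-)``: the difference of pre/post activation products
    between the outcome (plus) and expectation (minus) phases.  Zero whenever
    the two phases agree; swapping the phases negates it exactly.
    """
    return eps * (
        np.asarray(x_plus) * np.asarray(y_plus)
        - np.asarray(x_minus) * np.asarray(y_minus)
    )


def effective_lrate(proj, learning) -> float:
    """Projection learning rate scaled by connection strength, capped."""
    return proj.lrate * min(proj.strength, learning.lrate_cap)


def apply_learning(net: NetworkState) -> float:
    """Update all plastic projections and biases from the recorded phases.

    Uses the phase activations stored by :func:`settle` (``y_minus`` /
    ``y_plus``); with batched phases the update equals the accumulated
    per-pattern deltas computed at fixed weights, divided by the batch size.
    Returns the maximum absolute weight/bias change applied.
    """
    learning = net.learning
    lam = learning.hebb
    max_change = 0.0
    for p in net.projections:
        if not p.plastic:
            continue
        eps = effective_lrate(p, learning)
        if eps == 0.0:
            continue
        src, tgt = net.layer(p.source), net.layer(p.target)
        xm, ym = src.y_minus, tgt.y_minus
        xp, yp = src.y_plus, tgt.y_plus
        b = xm.shape[0]
        dw = np.zeros_like(p.weights)
        if lam < 1.0:
            err = (xp.T @ yp - xm.T @ ym) / b
            dw += (1.0 - lam) * p.sign * err
        if lam > 0.0:
            hebb = (xp.T @ yp) / b - p.weights * (yp.mean(axis=0)[None, :])
            dw += lam * learning.cpca_correction * hebb
        dw *= eps
        if p.mask is not None:
            dw *= p.mask
        p.weights = np.clip(p.weights + dw, 0.0, 1.0)
        max_change = max(max_change, float(np.abs(dw).max(initial=0.0)))
    for layer in net.layers.values():
        if layer.role == "input" or learning.bias_lrate == 0.0:
            continue
        if layer.y_minus is None or layer.y_plus is None:
            continue
        db = learning.bias_lrate * (layer.y_plus - layer.y_minus).mean(axis=0)
        layer.bias = layer.bias + db.astype(layer.bias.dtype)
        max_change = max(max_change, float(np.abs(db).max(initial=0.0)))
    return max_change
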