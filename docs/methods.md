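# Methods

## Scope

`microzone` simulates a single cerebellar microzone as a rate-coded
point-neuron network, trains it on a synthetic eyeblink (puff/buzz)
conditioning task, and then measures how the learned association degrades as
cells of each type are permanently removed from the trained circuit.  The
package covers the model, the task generator, the trainer, the lesion engine
and the study orchestration (degradation curves, trend fits, the Hull
inter-stimulus-interval probe, and a size-weighted random-degeneration
condition).

## Point-neuron model

Each unit holds a membrane potential `V_m` updated from three conductance
channels (excitatory, inhibitory, leak) toward their reversal potentials:

    dV_m = tau * sum_c g_c(t) * gbar_c * (E_c - V_m)

with normalized reversal potentials `E_inhib = 0.15 <= E_leak = 0.30 <
E_excit = 1.00` and maximal conductances `gbar = (1, 1, 0.1)`.  `tau = 0.2`
is the Euler step size.  Because the circuit contains conductances spanning
five orders of magnitude (the climbing-fiber input is ~26,000 times stronger
than baseline) and trainable biases are unbounded, the explicit update is
stabilized by capping the per-step factor: `V <- V + min(tau*G, 1) *
(V_inf - V)` where `G` is the total conductance and `V_inf` the
conductance-weighted equilibrium.  For ordinary conductances this is exactly
the explicit rule; for very large `G` the potential lands on `V_inf` instead
of overshooting it (the continuous dynamics never leave `[E_min, E_max]`).

The rate-code output is the saturating `x/(x+1)` form with a hard zero below
threshold:

    y = x / (x + 1),   x = max(0, gain * (V_m - threshold))

with `threshold = 0.5` and `gain = 50` by default.  The gain was chosen
(once, before the lesion studies) so that parallel-fiber-driven Purkinje
activity is *graded*: much higher gains make every supra-threshold unit
binary, which destroys the readout's feasibility margins; much lower gains
silence the parallel-fiber pathway entirely.  Either extreme makes the model
insensitive to granule/Golgi/basket damage.

Settling runs up to 30 cycles per phase, sweeping layers in afferent order
within each cycle, and exits early when no activation moves by more than
`settle_tol = 1e-4` (a numerical shortcut only).  Non-finite activations
abort with a settling error carrying the cycle index.  Purely feedforward
subnetworks reach their fixed point well within the cycle budget; the
recurrent granule–Golgi loop, by contrast, retains a small damped
oscillation at the cap, so the phase state is defined as the
(deterministic) state after the final cycle rather than a strict
equilibrium.  Training and evaluation both use the same definition, so the
statistic is consistent; this is a known numerical property, not a fault
mode.

## Inhibitory competition

Layers under k-winners-take-all use the fast average-free approximation: for
each unit the inhibitory conductance that would hold it exactly at threshold
is computed from its excitatory drive, and the layer-wide inhibition is
placed a fraction `kwta_pt = 0.25` of the way between the (k+1)-th and k-th
largest of these values, so at most k units can exceed threshold while the
drive ordering is preserved.  Exactly tied boundary drives collapse onto the
threshold (both silent), which keeps the at-most-k contract; the reported
winner set breaks ties by lowest index.

In the default circuit only the granule layer competes (k = 5% of the layer,
165 of 3300).  Golgi and basket cells receive dense, nearly homogeneous
granule input, so rank-based competition degenerates there — every drive
ties at the boundary and the layer silences itself; they are modeled as
feedforward inhibitory gain controls instead.  Purkinje cells are inhibited
by the explicitly modeled basket projection (layer competition would also
mask the per-subgroup climbing-fiber code), and a 2-unit output layer under
10% kWTA would round to k = 0, i.e. silence itself; the deep nuclei are
instead sculpted by the learned Purkinje inhibition.

## Circuit

Canonical counts: 24 mossy fibers, 3 climbing fibers, 3300 granule, 300
Golgi, 130 basket, 15 Purkinje (3 subgroups of 5, each wired to exactly one
climbing fiber), 2 deep-nuclear output units.  Inhibitory projections:
Golgi->granule, basket->Purkinje, Purkinje->deep nuclei; everything else is
excitatory.  Relative strengths: climbing->Purkinje 26,000x, mossy->granule
4x, all others 1x.  A projection's net input is
`strength * sum_i(y_i w_ij) / (fan_in * act_scale_source)`, where the
divisor (fan-in times the source's expected activity mass) is frozen at
build time — removing source cells therefore *reduces* drive rather than
being renormalized away, which is what makes lesions consequential.

Connectivity is all-to-all except where sparse sampling is the defining
feature of the circuit element:

* mossy->granule: fan-in 4 (the classic sparse mossy sampling behind the
  granule layer's combinatorial expansion; with all-to-all wiring all
  granule drives are nearly equal and the kWTA boundary pins every winner at
  zero activation),
* granule->Purkinje and granule->basket: fan-in 330 (10%), so the
  *composition* of the active granule population, not just its total mass,
  shapes each target's drive,
* Golgi->granule: fan-in 10 (glomerular convergence).

`scale_group` scales a group's count (and the fan-ins of its outgoing
sparse projections, proportionally) while preserving the wiring; the kWTA
count is re-derived from the stored fraction at build time.

The granule layer's outgoing activity mass is normalized with
`act_scale = 0.025` (5% winners at roughly half activation) — the
sparse-activity correction, which balances the parallel-fiber drive against
basket inhibition at the Purkinje membrane.

Weights initialize uniformly in [0.25, 0.75], per-projection seeded;
rebuilding with the same seed is bit-identical.  The default dtype is
float32 (the study is insensitive to the extra precision and the settling
cost halves); the dynamics primitives preserve float64 when given float64.

Two wiring choices depart from a literal reading of the source circuit
diagram and are central to the model behaving like a cerebellum rather than
a generic readout:

* The feedforward inhibitory synapses (Golgi->granule, basket->Purkinje)
  are non-plastic.  The circuit's plasticity sites are the parallel-fiber
  and nuclear synapses; with no error signal reaching hidden layers, the
  Hebbian component otherwise drifts these weights toward the (high)
  presynaptic activity and strangles the parallel-fiber pathway.
* The nuclear collateral is climbing->deep-nuclei only.  The output layer
  needs an excitatory drive aligned with the teaching signal (its only
  other afferent is inhibitory), but a direct mossy->nuclei shortcut lets
  the delta rule load the association onto a cortex-bypassing path, making
  the trained behavior insensitive to every cortical lesion.  Both
  collaterals remain available through the configuration file.

## Task

The training set is 140 samples of 27 inputs (24 + 3) and 2 one-hot targets
(3780 scalar training points).  Mossy channels are independent bounded
random walks on [0, 1] (uniform increments within ±0.15, reflecting at the
edges; the stationary marginal is uniform).  Climbing channels step through
the 3-bit reflected Gray sequence cyclically, so consecutive samples differ
in exactly one bit and all 8 patterns appear once per period; a
`table_order` flag reproduces plain binary counting instead (which breaks
the one-bit property and exists only for comparison with the tabular
example).  The target is `(1,0)` while the first climbing bit is 0 and
`(0,1)` once it is 1.  Only the mossy stream is stochastic.

For inter-stimulus-interval experiments, the climbing stream and its
targets are delayed relative to the mossy stream by `round(isi / 0.25 s)`
samples as a cyclic shift; `sample_dt = 0.25 s` places the classic
conditioning optimum at a one-sample shift.

## Training

Each pattern is settled in an expectation (minus) phase with the output
free, and an outcome (plus) phase with the target clamped.  Because the
output layer has no efferent projections, the plus-phase state equals the
minus-phase state with the output replaced by the target; the trainer uses
this shortcut (a full clamped settle gives the identical result and is used
whenever the output layer has efferents).

Weight updates mix the error-driven (GeneRec) and Hebbian (CPCA) deltas,

    dw = eps * [ (1 - hebb) * sign * (x+ y+ - x- y-) + hebb * y(x - w) ]

with `eps = lrate * min(strength, 10)`, `lrate = 0.2`, and the projection
sign applied to the error-driven term (raising an inhibitory weight lowers
the receiver, so its gradient is reversed).  Biases on non-input units learn
by the error-driven rule at the same rate.  The default Hebbian mix is
`hebb = 0.01` — predominantly error-driven, with a small representational
component on the plastic excitatory pathways (the non-plastic feedforward
inhibitory synapses are unaffected).

By default deltas aggregate per epoch: all 140 patterns settle as one
batch, and the applied update equals the accumulated per-pattern deltas
computed at fixed weights (divided by the pattern count).  The per-pattern
(online) mode is available via `update_mode` but at usable learning rates
its weight trajectory oscillates and does not meet the strict stopping rule
below; the batched mode is also roughly fifty-fold faster, which is what
makes 100-trial studies tractable.

The association error is the averaged sum squared error of the
expectation-phase outputs, as a percentage, with the neural-simulator
convention for "the error reached exactly 0%": per-output deviations
strictly below `err_tol = 0.5` count as zero (a deviation of exactly 0.5
counts in full).  Training stops as soon as the epoch error drops below
5e-7 % — zero to six significant figures — and the stop happens *before*
that epoch's update, so the returned weights are exactly the ones that
achieved the recorded error.  Runs that do not reach criterion within
`max_epochs` are flagged as non-convergent (not an exception) and excluded
from downstream lesion averages.

`detect_local_minimum` flags a stalled run: the latest epoch's maximum
absolute weight change strictly below tolerance while the error is still
above criterion.

### Convergence variability

Epochs-to-criterion is strongly seed dependent (roughly thirty to a few
hundred): the readout's feasibility margins are set by the random
parallel-fiber weights, and seeds that land near the feasibility boundary
approach criterion along a slow tail.  Runs that miss the epoch cap are
flagged non-convergent and excluded from lesion averages; the exclusion
count is part of every study manifest.

## Lesion experiments

Cell death marks units as lesioned: activation pinned to zero, no
contribution to any net input, excluded from the kWTA count (k clamps to
the live population).  Removal is permanent; no retraining or plasticity
follows.  Masking a cell is exactly equivalent to zeroing its weight rows
(verified as a test oracle).  Error is measured on the training set itself:
the quantity of interest is the loss of the *trained* association.

Schedules: granule/Golgi/basket lose 1% of the group per step up to 30%
(rounded half-up); mossy fibers one cell per step to 8 of 24; climbing
fibers a single cell of 3; Purkinje one cell per step to 5 of 15.  The
basket row's printed removal total (29) disagrees with the 30% arithmetic
(39); the percentage reading is canonical and `mode="table"` selects the
printed count.  Random degeneration pools the intrinsic types (3300 + 300 +
130 + 15 = 3745 cells; granule share 88%) and removes 1% of the pool per
step, drawing uniformly without replacement, to 30%.

Each experiment averages independently seeded trials (100 by default; the
reduced study uses 10).  Per trial, fresh weight, mossy-stream and
removal-order seeds derive from the base seed via `SeedSequence` spawning;
one trained network per trial is shared across damage types (each type
lesions its own copy), like lesioning one conditioned animal several ways.
Non-convergent trials are recorded and excluded.  Because cumulative uniform
increments compose into a uniform random subset, measuring only the final
step of a schedule is distributionally identical to walking it, and the
acceptance script exploits this; full curves are produced by the study
pipeline.

## Trend analysis

Each trial-mean curve is fit by least squares to a line `y = a + b f` and
to `y = a + b ln(1 + c f)` with the inner scale `c` fixed at
(steps)/(max fraction) so both fits stay linear in their parameters.  A
curve is sublinear when the logarithmic R² exceeds the linear R² by at
least 0.02; constant curves are flagged degenerate and not classified.

## Hull stimulus-trace probe

The reference trace is the parametric `A (t/t0) exp(1 - t/t0)` with
`t0 = 0.25 s`, `A = 1` (substitutable via configuration).  The model is
trained once with per-epoch weight snapshots; at checkpoints 0, 0.5 and 1.0
of the training duration it is evaluated on climbing-stream shifts covering
0–3 s in 0.25 s steps.  Association strength at one shift is the
chance-corrected retention of the *originally timed* conditioned response:

    S(isi) = max(0, 1 - 2 * mean |target_original - output|)

so chance-level output maps to 0 and a perfect response to 1.  Divergence
per checkpoint is the mean absolute difference from the reference, in
percent.

A structural caveat: the climbing sequence is cyclic with period 8 samples
= 2 s, so the teaching signal at a 2 s separation is (nearly) identical to
the unshifted one and the model's association *recurs* there, where the
reference trace has decayed to almost zero.  The probe's divergence
therefore need not decrease monotonically over training for every
configuration; the stimulus encoding has no intrinsic trace decay.  The
test suite checks the qualitative start > middle > end ordering, and this
limitation is the first place to look if it fails.

## Synthetic data: what it does and does not emulate

The generator reproduces the *statistics* the conditioning design needs —
slow bounded contextual drift, sparse one-bit teaching transitions, a
deterministic response mapping — not airpuff/tone physics, spike timing, or
trial-to-trial variability of real conditioning.  Passing tests therefore
show that the circuit model behaves as claimed *under these statistics*;
they do not certify performance on physiological recordings.

## Problem sizes and determinism

The test suite exercises a miniature circuit (granule 80, Golgi 20, basket
10, full-size everything else) that trains in seconds; the reduced
("fast") study scales granule to 330 and uses 10 trials with a 250-epoch
cap; the acceptance script runs the canonical circuit with 10 trials and a
120-epoch cap.
All randomness flows from explicit seeds through `numpy` generators; a
fixed (config, seed) pair reproduces bit-identical networks, training
histories and CSV outputs on the same platform.

## Known limitations

* The learning constants the source material does not specify (gain, kWTA
  fractions, learning rates, the Hebbian mix) dominate the *quantitative*
  per-type error levels; the qualitative structure (Purkinje dominance,
  mild sublinear granule damage, intermediate basket damage) is robust
  across seeds, but matching every printed percentage is not expected.
* Hidden layers receive no error signal in a purely feedforward circuit,
  so GeneRec trains only the nuclear afferents and biases; cortical
  representations are shaped by initialization (and CPCA when enabled).
* Epochs-to-criterion varies widely across seeds (tens to hundreds);
  trials that miss the cap are excluded from lesion averages rather than
  extrapolated.
* No recovery, retraining, excitotoxicity, spiking dynamics, or neuron
  subtype physiology; single microzone only.
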