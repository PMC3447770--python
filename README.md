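# microzone

Rate-coded simulation of a cerebellar microzone — mossy- and climbing-fiber
inputs, granule, Golgi, basket and Purkinje cells, and deep cerebellar
neurons — trained on a synthetic eyeblink-conditioning task and then
subjected to progressive, permanent cell loss to measure how the learned
association degrades.

The package is for computational neuroscientists studying how the *location*
of neurodegeneration within a well-mapped circuit shapes the resulting
functional deficit: diseases such as the spinocerebellar ataxias target
Purkinje cells, prion diseases preferentially kill granule cells, and
vascular insults strike indiscriminately.  The model lets each pattern of
cell death be applied to the same trained circuit and its behavioral cost
measured directly.

## Model

Each neuron is a point unit whose membrane potential relaxes toward the
conductance-weighted mixture of reversal potentials,

    dV_m = tau * sum_c g_c(t) * gbar_c * (E_c - V_m),

with a saturating rate output `y = x/(x+1)`, `x = gain * (V_m - threshold)+`,
and layer-level inhibitory competition via a fast k-winners-take-all
approximation in the granule layer.  Learning combines an error-driven
contrastive rule (GeneRec) with an optional Hebbian component (CPCA):

    dw_ij = eps * [ (1 - hebb) * (x_i+ y_j+ - x_i- y_j-) + hebb * y_j (x_i - w_ij) ]

applied between an expectation phase (output free) and an outcome phase
(output clamped to the target).  The conditioned response lives in the two
deep-nuclear units; the association error is the averaged sum squared error
of the expectation-phase outputs, as a percentage, with per-output
deviations below 0.5 counting as zero (so "trained to 0%" is well defined).

Cell death is modeled by permanently masking units of the trained network —
activation pinned to zero, no net-input contribution, excluded from the
competition count — in 1% increments up to 30% of a group (single cells for
the small groups), averaged over independently seeded trials.  A
size-weighted random-degeneration condition draws cells from the pooled
intrinsic population (3745 cells; a granule cell is hit 88% of the time).

See `docs/methods.md` for the full model description and design rationale.

## Worked example

Train the canonical microzone and remove Purkinje cells one at a time:

```python
import numpy as np
from microzone import (build_microzone, default_config,
                       generate_training_set, train_to_criterion)
from microzone.lesions import build_schedule, degrade_trained

cfg = default_config()
net = build_microzone(cfg, seed=1)
tset = generate_training_set(cfg, seed=2)

result = train_to_criterion(net, tset, max_epochs=250)
print(f"epochs={result.epochs} converged={result.converged}")

sch = build_schedule("purkinje", cfg)          # remove 1..5 of 15 cells
errs = degrade_trained(result.network, tset, sch,
                       np.random.default_rng(0))
for frac, err in zip(sch.fractions, errs):
    print(f"removed {frac:5.1%} -> association error {err:6.2f}%")
```

Output from this exact script (seeds included):

```
epochs=33 converged=True
removed  0.0% -> association error   0.00%
removed  6.7% -> association error   5.53%
removed 13.3% -> association error  10.40%
removed 20.0% -> association error  13.00%
removed 26.7% -> association error  17.68%
removed 33.3% -> association error  21.58%
```

The intact network expresses the association perfectly (0% at step 0);
losing a third of the Purkinje cells costs roughly a fifth of the learned
behavior in this single trial — far more than the same fractional loss of
any other cell type, because Purkinje cells sit immediately upstream of the
circuit output.  Trial-averaged curves, trend classification (linear vs
sublinear), the Hull inter-stimulus-interval probe and the random
degeneration condition are produced by the study driver:

```bash
microzone --seed 0 full-study --out results/study --fast   # 10 trials, granule 330
microzone --seed 0 lesion --group granule --trials 100 --out granule.csv
microzone --seed 0 hull
```

`full-study` writes per-curve CSVs, a summary table (group, total cells,
removed, remaining, resulting error %), trend fits, the Hull result and a
JSON manifest with seeds and the configuration hash.

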