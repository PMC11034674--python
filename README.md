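# adaptlab

Simulation and analysis tools for a question in sensorimotor neuroscience:
is **implicit adaptation** — the automatic recalibration of reaching
movements in response to errors — modulated by the *variability* of the
perturbations a person experiences, or is it a rigid process whose output
depends only on the size of the current error?

The package is built around a **non-linear motor correction function**
M(e): the expected trial-to-trial change in reach angle as a function of the
visual error e (degrees).  M(e) rises roughly in proportion to small errors,
peaks near 7–8°, and declines for large errors.  It is modelled as

    M(e) = kS · p(positive | e) · p(relevant | e)

where `p(positive | e) = ∫ sign(e′) N(e − e′; σv) de′` is the probability
that a visual system with noise σv perceives the error in the correct
direction, and `p(relevant | e) = N(e; σp) / (N(e; σp) + C)` is a
relevance-inference weight that discounts large errors as unlikely to come
from the motor system.  The error-sensitivity form is z(e) = M(e)/e.

Learning is a state-space model over trials n:

    x(n+1) = a·x(n) + b(e, n)·e(n) + εx(n)      y(n) = x(n) + εy(n)

with retention a and error sensitivity b.  Three interchangeable engines
supply b:

| engine   | b(e, n) | history dependence |
|----------|---------|--------------------|
| `nlmc`   | k·M(e)/e, fixed | none |
| `moe`    | starts flat at b0; per 3° bin, grows by β when consecutive errors share a sign, shrinks on sign flips, with retention α (memory of errors) | yes |
| `hybrid` | memory-of-errors updating initialized from k·M(e)/e | yes |

Because a fixed non-linear M(e) makes the *average* correction depend on the
error distribution (Jensen-style sampling bias), high-variance perturbation
schedules produce slower learning and lower asymptotes even with no
history-dependent mechanism at all — which is the confound the analysis
toolkit here is designed to expose.  The package also includes the
experiment designs that separate the accounts (error-clamp schedules whose
error distribution is confined to the linear descending limb of M), a
trial-triplet analysis of error history, grid-search fitting of the hybrid
model with a participant-level bootstrap, preprocessing of raw trial tables,
and synthetic-data generators with known ground truth standing in for the
behavioural datasets.

## Worked example

```python
from adaptlab import (ModelParams, make_clamp_schedule, simulate_cohort,
                      tsay_like_truth, error_sensitivity, calibrate_sim_scale)

truth = tsay_like_truth()                 # planted correction function
print(error_sensitivity(30.0, truth))     # 0.0092  (baseline z at 30 deg)
print(calibrate_sim_scale(truth, 0.037, 30.0))  # 4.0  (gain matching b(30)=0.037)

nlmc = ModelParams(engine="nlmc", sim_scale=3.0, motor_noise_sd=3.0)
for variance in ("zero", "high"):
    factory = lambda s, v=variance: make_clamp_schedule("exp1", v, s)
    summary, _ = simulate_cohort(factory, nlmc, truth, n_participants=100, seed=0)
    print(variance, round(summary.asymptote, 2), round(summary.asymptote_sem, 2))
```

prints

```
zero 25.59 0.04
high 14.7 0.21
```

With the clamp distribution centered on the concave region of M(e)
(mean 12°), the history-free model alone produces a markedly lower
asymptote under high variance (14.70° vs 25.59°): averaging a concave
function over a wide error distribution lowers the mean correction.  Running
the same schedule through the memory-of-errors engine
(`ModelParams(engine="moe", motor_noise_sd=3.0)`) gives an asymptote of
289.82° — under clamped feedback the error never shrinks, so sign-consistent
sensitization compounds without bound, a qualitatively implausible
prediction that the fixed-correction-function account does not make.

A thin CLI wraps the main entry points:

```bash
adaptlab synth --design exp1 --engine nlmc --n 40 --seed 0 --out data/
adaptlab simulate --design albert6 --variance high --engine nlmc --n 100 --seed 0 --out sim/
adaptlab triplets --in data/exp1_nlmc.csv --window 2 --out triplets/
adaptlab fit --data data/exp1_nlmc.csv --mode coarse_fine --out fit.json
```

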