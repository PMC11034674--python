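# Methods

## The motor correction function

The core object is the expected single-trial motor correction M(e) to a
visual error of size e (degrees), modelled as the product of a
perceived-direction factor and a relevance factor:

- `prob_positive(e; σv) = ∫₋₁₈₀¹⁸⁰ sign(e′) N(e − e′; σv) de′` — a visual
  system with Gaussian noise σv sometimes mis-perceives the *direction* of a
  small error; the signed expectation rises from 0 at e = 0 toward ±1, which
  produces the proportional rise of M over small errors.
- `prob_relevant(e; σp, C) = N(e; σp) / (N(e; σp) + C)` — large errors are
  discounted as unlikely to reflect miscalibration of the motor system.  The
  Gaussian here is a pdf evaluated in degree units, so C carries density
  units (deg⁻¹); it is documented rather than rescaled.  An overall
  relevance scale S is not separately identifiable from the gain k and the
  two are always estimated as one product, `kS`.

M(e) = kS · prob_positive · prob_relevant is antisymmetric, peaks in the
7–8° range for the parameter regime used here, and declines for large
errors.  Error sensitivity is z(e) = M(e)/e; z(0) is defined by the
symmetric small-e limit, evaluated at e = ±0.01° and averaged.

Alternative correction shapes (saturating, declining, piecewise-linear) can
be supplied anywhere a `CorrectionParams` is accepted, as a plain callable
M(e); the variance-effect logic is a property of non-linearity itself, not
of this parametric family, and tests exercise that with linear plug-ins.

### Quadrature

All integrals run over ±180° in degrees.  The sign factor in
`prob_positive` is folded analytically into the smooth half-domain
integrand `N(e − e′) − N(e + e′)` on [0, 180], which composite Simpson with
a fixed 0.1° step (a config knob) integrates with O(h⁴) error — about 1e−8
against the probit closed form across σv ∈ [1°, 30°].  A fixed-step rule
applied to the raw signed integrand would be limited to O(h²) by the jump
at e′ = 0 (~4e−4 at σv = 1°), which is why the antisymmetrized form is
used.  The closed form 2Φ(e/σv) − 1 itself ignores the ±180° truncation;
the neglected tail mass reaches ~1e−3 only for σv ≈ 30° at e = 90°, and
comparisons at that scale use the truncated closed form.

Convolution with a perturbation distribution (the expected correction under
a Gaussian or uniform error distribution) uses trapezoid quadrature; the
uniform kernel is integrated on a subgrid aligned with its box support so
that a correction profile linear across the support is reproduced exactly,
and a degenerate distribution (sd = 0, or lo = hi) returns M(e) bit-for-bit.

Trial-loop simulations evaluate M through a cached linear interpolant
tabulated at 0.05° from the same quadrature (interpolation error ~1e−9,
three orders below any tolerance used anywhere).

### Fitting M(e)

`fit_correction` runs bounded nonlinear least squares on (σv, σp, C, kS)
against a median-correction table, with multi-start (default 20 log-uniform
initial points within σv ∈ [0.5, 30], σp ∈ [1, 60], C ∈ [1e−6, 1],
kS ∈ [0.1, 100]); the 4-parameter product model has local minima and a
single start is not trusted.

## State-space learning

x(n+1) = a·x(n) + b(e, n)·e(n) + εx, y(n) = x(n) + εy.  Parameters and
defaults (all dimensionless unless noted):

| parameter | default | meaning |
|---|---|---|
| a | 0.945 | retention factor, per trial |
| b0 | 0.037 | baseline sensitivity (memory-of-errors engines) |
| α | 0.9568 | sensitivity retention rate |
| β | 0.0558 | sensitivity learning rate |
| k (`sim_scale`) | 4.0 | gain applied to M(e); 4.0 matches b(30°) = 0.037 for the planted curve (3.0 is used for the clamp-experiment simulations) |
| bin width | 3° | sensitivity generalization bin |
| εy SD | 3° | motor (output) noise |
| εx SD | 0° | planning noise (kept at 0; it does not differentiate the variance conditions) |

Error semantics: rotation trials experience e = r − x (the error closes as
learning proceeds); clamp trials experience e equal to the clamp angle
regardless of the state; veridical-feedback trials behave as a rotation of
0; no-feedback trials apply retention only.  Motor noise perturbs the
measured reach y only and is never fed back into x.

The sensitivity update after observing the pair (e(n), e(n+1)) is

    b ← b_base + α·(b − b_base) + β·sign(e(n)·e(n+1))

applied to the bin containing e(n), clipped at 0 (a negative sensitivity
would invert corrections), with b_base = b0 for the memory-of-errors engine
and b_base = k·M(center)/center for the hybrid.  The update is written in
explicit recurrence form (previous value decays toward base, then the sign
term is added).  Choices where the mechanism is underdetermined: bins are a
fixed half-open partition [3i, 3(i+1)) of the error axis; only the visited
bin updates by default (decay of unvisited bins is available behind
`decay_unvisited`); sign(0) = 0, so a zero error contributes no
enhancement or attenuation (the retention term still applies); a
no-feedback trial breaks the update chain.  A consequence of the zero
floor worth knowing: under random-sign schedules the clipped chain's
long-run mean sits *above* b0 (the attenuation side saturates at 0 while
enhancement does not), even though the unclipped recursion is exactly
mean-b0; the tests assert both facts separately.

## Schedules and cohorts

Three blocked designs: a rotation design (40 baseline with veridical
feedback, 240 training at 30° fixed or Normal(30°, 12°) per trial, 40
no-feedback trials) and two clamp designs (40 no-feedback + 40 veridical
familiarization trials, then 240 clamp trials; clamp 12° fixed vs
Normal(12°, 12°), or 30° fixed vs Uniform(15°, 45°)).  Gaussian draws are
not truncated beyond clipping at ±180°.  Four targets (±45°, ±135°) cycle
every 4 trials; learning is simulated at a single target per participant
and curves are grouped into 4-trial pseudo-cycles for comparability with
empirical cycle averaging.

Trial-by-trial schedules are permuted blocks of a zero-mean error set; the
default set is {0, ±4, ±8, ±16, ±32}° — nine values, with 0° included so a
"one of each per cycle" block has an odd, sign-balanced composition.

Cohorts get independent seed-sequence substreams per participant (schedule
draws and noise separately).  The asymptote is the mean reach angle over
the final 10 cycles (40 trials) of training — the window length matches the
washout-block length, since "late in learning" has no canonical
definition.  Cohort sizes default to 100 simulated participants.

## Preprocessing

Trials are invalid if movement time exceeds 500 ms or |hand angle| exceeds
70° (strict inequalities: a trial exactly at either bound is valid);
participants with under 70% valid trials are dropped.  Hand angles are
flipped per participant so adaptation (opposite the perturbation) is
positive, with the direction inferred from the signed training
perturbations; zero-mean designs are left unflipped.  Cycle means use valid
trials only; an all-invalid cycle is missing, a trailing partial cycle is
kept and flagged.  Per-target baseline subtraction from the no-feedback
familiarization block exists behind a flag but is off by default —
conservative fidelity to the stated pipeline.

## Trial-triplet analysis

Triplets (n−1, n, n+1) are selected where the flanking errors share a sign
and differ by less than 2° (and trial n+2 exists); overlapping triplets are
all kept, with within-participant averaging absorbing the dependence.
Forgetting-corrected deltas, `y(n) − â·y(n−1)` and `y(n+2) − â·y(n+1)`, are
each aligned by the sign of their driving error so corrections pool across
directions, and the contrast (post − pre) is averaged within participant
per consistency class, then across the cohort.

The retention estimate â is a per-participant output-error fit: for a
candidate a, the latent state implied by the binned-sensitivity state-space
model is linear in (x0, per-bin sensitivities), so those are concentrated
out by linear least squares and a is searched on [0, 1.05] (0.005 grid plus
a bounded local refine).  Regressing y(n+1) directly on the noisy y(n)
would attenuate â severely (errors-in-variables — with 3° motor noise the
naive estimate collapses toward 0); the profile form is consistent because
the noise sits on the output only, and it is exact for noise-free data.
A fixed or group-level a can be substituted via `a_source`.

## Model fitting

The hybrid model is fit by exhaustive grid search over α, β ∈ [0, 1] (step
0.01) and k ∈ [0, 5] (step 0.1), driving the model with the actually
experienced errors, motor noise 0, and summing squared residuals over
participants (and targets).  The search simulates all grid points at once
(states vectorized across points), which keeps the full ~520k-point grid
tractable; a two-stage mode thins the grid 5× and then refines at full
resolution around the top five coarse candidates — several, because the
SSE surface is steep and multi-basined near α ≈ 1 where sensitivity
compounds geometrically.  Exact SSE ties are broken toward the smallest β,
then α, then k, deliberately favouring the history-free special case; in
particular, when β = 0 the α axis ties exactly (α has no influence) and is
reported at 0 with a tie note.

The participant-level bootstrap of (α, β) holds k and the correction
function frozen, resamples participants with replacement within
experiment × condition strata, and refits on the grid.  Since the SSE is a
sum over participants, each participant's SSE surface is computed once and
resamples only re-weight it — algebraically identical to refitting and two
orders of magnitude faster.

The joint fit adds an outer continuous search over (σv, σp, C, kS) in
log-parameter space (bounded differential evolution plus a Nelder-Mead
polish; local multi-start searches demonstrably stall on ridges of this
landscape) around the inner grid.  Only the product of kS with the inner k
is identified; recovery is therefore assessed on the product scale.

`estimate_error_sensitivity_blocked` is deliberately the *naive* estimator
an experimenter can apply to blocked rotation data:
b̂ = (y(n+1) − a·y(n)) / e_obs(n), binned by the observed error
e_obs = r − y.  Because the motor noise in y enters numerator and
denominator with correlated sign, b̂ is biased, and most strongly where the
true error is nearly constant — the zero-variance condition — so identical
true sensitivity in both conditions yields a selectively inflated
zero-variance estimate.  Using the latent error r − x instead would make
the estimator exactly unbiased and hide the phenomenon.  Trials with
|e_obs| < 1° are excluded (the ratio degenerates near zero denominators).

## Synthetic data

No behavioural recordings ship with the package; the generators produce
stand-ins with known ground truth.

The planted correction function (σv = 3°, σp = 22°, C = 0.0218 deg⁻¹, with
kS derived so that 4·M(30°)/30° = 0.037 exactly) was constructed once to
have the three properties reported for empirically estimated functions: a
peak near 7.5° (7.8° here), a monotone-decreasing z(e), and a near-linear
descending limb over 15–45° (E[M(U(15, 45))] − M(30°) ≈ −8e−4°, so the
linear-zone design genuinely predicts a null variance effect).  Median
tables add Gaussian noise to M(e) on the 19-condition error set
(0, ±1.5, ±3.5, ±10, ±18, ±30, ±45, ±60, ±75, ±90°); the default noise of
0.03° matches the sampling precision of the emulated group medians on this
curve's (pre-gain) scale.

Experiment tables emulate: counterbalanced clockwise/counterclockwise
perturbation directions (alternating assignment); lognormal movement times
(median 350 ms, log-SD 0.12, so the natural rate of >500 ms trials is
~0.15%); injected invalid trials at 3% (half slow movements at 520–900 ms,
half outlier angles replaced by ±(70.5–120)°); and a 4% rate of
noncompliant participants whose 45% invalid rate puts them below the
70%-valid inclusion bar, reproducing realistic exclusion counts.  Movement
times and the invalid-trial mechanism are emulation devices, not
measurements.  Every dataset carries a JSON sidecar (engine, parameters,
per-participant signs and flags, seeds) sufficient to regenerate it bit for
bit.

What the generators do *not* emulate: within-movement kinematics, explicit
re-aiming, reaction-time pressure, target-to-target generalization,
attentional drift, or any drift in motor noise over a session.  Passing
tests therefore validate the algorithms and their statistical behaviour
under the stated generative assumptions, not the empirical truth of those
assumptions for any real dataset.

## Problem sizes and runtime

Test and acceptance runs use desk-scale versions of the study conditions:
cohorts of 100 simulated participants for direction checks; 100
participants × 200 cycles (1800 trials) for the triplet discrimination —
comfortably fewer than the 400 × 8000-trial simulations such analyses are
reported with, at the cost of wider Monte-Carlo intervals that the 3-SE
test thresholds already account for; grid-search recovery on 6 noise-free
simulated participants; 100 bootstrap resamples; 100 cohort pairs of 8
participants for the blocked-design bias.  All randomness flows from
explicit seeds via numpy seed sequences; every reported quantity is exactly
reproducible.

## Known limitations

- The hybrid/grid machinery quantizes sensitivity at bin centers; fitting
  it to data generated by the *continuous* history-free engine leaves a
  structural residual (the fit still selects β = 0, but SSE does not reach
  0 and recovered shape parameters absorb some quantization).
- The joint fit's outer parameters are only partially identified from
  blocked clamp designs (errors probe a limited range, and kS trades off
  against k); the bootstrap freezes them for exactly this reason.
- Degenerate inputs: fitting requires ≥ 6 distinct error sizes of both
  signs; retention estimation requires ≥ 50 trials and falls back to a
  configured a = 0.945 on signal-free series; triplets with a zero error
  anywhere in the triple are discarded (sign undefined).
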