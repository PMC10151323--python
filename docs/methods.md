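# Methods

This note documents the models, algorithms and numerical choices behind
`polarhit`, and what the bundled synthetic cohorts do and do not establish.

## The discrete-time competing-risks model

Follow-up time is discretized into 30-day bins with a grid point at time 0
and one every bin width up to the horizon; bin `t` covers days
`((t-1)·30, t·30]` and day 0 falls in bin 0.  With the default horizon of
3,900 days the grid has `T = 131` columns.  For each patient the network
outputs a joint probability mass `y[k][t]` over `K = 3` event types
(acute coronary syndrome, all-cause death, coronary revascularization) and
`T` bins — a single softmax over all `K·T` logits, so
`Σ_{k,t} y[k][t] = 1`.  Derived quantities:

- cumulative incidence `CIF_k(t) = Σ_{s≤t} y[k][s]`,
- event-free survival `S(t) = 1 − Σ_k CIF_k(t)`.

No explicit "no event by horizon" cell is added; the residual mass lives in
bins beyond the observed follow-up.  For this construction to be well
behaved the grid horizon must strictly exceed the last possible censoring
time (otherwise a patient censored in the final bin has zero survival mass
by construction); the default horizon provides years of headroom over the
administrative follow-up window.

### Architecture

Two branches feed a shared trunk:

- image branch: 5-channel 28×36 polar-map stack → two convolution blocks
  (3×3 kernels, stride 1, batch normalization, leaky ReLU with slope 0.01,
  dropout, 2×2 max pooling; 16 then 32 channels by default) → dense layer
  with 512 units;
- clinical branch: 15 features → dense layer with 32 units.

The concatenation passes through a 256-unit shared layer and one 256-unit
layer per event; each head emits `T` logits.  The clinical-only comparator
drops the image branch (and its 512-unit layer) and is otherwise identical,
sharing every output contract.

The network is implemented as a small numpy layer stack with hand-written
backward passes (convolution as nine shifted channel-contractions,
channels-last layout) and an Adam optimizer with optional global
gradient-norm clipping and decoupled weight decay.  Compute is float32 by
default; float64 is available and is used by the finite-difference gradient
tests, which agree with backpropagation to ~1e-9.

### Losses

With discretized outcome `(k_i, t_i)` (k = 0 meaning censored):

- likelihood: mean of `−log y[k_i][t_i]` for events and `−log S(t_i)` for
  censored patients; probabilities are floored at 1e-12 before the
  logarithm (gradient set to zero below the floor);
- ranking: for every event `k` and ordered pair (i, j) with `k_i = k` and
  `t_i < t_j`, the penalty `exp(−(CIF_k(t_i|x_i) − CIF_k(t_i|x_j))/σ)`;
  the mean over valid pairs is used so batch size does not rescale the
  term (the empty-pair case returns 0);
- total: `α·likelihood + (1−α)·ranking`, default `α = 0.5`, `σ = 0.1`.

### Preprocessing

Missing clinical values are imputed with training-set means (continuous)
or modes (categorical; smallest value on tie).  Continuous features are
standardized with training mean/SD (a constant feature is centered only,
with a warning); binary features pass through.  Map pixels are divided by
100.  All statistics are estimated on training rows only and stored in the
fitted estimator for exact reuse at prediction time.

### Training protocol

Stratified 10-fold repeated hold-out: folds preserve the fraction of each
event kind to within one patient per stratum.  Ten models are trained,
each on nine folds, with a randomly selected 20% of its training rows held
out for early stopping (patience on the validation total loss, best
weights restored); the tenth fold is predicted out-of-fold, and the ten
prediction sets concatenate to cover every patient exactly once.  External
evaluation applies all ten models — each with its own stored
imputation/normalization state — and summarizes metrics as mean with
bootstrap confidence intervals.  Optimization uses Adam (batch 256,
learning rate 1e-3 by default); all randomness derives from the
estimator's `random_state`, and runs are bit-reproducible on CPU.

## Evaluation metrics

Censoring is handled by a Kaplan–Meier estimate `Ĝ` of the censoring
survival function (events treated as censored observations of the
censoring time), giving inverse-probability-of-censoring weights
`ŵ_i = 1/Ĝ(τ_i)`.

- Cumulative/dynamic AUC at time `t`: weighted probability that a patient
  failing by `t` outranks a patient still event-free at `t`; ties count
  one half; times with no cases or no controls are reported as NaN, never
  interpolated.  The curve's mean over the first six months (≤183 days)
  is reported as a named summary.  With zero censoring the statistic
  reduces exactly to the fixed-time AUC — this identity is tested.
- Time-dependent concordance: over comparable pairs (i fails at `τ_i`, j
  observed beyond `τ_i`), concordant when `CIF_k(τ_i|x_i) > CIF_k(τ_i|x_j)`;
  with one event type and time-constant scores this is Harrell's C.
- Fixed-time AUC: Mann–Whitney with midrank tie correction on labels from
  the fixed-time rule (events by `t` positive, followed beyond `t`
  negative, censored before `t` excluded; for cause-specific analyses a
  competing first event before `t` is excluded as neither case nor
  observable control).
- DeLong comparison of paired markers via placement values; identical
  markers give difference 0 and p = 1.
- Bootstrap: percentile intervals over 100 patient-level resamples;
  resamples with undefined metrics are redrawn (bounded, logged).

For event-specific metrics, competing first events are censored at their
event time (cause-specific convention).  Evaluation times are restricted
to [first observed event, 95th percentile of follow-up] so `Ĝ` stays
positive.

## The Cox comparator and the perfusion-abnormality score

The multivariable Cox model uses the 15 clinical features plus the stress
perfusion-deficit extent; partial-likelihood maximization with the Efron
tie correction is delegated to lifelines.  Cause-specific fits censor
competing events at their event time; a composite any-event fit is exposed
via `event_kind="MACE"`.  The perfusion-abnormality score is a simplified
surrogate of clinical total-perfusion-deficit quantitation: the percentage
of pixels below 0.7× a normal template.  It is scale-free under joint
rescaling of map and template and, on synthetic maps, rank-correlates
>0.99 with the generator's true defect extent.

## Synthetic cohort generator

The generator emulates the statistical structure the model assumes, with
full oracle access:

- Clinical covariates: marginals chosen to resemble a contemporary
  perfusion-imaging registry (age ≈ 64 ± 12, 57% male, 26% diabetes, 52%
  pharmacologic stress, resting HR ≈ 69 ± 13, LVEF ≈ 60 ± 12 as the
  configurable 15th feature).  A Gaussian copula correlates age with
  resting heart rate (ρ = 0.30) and defect occurrence with prior PCI
  (latent ρ = 0.45); other features are independent.  Missing values are
  injected at 2% into five continuous columns after outcomes are drawn.
- Polar maps: a smooth radial template per channel (normal zones roughly
  75–100 on the 0–100 scale) minus a Gaussian-shaped defect with drawn
  amplitude (25–65), radial/angular widths and location, plus pixel noise
  (SD 2), clipped to [0, 100].  The true extent `E` is the fraction of
  perfusion pixels whose noiseless defect depth exceeds 0.3× the template,
  mirroring the 0.7-threshold surrogate.  40% of patients carry a defect
  by default.
- Outcomes: discrete cause-specific hazards
  `h_k(t|x) = logistic(b_k + β_k'x + γ_k E)` on a 30-day grid to 1,890
  days; the joint hitting-time distribution is sampled exactly (the cell
  probabilities are `h_k(t)·Π_{s<t}(1−Σ_j h_j(s))`), the event day is
  drawn uniformly inside its bin, and independent censoring combines a
  per-bin dropout hazard (0.003) with an administrative window uniform on
  1,095–1,825 days.  Intercepts were calibrated once by simulation at
  n = 40,000 so that observed prevalences over the follow-up window are
  ≈5% death, ≈3% ACS and ≈7% revascularization, and then frozen.
- Oracle: analytic `CIF_k(t|x) = Σ_{s≤t} h_k(s|x)·Π_{u<s}(1−Σ_j h_j(u|x))`,
  satisfying conservation (`Σ_k CIF_k(T−1) + S(T−1) = 1`) exactly.

A second preset (`defect_driven_config`) attenuates clinical effects
(β × 0.3) and amplifies the defect effects (γ = 6/7/9 for ACS, death,
revascularization; defect prevalence 0.6) to create conditions in which
the imaging signal carries most of the prognostic information; it is used
by the model-comparison experiments.

What the generator does **not** emulate: real myocardial anatomy or
camera physics, site effects, time-varying covariates, informative
censoring, or the clinical TPD algorithm.  Passing tests on these cohorts
establish that the estimators recover known structure under the model's
own assumptions — not clinical-grade performance on registry data.

## Explanations and counterfactuals

The explained scalar is the time-averaged cumulative incidence of one
event ("average risk").  The attribution game has 20 atomic players: the
15 clinical features and the 5 polar-map channels (a channel present =
the patient's pixels, absent = a background patient's pixels).  With the
marginal-expectation value function
`v(S) = mean over background of f(hybrid(x, b, S))`, atomic channel
players coincide with summing per-pixel attributions over a channel; the
channel total (sum) is reported by default.  Estimators: exact subset
enumeration whenever grouping reduces the game to ≤12 players, otherwise
a Monte-Carlo permutation estimate (default 128 orderings) whose
contributions sum exactly to `f(x) − E[f]` per permutation, so efficiency
holds for the estimate itself; per-player standard errors are reported.
The background is a fixed-seed sample of 100 training patients.

Waterfall records order players by absolute contribution, truncate to the
top n with an "all others" residual, and carry a running total from the
population expected value to the patient's final value exactly.
Counterfactuals replace named clinical features on the raw scale,
re-normalize with the stored training statistics, and report
`Δ% = 100·(f_before − f_after)/f_before` plus full before/after CIF
curves for all three events (maps unchanged; a zero baseline risk is
signalled as undefined rather than returning a value).

## Problem sizes used by the test suite and acceptance script

Property and oracle tests run on hand-written batches (≤8 patients, ≤5
bins) and tiny network instantiations.  The simulator fidelity check uses
n = 20,000 patients without censoring.  The parameter-recovery study uses
the default study conditions at n = 4,000 with the full 10-fold protocol
and a scaled-down network instantiation (4/8 conv channels, 32-dim image
embedding, 16-dim clinical embedding, 32/16 shared/head widths, five-year
64-column grid, 18 epochs at batch 256 with weight decay 1e-2); the
image-vs-clinical comparison runs the defect-driven preset at n = 1,000;
the acceptance script runs the same pipelines end-to-end at n = 1,200.
Recovery is summarized per fold-model on its own held-out patients and
averaged, the same way the external-testing protocol summarizes its ten
prediction sets; concatenated out-of-fold values are reported alongside
(rank-pooling across ten separately calibrated models is slightly
pessimistic).  These sizes are the package's own defaults for a desk-scale
study; all are configurable.

## Known limitations

- A registry-scale cohort (tens of thousands of patients, thousands of
  events) is needed before the deep model's discrimination advantage over
  linear comparators becomes large; at desk scale the Cox comparator with
  the surrogate deficit extent is a strong baseline, and the recovery
  experiments measure rank agreement with the generator truth rather than
  clinical AUC levels.
- The hitting-time likelihood is proper but weakly informative at low
  event counts; training is correspondingly noise-limited, which the
  methods above mitigate with early stopping, gradient clipping and
  weight decay rather than architecture search.
- DeLong p-values are asymptotic; at very small n the bootstrap oracle in
  the tests is the sharper reference.
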