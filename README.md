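# polarhit

Event-specific, time-resolved risk modelling after cardiac perfusion
imaging (SPECT MPI).

Standard interpretation of myocardial perfusion imaging yields a single
composite risk of "major adverse cardiovascular events" (MACE).  This
package implements a discrete-time competing-risks survival network that
instead predicts, for every patient, the probability of each specific
event — all-cause death, acute coronary syndrome (ACS), and coronary
revascularization — at time 0 and every 30 days up to the follow-up
horizon, directly from a 5-channel 28×36 polar-map stack (perfusion,
motion, thickening, phase, amplitude) plus 15 clinical features.  It is
aimed at methods researchers in imaging-based survival prognostics who
need a complete, inspectable, CPU-reproducible reference pipeline.

## The model

For patient `i` with covariates `x_i`, the network outputs a joint
probability mass over event type and hitting-time bin,

```
y[k][t] = P(event k occurs in bin t | x_i),    softmax over all K·T cells
```

with `K = 3` events and `T = 131` bins by default (30-day bins to 3,900
days), giving the 3×131 per-patient risk surface.  Derived quantities are
the cause-specific cumulative incidence `CIF_k(t) = Σ_{s≤t} y[k][s]` and
event-free survival `S(t) = 1 − Σ_k CIF_k(t)`.  Training minimizes

```
α · L_likelihood + (1−α) · L_ranking
```

where `L_likelihood` is the hitting-time negative log-likelihood
(`−log y[k_i][t_i]` for events, `−log S(t_i)` for censored patients) and
`L_ranking` is the event-specific pairwise penalty
`exp(−(CIF_k(t_i|x_i) − CIF_k(t_i|x_j))/σ)` averaged over comparable
pairs.  The architecture is two-branch: two 3×3 convolution blocks (batch
normalization, leaky ReLU, dropout, 2×2 pooling) and a 512-unit dense
layer for the images, a 32-unit layer for the clinical vector, then a
256-unit shared layer and a 256-unit head per event.  Training follows a
stratified 10-fold repeated hold-out with an inner 20% validation split
per fold for early stopping.

Also included:

- censoring-aware metrics: IPCW cumulative/dynamic AUC curves,
  time-dependent concordance, fixed-time AUC with DeLong comparisons,
  100-resample percentile bootstrap CIs;
- comparators: a clinical-only network (same architecture minus the image
  branch), a multivariable cause-specific Cox model (lifelines, Efron
  ties), and a pixel-threshold surrogate of the total-perfusion-deficit
  score;
- per-patient explanations: Shapley attributions over the 15 clinical
  features plus the 5 map channels as atomic players (exact enumeration
  or Monte-Carlo permutations), waterfall records, individual CIF curves,
  and counterfactual "what-if" simulation of risk-factor modification;
- a synthetic cohort generator with known discrete cause-specific hazards
  and analytic CIF oracles, used throughout the tests.

## Worked example

```python
from polarhit import (
    DeepHitSurvival, TimeGrid, default_config, generate_cohort, train_cv,
    td_concordance,
)

cfg = default_config(n_patients=1200, seed=7, grid=TimeGrid(30, 1890))
cohort, truth = generate_cohort(cfg)
print(cohort.outcomes["event_kind"].value_counts().to_dict())

est = DeepHitSurvival(
    horizon_days=1890, conv_channels=(4, 8), image_dense_width=32,
    clinical_dense_width=16, shared_width=32, head_width=16,
    max_epochs=20, patience=20, weight_decay=1e-2, batch_size=256,
    random_state=0,
)
result = train_cv(cohort, est, k=10, seed=0)
c = td_concordance(result.oof_pmf, cohort.outcomes, "death", result.grid)
print(f"out-of-fold td-concordance (death): {c:.3f}")
```

Output from this exact snippet (a few minutes on one CPU):

```
{'censored': 1008, 'revascularization': 88, 'death': 65, 'ACS': 39}
out-of-fold td-concordance (death): 0.665
```

The first line is the simulated cohort's event mix (≈5% death, ≈3% ACS,
≈7% revascularization over a 3–5-year follow-up window, mirroring
contemporary registry prevalences).  The concordance is the probability
that, of two comparable patients, the one dying earlier was assigned the
higher predicted cumulative incidence of death at that time — 0.5 is
uninformative.

A command-line workflow wraps the same pipeline:

```bash
polarhit simulate --n 500 --seed 0 --out data/
polarhit train --clinical data/clinical.csv --maps data/maps.h5 \
    --outcomes data/outcomes.csv --out run/ --folds 10
polarhit evaluate --run run/ --clinical data/clinical.csv --maps data/maps.h5 \
    --outcomes data/outcomes.csv --out metrics/ --sensitivity-revasc180
polarhit explain --run run/ --clinical data/clinical.csv --maps data/maps.h5 \
    --outcomes data/outcomes.csv --patient P000003 \
    --counterfactual resting_hr=70 --out explain/
```

See `docs/methods.md` for the full model description, the synthetic
cohort's design, and every numerical choice.

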