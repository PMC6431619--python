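# proclens

Dynamic prediction of **task duration** and **final success/failure** from
time-stamped problem-solving process data.

When people solve an interactive task on a computer — for example exploring
a simulated control panel with three sliders — the log file records every
action they take and when they take it. `proclens` answers, at *any* time
`t` while a person is still working: *how much longer will they need, and
will they succeed?* It is aimed at researchers in psychometrics,
educational measurement and learning analytics who work with clickstream /
event-log data, and at anyone who wants a transparent, regression-style
baseline for dynamic prediction on event histories.

## The model

Let `τ_i` be person *i*'s total task time, `y_i ∈ {0,1}` the final outcome,
and `H_i(t)` a *p*-vector of features computed from the actions taken up to
time `t` (counts, rates and indicators of panel actions — see below).
Conditionally on still working at `t` (`τ_i > t`), the model assumes

```
P(Y_i = 1 | H_i(t), T_i > t)        = Φ( b₁ᵀ H_i(t) )          (probit)
log(T_i − t) | H_i(t), T_i > t      ~ N( b₂ᵀ H_i(t), σ² )      (log-normal)
```

with time-constant coefficients `B = (b₁, b₂)` and variance `σ²`. The
parameters are estimated by maximizing a **pooled pseudo-likelihood**: the
conditional likelihood terms are stacked over all persons and a grid of
landmark times `t₁ < … < t_J` (placed at equally spaced quantiles of the
empirical duration distribution) and treated as independent. The
pseudo-likelihood factorizes, so `b₁` is a probit maximum-likelihood fit
and `(b₂, σ²)` a least-squares fit on the pooled table. Prediction is then
available on the whole time continuum:

```
p̂_success(t) = Φ( b̂₁ᵀ H_i(t) ),     τ̂_i(t) = t + exp( b̂₂ᵀ H_i(t) ).
```

Shipped history features (for the three-slider panel task): the action
count `N(t)`, simple-action count `S(t)` (moving exactly one slider),
reset count `R(t)`, repeat count `RP(t)`, their rates `·/t` and positivity
indicators, the vary-one-thing-at-a-time indicator `I_votat` (all three
sliders explored via simple actions), and the time basis `1, t, t², t³`.
Test-set accuracy is summarized per evaluation time by the tie-aware
Mann–Whitney AUC of the success scores and the RMSE of predicted duration,
both over the at-risk set (`τ_i > t`). A stepwise forward selector adds
features by maximal gain in five-fold person-level cross-validated log
pseudo-likelihood.

## Worked example

```python
import numpy as np
from proclens import (SimConfig, simulate_dataset, split, select_grid, fit,
                      predict_at, evaluate_curve)

cfg = SimConfig(n_individuals=2000, seed=8)   # synthetic cohort
ds = simulate_dataset(cfg)
train, test = split(ds, 0.8, seed=8)

grid = select_grid(train.durations, J=9)       # 10%..90% duration quantiles
features = ("const", "I_votat", "N_over_t", "S_pos")
res = fit(train, grid, features)
print(np.round(res.params.b1, 3), np.round(res.params.b2, 3))

rec = test.records[0]
p = predict_at(res.params, rec, 90.0)          # any t, not only grid points
print(p.p_success, p.predicted_duration)

curve = evaluate_curve(res.params, test, [70, 100, 130, 160])
print(curve.to_frame().round(3))
```

Output:

```
grid: [ 77.9  88.3  98.5 110.3 126.8 145.1 171.  209.3 273.2]
b1: [0.272 0.201 0.318 0.444]
b2: [ 4.447 -0.362 -2.214 -0.293]
pred: sim00006  p_success 0.765  predicted_duration 150.6  (actual 208.2, success)
 time  n_at_risk   auc    rmse
 70.0        385 0.643 106.800
100.0        273 0.625 116.238
130.0        195 0.587 124.744
160.0        123 0.570 141.595
```

Reading this: the nine landmark times span the bulk of the duration
distribution; `b1` says that having explored all sliders one-at-a-time
(`I_votat`), acting at a higher rate and having taken a simple action all
raise the predicted success probability on this synthetic cohort, while
`b2 < 0` entries shorten the predicted remaining time. The evaluation
curve shows discrimination above the 0.5 chance level at every time point;
a model using only `1, t, t², t³` (no individual history) scores one common
value for everyone still at risk, so its AUC is exactly 0.5 — the built-in
chance baseline.

The same pipeline runs from the shell:

```bash
proclens simulate --n 400 --seed 7 --out-logs L.csv --out-labels Y.csv
proclens validate --logs L.csv --labels Y.csv
proclens fit      --logs L.csv --labels Y.csv \
                  --features const,I_votat,N_over_t,S_pos --grid-size 9 --out model.json
proclens evaluate --model model.json --logs L.csv --labels Y.csv --out curve.csv
proclens select   --logs L.csv --labels Y.csv --folds 5 --seed 3 --out path.csv
```

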