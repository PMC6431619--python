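# Methods

## The model and its assumptions

`proclens` implements a landmark (event-history) regression for process
data. For person *i* with total task time `T_i`, final outcome
`Y_i ∈ {0,1}` and history-feature vector `H_i(t)`, two conditional models
are specified given that the person is still working at `t`:

* `P(Y_i = 1 | H_i(t), T_i > t) = Φ(b₁ᵀ H_i(t))` — a probit regression;
* `log(T_i − t) | H_i(t), T_i > t` has mean `b₂ᵀ H_i(t)` and variance `σ²`,
  treated as Gaussian (equivalently, remaining time is log-normal).

These are *working* marginal models indexed by a continuous time domain,
not a coherent joint law: the same coefficient vectors are assumed at every
`t`, and pooled likelihood terms across persons and landmark times are
treated as independent. Both assumptions are deliberate simplifications —
they buy a convex, factorized estimation problem and interpretable
coefficients at the price of bias where effects genuinely vary with time
or persons contribute many correlated rows. No within-person correlation
adjustment is applied, and no standard errors are reported: the intended
use is prediction and feature ranking, not inference on coefficients.

Estimation maximizes the pooled log pseudo-likelihood over a landmark grid
`t₁ < … < t_J`. It factorizes exactly into an outcome part (probit
likelihood on all at-risk rows) and a duration part (Gaussian likelihood of
`log(τ_i − t_j)`), so the two blocks are maximized separately:

* `b₁`: probit ML via Newton iterations, relative log-likelihood tolerance
  1e-8, at most 100 iterations, no regularization;
* `b₂`: ordinary least squares; `σ²` is the mean squared residual with
  **no** degrees-of-freedom correction (the pseudo-likelihood's own
  estimating equation);
* the reported total log pseudo-likelihood is the sum of the two parts.

Prediction at any `t` (not only grid points) is
`Φ(b̂₁ᵀ H_i(t))` for success and `t + exp(b̂₂ᵀ H_i(t))` for total
duration; the latter is always larger than `t` by construction.

## Feature conventions

The shipped features for the three-slider panel task follow fixed
conventions, chosen once and applied everywhere:

* **"Up to time t" is closed**: events at exactly `t` count, making
  `H_i(t)` right-continuous between events.
* **Simple action**: an `apply` whose configuration differs from the
  current *reference state* in exactly one slider. The reference state is
  the configuration of the previous `apply`; a `reset` (and the task
  start) sets it to the initial configuration, which is part of the task
  configuration (default `(0,0,0)`) rather than hard-coded.
* An `apply` identical to the reference state counts as an action (`N`)
  but not as a simple action (`S` requires one moved slider).
* **VOTAT indicator** `I_votat`: 1 once each of the three sliders has been
  the moved slider of some simple action — i.e. all three inputs explored
  one-at-a-time.
* **Repeat**: an `apply` whose full slider triple equals that of some
  strictly earlier `apply`; resets are excluded from repeat accounting.
* Reset clicks are included in the action count `N` (the definition of
  "action" covers both panel operations; only the repeat features exclude
  resets explicitly).
* **Rates** divide by the raw landmark time `t`, with `0/0 := 0` at
  `t = 0` (not by time since the first action).

The feature framework is extensible: `register_feature(kind, func)` adds a
named extractor, used e.g. to inject synthetic noise features in selection
experiments. The built-in set is exactly the 13 history features plus the
4 time-basis terms.

## Landmark grid

`select_grid(durations, J)` places landmarks at equally spaced probability
levels `k/(J+1)`, `k = 1..J` of the empirical duration distribution (so
`J = 9` gives the 10%–90% deciles). The empirical quantile convention is
the smallest order statistic whose empirical CDF reaches the level.
Duplicate quantile values are collapsed (with a logged warning, reducing
`J`); a grid that cannot contain `J` distinct informative points raises a
degenerate-grid error. Pooled rows require `τ_i − t_j > 1e-6` s so the log
remaining time stays finite; nearer-boundary rows are dropped with a
warning.

## Evaluation

At each evaluation time the at-risk set is `{i : τ_i > t}`. The outcome
metric is the Mann–Whitney AUC with half-credit for ties (equal to the
probability that a random success outscores a random failure); the
duration metric is the RMSE of predicted total duration. Both are
`None`/`NA` when undefined (a missing class, or an empty at-risk set) —
undefined is a value, not an error. A model whose features depend on `t`
alone gives every at-risk person one common score, hence AUC exactly 0.5:
the chance baseline any history feature must beat. Default evaluation
times are 20 equally spaced points between the 2.5% and 97.5% training
duration quantiles.

## Stepwise selection

Forward selection starts from a user-supplied initial set (classically
`1, t, t², t³`) and greedily adds the candidate with the largest
cross-validated log pseudo-likelihood, stopping when no candidate improves
the incumbent. Design choices:

* CV partitions **persons**, not pooled rows — a held-out person
  contributes all their landmark rows at once; splitting rows would leak
  each person's history across folds.
* The landmark grid is fixed once from the full training set before CV,
  not refitted per fold.
* Fold assignment is a seeded uniform shuffle with near-equal sizes, no
  outcome stratification; argmax ties break by candidate declaration
  order. The whole path is deterministic given the seed.
* A candidate whose fits fail everywhere (e.g. it makes the design
  collinear) is skipped with a logged warning and can never be accepted.

## Synthetic data generator

The generator produces event streams whose `(Y, T)` are linked to the
person's *own* history features exactly as the model assumes — but only at
one **anchor landmark** `t₁`. The marginal conditional models cannot in
general hold simultaneously at every `t` under a single generative law, so
anchoring at one landmark is what makes parameter recovery a well-posed
target: fitting with grid = (anchor) consistently estimates
`(b₁_true, b₂_true, σ²_true)`, while multi-grid fits are only checked for
optimizer correctness, mirroring the approximation status of the model on
real data.

Default configuration (all overridable via `SimConfig` / YAML):

| parameter | default | meaning / rationale |
|---|---|---|
| `n_individuals` | 5000 | mid-size cohort; recovery experiments use this size |
| `action_rate` | 0.15 /s | population mean action rate (≈ 9 expected actions by the 60 s anchor, of order the ~17 actions over ~130 s typical of slider-panel process data) |
| `rate_log_sd` | 1.3 | log-normal person-level spread of the rate. Real cohorts show strongly right-skewed action counts; a homogeneous rate would also leave the `N/t` coefficient barely identified — an a-priori asymptotic-SE analysis at n = 5000 gives worst-case expected absolute coefficient errors ≈ 0.08 at this value, versus ≈ 0.10 with spread 1.0 |
| `p_reset` | 0.1 | occasional resets |
| `p_simple` | 0.7 | most applies move a single slider |
| `anchor_time` | 60 s | near the lower decile of typical durations, so nearly everyone is still at risk |
| `feature_names` | const, I_votat, N_over_t, S_pos | the declared generative feature set |
| `b1_true` | (0.3, 0.5, −1.0, 0.7) | outcome loadings (VOTAT and simple actions help, high action rate hurts) |
| `b2_true` | (4.8, −0.8, −1.4, −0.2) | duration loadings (engaged exploration shortens remaining time) |
| `sigma_true` | 0.7 | log-scale remaining-time noise |
| `slider_values` | −2…2 | slider range of the emulated panel |

Mechanics: per person, a rate is drawn log-normally (mean `action_rate`);
actions arrive as a Poisson process on `(0, anchor]`; each is a reset with
probability `p_reset`, otherwise an apply moving one or two sliders
relative to the current reference state. `H(anchor)` is computed, then
`τ = anchor + exp(b₂ᵀH + ε)` with `ε ~ N(0, σ²)` (so `τ > anchor` always)
and `y ~ Bernoulli(Φ(b₁ᵀH))`. The action stream continues at the same rate
until `τ` (it affects nothing at the anchor but exercises parsing and
features), and an `end` marker is placed at `τ`. All randomness flows from
one seeded generator.

What the generator does **not** emulate: strategy learning or adaptation
over time, fatigue, answer-diagram actions, population mixtures, or any
dependence of the action process on the latent outcome beyond what the
anchor features carry. Passing recovery tests therefore shows the
estimator is correct under the model's own assumptions — not that the
model is correct for any particular real cohort.

## Numerical choices

* Probit Newton iterations run on a column-rescaled design (each column
  divided by its max absolute value) — an exact reparametrization undone
  on return — because the raw `1, t, t², t³` basis at second-scale
  landmarks is catastrophically ill-conditioned otherwise. The duration
  least-squares solve uses the same rescaling.
* Separation and non-convergence of the probit fit are reported in the
  returned convergence status, never silently ignored and never raised as
  exceptions; single-class tables and rank-deficient designs are errors
  that name the offending columns.
* `σ̂² = 0` with a nonzero residual makes the evaluated log
  pseudo-likelihood `−∞` (explicit sentinel); with all residuals exactly
  zero it is `+∞` (degenerate point mass).
* An empty pooled table (nobody at risk anywhere on the grid) evaluates
  the empty product: log pseudo-likelihood 0.
* Train/test splitting assigns `floor(fraction·N)` persons to the first
  part of a seeded permutation. (Note: on a cohort of 16,872 this yields
  13,497/3,375, not the 13,498/3,374 sometimes quoted for comparable
  analyses; the floor rule is the documented convention here.)

## Problem sizes used in the shipped experiments

The test suite runs the recovery experiment at n = 5000 for 20 seeds, the
estimating-equation oracle comparison on 200 random tables of at most 50
rows, the selection experiment at n = 2000 for 20 replicates with 5 folds,
and the feature-operator oracle on 1000 random records — sizes chosen so
the full suite completes in a few minutes on one CPU while keeping Monte
Carlo error well inside the asserted tolerances.

## Known limitations

* Time-constant coefficients: effects that genuinely change over time are
  averaged, with more weight at earlier landmarks (later landmarks have
  fewer at-risk rows).
* The log-normal remaining-time likelihood is a working choice; only the
  conditional mean and variance are substantively assumed.
* No uncertainty quantification (bootstrap/CV-based error bars) for
  coefficients or metrics.
* Homoscedastic `σ²` across time and persons.
* Single-task analysis only; no cross-task or multi-session support.
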