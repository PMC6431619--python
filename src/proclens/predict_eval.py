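"""Dynamic prediction at arbitrary times and time-indexed test metrics.

Given fitted coefficients, at any time ``t`` during a person's attempt the
model predicts

* the success probability ``Phi(b1' H_i(t))`` and
* the total duration ``t + exp(b2' H_i(t))``

for every person still at risk (``tau_i > t``).  Test-set performance is
summarized per evaluation time by the Mann-Whitney AUC of the success
scores (ties get half credit) and the RMSE of the predicted duration, both
restricted to the at-risk set.  When a metric is undefined at a time point
(a missing outcome class, or nobody at risk) it is reported as ``None``
(``NaN``/``NA`` in tabular output), never raised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .eventlog import Dataset, ProcessRecord
from .features import DEFAULT_INITIAL_CONFIG, FeatureSpec, as_specs, feature_vector
from .model import ModelParams

__all__ = [
    "Prediction",
    "EvalCurve",
    "predict_at",
    "evaluate_auc",
    "evaluate_rmse",
    "evaluate_curve",
    "default_eval_times",
]


@dataclass(frozen=True)
class Prediction:
    person_id: str
    at_time: float
    p_success: float
    predicted_duration: float


def predict_at(
    params: ModelParams,
    rec: ProcessRecord,
    t: float,
    specs: Sequence[FeatureSpec | str] | None = None,
    initial_config: tuple[int, int, int] = DEFAULT_INITIAL_CONFIG,
) -> Prediction:
    """Predict final outcome probability and total duration at any time t.

    Prediction is available on the whole time continuum, not only at the
    estimation grid points.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if specs is None:
        specs = params.spec_names
    specs = as_specs(specs)
    names = tuple(s.name for s in specs)
    if names != params.spec_names:
        raise ValueError(
            f"feature mismatch: params built for {params.spec_names}, got {names}"
        )
    h = feature_vector(rec, t, specs, initial_config).values
    p_success = float(norm.cdf(h @ params.b1))
    predicted_duration = float(t + np.exp(h @ params.b2))
    return Prediction(
        person_id=rec.person_id,
        at_time=float(t),
        p_success=p_success,
        predicted_duration=predicted_duration,
    )


def evaluate_auc(scores: Sequence[float], outcomes: Sequence[int]) -> float | None:
    """Mann-Whitney AUC of scores against binary outcomes, ties half-credited.

    Equals the probability that a randomly chosen success outscores a
    randomly chosen failure.  Returns ``None`` when either class is absent.
    The caller is expected to have restricted to the at-risk set.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if scores.shape != y.shape:
        raise ValueError("scores and outcomes must have equal length")
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        return None
    ranks = rankdata(scores)  # average ranks give half credit to ties
    return float((np.sum(ranks[y == 1]) - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate_rmse(
    predicted_durations: Sequence[float], durations: Sequence[float]
) -> float | None:
    """Root mean squared error of predicted total duration over the at-risk set.

    Returns ``None`` when nobody is at risk.
    """
    pred = np.asarray(predicted_durations, dtype=float)
    tau = np.asarray(durations, dtype=float)
    if pred.shape != tau.shape:
        raise ValueError("predictions and durations must have equal length")
    if pred.size == 0:
        return None
    return float(np.sqrt(np.mean((tau - pred) ** 2)))


@dataclass(frozen=True)
class EvalCurve:
    """AUC and RMSE indexed by evaluation time, with the at-risk count."""

    times: np.ndarray
    auc: np.ndarray         # NaN where undefined
    rmse: np.ndarray        # NaN where undefined
    n_at_risk: np.ndarray

    def __post_init__(self) -> None:
        for name in ("times", "auc", "rmse"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "n_at_risk", np.asarray(self.n_at_risk, dtype=int))
        n = self.times.size
        if not (self.auc.size == self.rmse.size == self.n_at_risk.size == n):
            raise ValueError("curve vectors must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_at_risk": self.n_at_risk,
                "auc": self.auc,
                "rmse": self.rmse,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, na_rep="NA")


def evaluate_curve(
    params: ModelParams,
    test: Dataset,
    times: Sequence[float],
    specs: Sequence[FeatureSpec | str] | None = None,
    initial_config: tuple[int, int, int] = DEFAULT_INITIAL_CONFIG,
) -> EvalCurve:
    """Evaluate AUC and RMSE at each time, restricted to the at-risk set."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a nonempty 1-D vector")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    auc = np.full(times.size, np.nan)
    rmse = np.full(times.size, np.nan)
    n_at_risk = np.zeros(times.size, dtype=int)
    for k, t in enumerate(times):
        at_risk = [rec for rec in test if rec.duration > t]
        n_at_risk[k] = len(at_risk)
        if not at_risk:
            continue
        preds = [predict_at(params, rec, t, specs, initial_config) for rec in at_risk]
        scores = [p.p_success for p in preds]
        outcomes = [rec.outcome for rec in at_risk]
        a = evaluate_auc(scores, outcomes)
        if a is not None:
            auc[k] = a
        r = evaluate_rmse([p.predicted_duration for p in preds], [rec.duration for rec in at_risk])
        if r is not None:
            rmse[k] = r
    return EvalCurve(times=times, auc=auc, rmse=rmse, n_at_risk=n_at_risk)


def default_eval_times(train_durations: Sequence[float], n_points: int = 20) -> np.ndarray:
    """Equally spaced evaluation times between the 2.5% and 97.5% duration quantiles."""
    d = np.asarray(train_durations, dtype=float)
    if d.size == 0:
        raise ValueError("durations must be nonempty")
    lo, hi = np.quantile(d, [0.025, 0.975])
    if not lo < hi:
        raise ValueError("degenerate duration distribution")
    return np.linspace(lo, hi, n_points)
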