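"""Pooled pseudo-likelihood estimation of the two-part landmark model.

For a person still working at time ``t`` (``tau_i > t``), the model assumes

* probit outcome:      ``P(Y_i = 1 | H_i(t), T_i > t) = Phi(b1' H_i(t))``
* log-normal remaining time:
  ``log(T_i - t) | H_i(t), T_i > t  ~  Normal(b2' H_i(t), sigma^2)``

with coefficients constant over time.  Estimation pools every at-risk
(person, grid point) pair into one table and maximizes the pooled
pseudo-likelihood, which factorizes into a probit likelihood for ``b1`` and
a Gaussian (linear-regression) likelihood for ``(b2, sigma^2)``.  Pooled
rows are treated as independent — this is a working model, not a joint
likelihood — so the two parts can be maximized separately:

* ``b1``: probit maximum likelihood (Newton, relative tolerance 1e-8);
* ``b2``: ordinary least squares of ``log(tau_i - t_j)`` on ``H_i(t_j)``;
* ``sigma^2``: mean squared residual (no degrees-of-freedom correction).

Landmark grid points are placed at equally spaced quantiles of the
empirical duration distribution, levels ``k/(J+1)`` for ``k = 1..J``.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .eventlog import Dataset
from .features import (
    FeatureSpec,
    LandmarkTable,
    as_specs,
    build_landmark_table,
    DEFAULT_INITIAL_CONFIG,
)

__all__ = [
    "Grid",
    "ModelParams",
    "FitResult",
    "EstimationError",
    "DegenerateGridError",
    "select_grid",
    "fit_outcome",
    "fit_duration",
    "fit",
    "log_pseudo_likelihood",
    "log_pseudo_likelihood_parts",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

MODEL_VERSION = 1

_LOG_2PI = math.log(2.0 * math.pi)


class EstimationError(RuntimeError):
    """Raised when a fit is impossible on the given table."""


class DegenerateGridError(ValueError):
    """Raised when no informative landmark grid can be built."""


@dataclass(frozen=True)
class Grid:
    """Strictly increasing landmark times used for estimation."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 1 or pts.size < 1:
            raise ValueError("grid needs at least one point")
        if np.any(pts <= 0):
            raise ValueError("grid points must be positive")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("grid points must be strictly increasing")

    @property
    def J(self) -> int:
        return int(self.points.size)


@dataclass(frozen=True)
class ModelParams:
    """Coefficients of the two-part model over a fixed, ordered feature set.

    ``b1`` drives the probit success probability, ``b2`` the conditional
    mean of the log remaining time, ``sigma2`` its conditional variance.
    """

    b1: np.ndarray
    b2: np.ndarray
    sigma2: float
    spec_names: tuple[str, ...]

    def __post_init__(self) -> None:
        b1 = np.asarray(self.b1, dtype=float)
        b2 = np.asarray(self.b2, dtype=float)
        object.__setattr__(self, "b1", b1)
        object.__setattr__(self, "b2", b2)
        object.__setattr__(self, "spec_names", tuple(self.spec_names))
        p = len(self.spec_names)
        if b1.shape != (p,) or b2.shape != (p,):
            raise ValueError("b1/b2 length must match spec_names")
        if not self.sigma2 >= 0:
            raise ValueError("sigma2 must be nonnegative")


@dataclass(frozen=True)
class FitResult:
    params: ModelParams
    grid: Grid
    loglik_total: float
    loglik_outcome: float
    loglik_duration: float
    n_rows: int
    convergence: dict


def select_grid(durations: Sequence[float], J: int) -> Grid:
    """Place J landmark times at equally spaced duration quantiles.

    Probability levels are ``k/(J+1)`` for ``k = 1..J`` (so J = 9 gives the
    deciles 10%..90%).  The empirical quantile is the smallest order
    statistic whose empirical CDF reaches the level.  Duplicate quantile
    values are collapsed with a logged warning.
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size == 0:
        raise ValueError("durations must be nonempty")
    if J < 1:
        raise ValueError("J must be >= 1")
    n_distinct = np.unique(durations).size
    if J >= n_distinct:
        raise DegenerateGridError(
            f"J={J} grid points need more than J distinct durations "
            f"(got {n_distinct})"
        )
    srt = np.sort(durations)
    n = srt.size
    levels = np.arange(1, J + 1) / (J + 1)
    idx = np.ceil(n * levels).astype(int) - 1  # smallest order stat with ECDF >= level
    points = srt[idx]
    uniq = np.unique(points)
    if uniq.size < points.size:
        logger.warning(
            "collapsed %d duplicate grid points; J reduced to %d",
            points.size - uniq.size, uniq.size,
        )
    return Grid(points=uniq)


def _column_scales(X: np.ndarray) -> np.ndarray:
    s = np.max(np.abs(X), axis=0)
    s[s == 0] = 1.0
    return s


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name columns implicated in a rank deficiency via pivoted QR."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.max() > 0 else 0.0
    bad = [names[piv[k]] for k in range(len(diag)) if diag[k] <= tol]
    if not bad and diag.size < len(names):
        bad = [names[j] for j in piv[diag.size:]]
    return bad


@dataclass(frozen=True)
class OutcomeFit:
    b1: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    message: str


def fit_outcome(lt: LandmarkTable) -> OutcomeFit:
    """Maximize the probit pseudo-likelihood for the outcome coefficients.

    Uses Newton iterations on a column-rescaled design (an exact
    reparametrization, undone before returning) for numerical stability
    with raw polynomial time bases.  Separation or non-convergence is
    reported in the returned status, not raised.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    if lt.n_rows < 1:
        raise EstimationError("landmark table is empty")
    y = lt.y
    X = lt.X
    classes = np.unique(y)
    if classes.size < 2:
        raise EstimationError(
            f"outcome fit needs both classes; table has only y={classes.tolist()}"
        )
    scales = _column_scales(X)
    Xs = X / scales  # rank and optimization on the rescaled design
    if np.linalg.matrix_rank(Xs) < X.shape[1]:
        bad = _collinear_columns(Xs, lt.feature_names)
        raise EstimationError(f"design is rank deficient; collinear columns: {bad}")

    converged = False
    n_iter = 0
    message = ""
    params_scaled = np.zeros(X.shape[1])
    loglik = -np.inf
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = sm.Probit(y, Xs).fit(
                method="newton", maxiter=100, tol=1e-8, disp=0, warn_convergence=False
            )
        params_scaled = np.asarray(res.params, dtype=float)
        loglik = float(res.llf)
        retvals = getattr(res, "mle_retvals", {}) or {}
        converged = bool(retvals.get("converged", False))
        n_iter = int(retvals.get("iterations", 0))
        separation = any(
            issubclass(w.category, PerfectSeparationWarning) for w in caught
        )
        if not converged:
            message = "probit Newton did not converge within 100 iterations"
        elif not np.all(np.isfinite(params_scaled)):
            converged = False
            message = "non-finite probit coefficients (possible separation)"
        elif separation:
            converged = False
            message = "detected separation: fitted probabilities numerically 0/1"
    except Exception as exc:  # separation can make the Hessian singular
        message = f"probit maximization failed: {exc}"
    b1 = params_scaled / scales
    return OutcomeFit(b1=b1, loglik=loglik, converged=converged, n_iter=n_iter, message=message)


@dataclass(frozen=True)
class DurationFit:
    b2: np.ndarray
    sigma2: float
    loglik: float


def fit_duration(lt: LandmarkTable) -> DurationFit:
    """Least-squares fit of log remaining time; sigma^2 is the mean squared residual."""
    X = lt.X
    z = lt.log_remaining
    n, p = X.shape
    if n < p + 1:
        raise EstimationError(f"duration fit needs at least p+1={p + 1} rows, got {n}")
    scales = _column_scales(X)
    Xs = X / scales  # solve on the rescaled design, undo after
    if np.linalg.matrix_rank(Xs) < p:
        bad = _collinear_columns(Xs, lt.feature_names)
        raise EstimationError(f"design is rank deficient; collinear columns: {bad}")
    b2s, _, _, _ = np.linalg.lstsq(Xs, z, rcond=None)
    b2 = b2s / scales
    resid = z - X @ b2
    sigma2 = float(np.mean(resid**2))
    loglik = _duration_loglik(z, resid, sigma2)
    return DurationFit(b2=b2, sigma2=sigma2, loglik=loglik)


def _duration_loglik(z: np.ndarray, resid: np.ndarray, sigma2: float) -> float:
    """Sum of log-normal log-densities; z = log(tau - t) so sum(z) is the Jacobian term."""
    n = z.size
    if n == 0:
        return 0.0
    if sigma2 == 0.0:
        return math.inf if np.all(resid == 0) else -math.inf
    return float(-np.sum(z) - 0.5 * n * (_LOG_2PI + math.log(sigma2)) - np.sum(resid**2) / (2 * sigma2))


def _outcome_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    if y.size == 0:
        return 0.0
    return float(np.sum(np.where(y == 1, norm.logcdf(eta), norm.logcdf(-eta))))


def fit(
    ds: Dataset,
    grid: Grid | Sequence[float],
    specs: Sequence[FeatureSpec | str],
    initial_config: tuple[int, int, int] = DEFAULT_INITIAL_CONFIG,
) -> FitResult:
    """Build the pooled landmark table and maximize both likelihood parts."""
    if not isinstance(grid, Grid):
        grid = Grid(points=np.asarray(grid, dtype=float))
    specs = as_specs(specs)
    lt = build_landmark_table(ds, grid, specs, initial_config)
    if lt.n_rows == 0:
        raise EstimationError("landmark table is empty: no person outlasts any grid point")
    out = fit_outcome(lt)
    dur = fit_duration(lt)
    params = ModelParams(
        b1=out.b1, b2=dur.b2, sigma2=dur.sigma2,
        spec_names=tuple(s.name for s in specs),
    )
    return FitResult(
        params=params,
        grid=grid,
        loglik_total=out.loglik + dur.loglik,
        loglik_outcome=out.loglik,
        loglik_duration=dur.loglik,
        n_rows=lt.n_rows,
        convergence={
            "outcome_converged": out.converged,
            "outcome_iterations": out.n_iter,
            "outcome_message": out.message,
        },
    )


def log_pseudo_likelihood_parts(
    params: ModelParams,
    ds: Dataset,
    grid: Grid | Sequence[float],
    specs: Sequence[FeatureSpec | str] | None = None,
    initial_config: tuple[int, int, int] = DEFAULT_INITIAL_CONFIG,
) -> tuple[float, float, float]:
    """Evaluate (total, outcome part, duration part) of the log pseudo-likelihood.

    Only at-risk (person, grid point) pairs contribute; with no included
    rows all three parts are 0 (the empty product).  ``sigma2 = 0`` with a
    nonzero residual yields ``-inf`` as an explicit sentinel.
    """
    if not isinstance(grid, Grid):
        grid = Grid(points=np.asarray(grid, dtype=float))
    if specs is None:
        specs = params.spec_names
    specs = as_specs(specs)
    names = tuple(s.name for s in specs)
    if names != params.spec_names:
        raise ValueError(
            f"feature mismatch: params built for {params.spec_names}, got {names}"
        )
    lt = build_landmark_table(ds, grid, specs, initial_config)
    if lt.n_rows == 0:
        return 0.0, 0.0, 0.0
    X = lt.X
    ll_out = _outcome_loglik(lt.y, X @ params.b1)
    z = lt.log_remaining
    resid = z - X @ params.b2
    ll_dur = _duration_loglik(z, resid, params.sigma2)
    return ll_out + ll_dur, ll_out, ll_dur


def log_pseudo_likelihood(
    params: ModelParams,
    ds: Dataset,
    grid: Grid | Sequence[float],
    specs: Sequence[FeatureSpec | str] | None = None,
    initial_config: tuple[int, int, int] = DEFAULT_INITIAL_CONFIG,
) -> float:
    """Total log pseudo-likelihood of ``params`` on a dataset; see the parts variant."""
    return log_pseudo_likelihood_parts(params, ds, grid, specs, initial_config)[0]


def save_model(result: FitResult, path: str | Path) -> None:
    """Serialize a fitted model to JSON (feature names travel with the coefficients)."""
    payload = {
        "model_version": MODEL_VERSION,
        "spec_names": list(result.params.spec_names),
        "b1": result.params.b1.tolist(),
        "b2": result.params.b2.tolist(),
        "sigma2": result.params.sigma2,
        "grid": result.grid.points.tolist(),
        "diagnostics": {
            "loglik_total": result.loglik_total,
            "loglik_outcome": result.loglik_outcome,
            "loglik_duration": result.loglik_duration,
            "n_rows": result.n_rows,
            "convergence": result.convergence,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_model(path: str | Path) -> tuple[ModelParams, Grid, dict]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("model_version") != MODEL_VERSION:
        raise ValueError(f"unsupported model_version {payload.get('model_version')!r}")
    params = ModelParams(
        b1=np.asarray(payload["b1"], dtype=float),
        b2=np.asarray(payload["b2"], dtype=float),
        sigma2=float(payload["sigma2"]),
        spec_names=tuple(payload["spec_names"]),
    )
    grid = Grid(points=np.asarray(payload["grid"], dtype=float))
    return params, grid, payload.get("diagnostics", {})
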