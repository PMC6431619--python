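"""Event-history features H_i(t) and the pooled landmark design table.

The event-history process ``H_i(t)`` summarizes person *i*'s actions up to
time *t* as a feature vector.  This module ships the thirteen candidate
features for the three-slider control-panel task plus the polynomial time
basis (1, t, t^2, t^3), and assembles the pooled landmark table used by the
pseudo-likelihood estimator: one row per (person, grid point) pair with
``tau_i > t_j``, carrying ``H_i(t_j)``, the outcome ``y_i`` and the
log remaining time ``log(tau_i - t_j)``.

Conventions (all deliberate, see the package methods note):

* "up to time t" is closed — events at exactly ``t`` count, which makes
  ``H_i`` right-continuous between events;
* a *simple action* is an ``apply`` whose configuration differs from the
  current reference state in exactly one slider; the reference state is the
  configuration of the previous ``apply``, reset to the initial
  configuration by ``reset`` and at task start;
* a *repeat* is an ``apply`` whose configuration equals that of some
  strictly earlier ``apply`` (resets excluded);
* frequency features divide by the raw landmark time ``t`` with the
  convention ``0/0 := 0`` at ``t = 0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .eventlog import Dataset, ProcessRecord

__all__ = [
    "FeatureSpec",
    "FeatureVector",
    "LandmarkTable",
    "TABLE_FEATURES",
    "BASIS_FEATURES",
    "count_actions",
    "count_simple_actions",
    "votat_indicator",
    "count_resets",
    "count_repeats",
    "feature_vector",
    "build_landmark_table",
    "register_feature",
    "REMAINING_TIME_FLOOR",
]

logger = logging.getLogger(__name__)

DEFAULT_INITIAL_CONFIG = (0, 0, 0)

#: rows need tau_i - t_j above this floor so log(tau_i - t_j) stays finite
REMAINING_TIME_FLOOR = 1e-6

#: the 13 history features, in their canonical order
TABLE_FEATURES = (
    "N", "N_over_t", "N_pos",
    "S", "S_over_t", "S_pos",
    "I_votat",
    "R", "R_over_t", "R_pos",
    "RP", "RP_over_t", "RP_pos",
)

#: polynomial time basis capturing the pure time effect
BASIS_FEATURES = ("const", "t", "t2", "t3")

# user-registered extractors: kind -> callable(rec, t) -> float
_CUSTOM: dict[str, Callable[[ProcessRecord, float], float]] = {}


def register_feature(kind: str, func: Callable[[ProcessRecord, float], float]) -> None:
    """Register a custom feature extractor under a new kind name.

    The built-in kinds cannot be overridden.
    """
    if kind in TABLE_FEATURES or kind in BASIS_FEATURES:
        raise ValueError(f"cannot override built-in feature kind {kind!r}")
    _CUSTOM[kind] = func


@dataclass(frozen=True)
class FeatureSpec:
    """A named feature; ``kind`` selects the extractor (defaults to ``name``)."""

    name: str
    kind: str | None = None

    def __post_init__(self) -> None:
        if self.kind is None:
            object.__setattr__(self, "kind", self.name)


def as_specs(specs: Sequence[FeatureSpec | str]) -> tuple[FeatureSpec, ...]:
    out = tuple(s if isinstance(s, FeatureSpec) else FeatureSpec(s) for s in specs)
    names = [s.name for s in out]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate feature names in spec list: {names}")
    return out


@dataclass(frozen=True)
class FeatureVector:
    """The values of H_i(t) together with the ordered feature names."""

    values: np.ndarray
    spec_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.spec_names),):
            raise ValueError("values and spec_names length mismatch")


def count_actions(rec: ProcessRecord, t: float) -> int:
    """N_i(t): number of apply and reset events with time <= t."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return sum(1 for e in rec.events if e.is_action and e.time <= t)


def _simple_moves(
    rec: ProcessRecord, t: float, initial_config: tuple[int, int, int]
) -> list[int]:
    """Indices of the moved slider for each simple action up to time t."""
    ref = tuple(initial_config)
    moved: list[int] = []
    for e in rec.events:
        if e.time > t:
            break
        if e.etype == "reset":
            ref = tuple(initial_config)
        elif e.etype == "apply":
            diff = [k for k in range(3) if e.payload[k] != ref[k]]
            if len(diff) == 1:
                moved.append(diff[0])
            ref = e.payload
    return moved


def count_simple_actions(
    rec: ProcessRecord, t: float, initial_config: tuple[int, int, int] = DEFAULT_INITIAL_CONFIG
) -> int:
    """S_i(t): applies up to t that move exactly one slider from the reference state."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return len(_simple_moves(rec, t, initial_config))


def votat_indicator(
    rec: ProcessRecord, t: float, initial_config: tuple[int, int, int] = DEFAULT_INITIAL_CONFIG
) -> int:
    """I_i(t): 1 iff all three sliders have each been moved by some simple action up to t.

    Encodes the vary-one-thing-at-a-time (VOTAT) exploration strategy.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    return int(set(_simple_moves(rec, t, initial_config)) == {0, 1, 2})


def count_resets(rec: ProcessRecord, t: float) -> int:
    """R_i(t): number of reset events with time <= t."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return sum(1 for e in rec.events if e.etype == "reset" and e.time <= t)


def count_repeats(rec: ProcessRecord, t: float) -> int:
    """RP_i(t): applies up to t whose configuration repeats a strictly earlier apply."""
    if t < 0:
        raise ValueError("t must be >= 0")
    seen: set[tuple[int, int, int]] = set()
    n_rep = 0
    for e in rec.events:
        if e.time > t:
            break
        if e.etype == "apply":
            if e.payload in seen:
                n_rep += 1
            seen.add(e.payload)
    return n_rep


def _evaluate(
    spec: FeatureSpec,
    rec: ProcessRecord,
    t: float,
    initial_config: tuple[int, int, int],
) -> float:
    kind = spec.kind
    if kind == "const":
        return 1.0
    if kind == "t":
        return float(t)
    if kind == "t2":
        return float(t) ** 2
    if kind == "t3":
        return float(t) ** 3
    if kind in ("N", "N_over_t", "N_pos"):
        n = count_actions(rec, t)
        if kind == "N":
            return float(n)
        if kind == "N_pos":
            return float(n > 0)
        return n / t if t > 0 else 0.0
    if kind in ("S", "S_over_t", "S_pos"):
        s = count_simple_actions(rec, t, initial_config)
        if kind == "S":
            return float(s)
        if kind == "S_pos":
            return float(s > 0)
        return s / t if t > 0 else 0.0
    if kind == "I_votat":
        return float(votat_indicator(rec, t, initial_config))
    if kind in ("R", "R_over_t", "R_pos"):
        r = count_resets(rec, t)
        if kind == "R":
            return float(r)
        if kind == "R_pos":
            return float(r > 0)
        return r / t if t > 0 else 0.0
    if kind in ("RP", "RP_over_t", "RP_pos"):
        rp = count_repeats(rec, t)
        if kind == "RP":
            return float(rp)
        if kind == "RP_pos":
            return float(rp > 0)
        return rp / t if t > 0 else 0.0
    if kind in _CUSTOM:
        return float(_CUSTOM[kind](rec, t))
    raise ValueError(f"unknown feature kind {kind!r}")


def feature_vector(
    rec: ProcessRecord,
    t: float,
    specs: Sequence[FeatureSpec | str],
    initial_config: tuple[int, int, int] = DEFAULT_INITIAL_CONFIG,
) -> FeatureVector:
    """Evaluate H_i(t) for one record at one landmark time."""
    if t < 0:
        raise ValueError("t must be >= 0")
    specs = as_specs(specs)
    if not specs:
        raise ValueError("specs must be nonempty")
    values = np.array([_evaluate(s, rec, t, initial_config) for s in specs])
    return FeatureVector(values=values, spec_names=tuple(s.name for s in specs))


@dataclass(frozen=True)
class LandmarkTable:
    """The pooled landmark design: one row per at-risk (person, grid point) pair.

    ``frame`` columns: ``person_id``, ``grid_index``, ``landmark_time``,
    ``y``, ``log_remaining`` and one column per feature name.
    """

    frame: pd.DataFrame
    feature_names: tuple[str, ...]

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(self.feature_names)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["y"].to_numpy(dtype=int)

    @property
    def log_remaining(self) -> np.ndarray:
        return self.frame["log_remaining"].to_numpy(dtype=float)

    @classmethod
    def from_arrays(
        cls,
        X: np.ndarray,
        y: np.ndarray,
        log_remaining: np.ndarray,
        feature_names: Sequence[str],
        person_id: Sequence[str] | None = None,
        grid_index: Sequence[int] | None = None,
        t: Sequence[float] | None = None,
    ) -> "LandmarkTable":
        """Assemble a table directly from arrays (for programmatic designs)."""
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        frame = pd.DataFrame(
            {
                "person_id": list(person_id) if person_id is not None else [str(i) for i in range(n)],
                "grid_index": list(grid_index) if grid_index is not None else [0] * n,
                "landmark_time": list(t) if t is not None else [0.0] * n,
                "y": np.asarray(y, dtype=int),
                "log_remaining": np.asarray(log_remaining, dtype=float),
            }
        )
        for k, name in enumerate(feature_names):
            frame[name] = X[:, k]
        return cls(frame=frame, feature_names=tuple(feature_names))


def build_landmark_table(
    ds: Dataset,
    grid: Sequence[float] | "np.ndarray",
    specs: Sequence[FeatureSpec | str],
    initial_config: tuple[int, int, int] = DEFAULT_INITIAL_CONFIG,
) -> LandmarkTable:
    """Pool every at-risk (person, grid point) pair into one design table.

    Rows with ``tau_i <= t_j`` are absent; rows with a positive but
    numerically negligible remaining time (``tau_i - t_j <= 1e-6`` s) are
    excluded with a logged warning so ``log(tau_i - t_j)`` stays finite.
    """
    points = np.asarray(getattr(grid, "points", grid), dtype=float)
    if points.ndim != 1 or points.size == 0:
        raise ValueError("grid must be a nonempty 1-D sequence of times")
    if np.any(np.diff(points) <= 0):
        raise ValueError("grid points must be strictly increasing")
    specs = as_specs(specs)
    names = tuple(s.name for s in specs)

    rows: list[dict] = []
    for rec in ds:
        for j, tj in enumerate(points):
            rem = rec.duration - tj
            if rem <= 0:
                continue
            if rem <= REMAINING_TIME_FLOOR:
                logger.warning(
                    "excluding row (person=%s, t=%g): remaining time %g below floor",
                    rec.person_id, tj, rem,
                )
                continue
            fv = feature_vector(rec, tj, specs, initial_config)
            row = {
                "person_id": rec.person_id,
                "grid_index": j,
                "landmark_time": float(tj),
                "y": rec.outcome,
                "log_remaining": float(np.log(rem)),
            }
            row.update(dict(zip(names, fv.values)))
            rows.append(row)

    columns = ["person_id", "grid_index", "landmark_time", "y", "log_remaining", *names]
    frame = pd.DataFrame(rows, columns=columns)
    return LandmarkTable(frame=frame, feature_names=names)
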