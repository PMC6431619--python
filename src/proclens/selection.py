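"""Stepwise forward feature selection by cross-validated log pseudo-likelihood.

At each step, every remaining candidate feature is tried in turn; the one
with the largest cross-validated log pseudo-likelihood is added if it
improves on the incumbent value, otherwise selection stops.  The
cross-validation partitions *persons* (never pooled rows) into folds, so a
held-out person contributes all of their landmark rows at once — splitting
rows would leak each person's history across folds.  The landmark grid is
fixed once, before cross-validation, and shared by all folds.

Ties at the argmax are broken by candidate declaration order, and the fold
assignment is a seeded uniform shuffle, so the whole path is deterministic
given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .eventlog import Dataset
from .features import DEFAULT_INITIAL_CONFIG, FeatureSpec, as_specs
from .model import Grid, fit, log_pseudo_likelihood_parts

__all__ = [
    "CVLikelihood",
    "SelectionStep",
    "SelectionPath",
    "SelectionError",
    "cv_log_pseudo_likelihood",
    "stepwise_forward",
]

logger = logging.getLogger(__name__)


class SelectionError(RuntimeError):
    """A fold could not be fitted during cross-validation."""


class CVLikelihood(NamedTuple):
    total: float
    outcome: float
    duration: float


@dataclass(frozen=True)
class SelectionStep:
    step: int
    added: str | None          # None for the initial model
    cv_total: float
    cv_outcome: float
    cv_duration: float


@dataclass(frozen=True)
class SelectionPath:
    steps: tuple[SelectionStep, ...]
    initial_specs: tuple[FeatureSpec, ...]
    final_specs: tuple[FeatureSpec, ...]

    def to_frame(self) -> pd.DataFrame:
        """Selection path as a table: step, var_added, lik, lik_out, lik_dur."""
        return pd.DataFrame(
            {
                "step": [s.step for s in self.steps],
                "var_added": [s.added if s.added is not None else "(initial)" for s in self.steps],
                "lik": [s.cv_total for s in self.steps],
                "lik_out": [s.cv_outcome for s in self.steps],
                "lik_dur": [s.cv_duration for s in self.steps],
            }
        )


def _person_folds(ds: Dataset, folds: int, seed: int) -> list[list[str]]:
    ids = list(ds.person_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return [[ids[i] for i in chunk] for chunk in np.array_split(perm, folds)]


def cv_log_pseudo_likelihood(
    ds: Dataset,
    grid: Grid | Sequence[float],
    specs: Sequence[FeatureSpec | str],
    folds: int,
    seed: int,
    initial_config: tuple[int, int, int] = DEFAULT_INITIAL_CONFIG,
) -> CVLikelihood:
    """Cross-validated log pseudo-likelihood, summed over held-out folds.

    Persons are partitioned into ``folds`` groups by a seeded shuffle; for
    each fold the model is fitted on the remaining persons and the held-out
    persons' log pseudo-likelihood is accumulated.  Returns the total and
    its outcome/duration components.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > ds.N:
        raise ValueError(f"folds={folds} exceeds number of persons {ds.N}")
    specs = as_specs(specs)
    assignments = _person_folds(ds, folds, seed)
    total = out = dur = 0.0
    for k, held_ids in enumerate(assignments):
        held = set(held_ids)
        train = ds.subset([pid for pid in ds.person_ids if pid not in held])
        test = ds.subset(held_ids)
        try:
            res = fit(train, grid, specs, initial_config)
        except Exception as exc:
            raise SelectionError(f"fold {k}: fit failed: {exc}") from exc
        t, o, d = log_pseudo_likelihood_parts(
            res.params, test, grid, specs, initial_config
        )
        total, out, dur = total + t, out + o, dur + d
    return CVLikelihood(total=total, outcome=out, duration=dur)


def stepwise_forward(
    ds: Dataset,
    grid: Grid | Sequence[float],
    initial: Sequence[FeatureSpec | str],
    candidates: Sequence[FeatureSpec | str],
    folds: int = 5,
    seed: int = 0,
    initial_config: tuple[int, int, int] = DEFAULT_INITIAL_CONFIG,
) -> SelectionPath:
    """Greedy forward selection on the cross-validated log pseudo-likelihood.

    Starting from the ``initial`` feature set, each step adds the candidate
    giving the maximum CV value, provided it strictly exceeds the incumbent;
    otherwise selection stops.  A candidate on which every evaluation fails
    (e.g. it makes the design collinear) is skipped with a logged warning
    and never accepted.
    """
    initial = list(as_specs(initial))
    if not initial:
        raise ValueError("initial feature set must be nonempty")
    current_names = {s.name for s in initial}
    remaining = [s for s in as_specs(candidates) if s.name not in current_names]

    base = cv_log_pseudo_likelihood(ds, grid, initial, folds, seed, initial_config)
    steps = [SelectionStep(0, None, base.total, base.outcome, base.duration)]
    current = list(initial)
    incumbent = base

    step_no = 0
    while remaining:
        best_idx: int | None = None
        best_cv: CVLikelihood | None = None
        for idx, cand in enumerate(remaining):
            try:
                cv = cv_log_pseudo_likelihood(
                    ds, grid, current + [cand], folds, seed, initial_config
                )
            except SelectionError as exc:
                logger.warning("skipping candidate %s: %s", cand.name, exc)
                continue
            if best_cv is None or cv.total > best_cv.total:  # ties: first in order
                best_idx, best_cv = idx, cv
        if best_cv is None or not best_cv.total > incumbent.total:
            break
        step_no += 1
        chosen = remaining.pop(best_idx)
        current.append(chosen)
        incumbent = best_cv
        steps.append(
            SelectionStep(step_no, chosen.name, best_cv.total, best_cv.outcome, best_cv.duration)
        )
    return SelectionPath(
        steps=tuple(steps),
        initial_specs=tuple(initial),
        final_specs=tuple(current),
    )
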