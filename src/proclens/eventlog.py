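"""Data model and CSV I/O for time-stamped problem-solving process data.

A *process record* is one person's interaction log on a single task: a
time-ordered sequence of events (panel actions plus start/end markers),
together with the labelled total duration ``tau`` (seconds) and the binary
final outcome ``y`` (1 = success).  The task emulated here is a three-slider
control panel: ``apply`` events carry the applied slider configuration,
``reset`` events restore the initial configuration, and ``start``/``end``
are bookend markers, not actions.

File formats
------------
Log file
    CSV with header ``person_id,time,etype,top,central,bottom``.  The three
    slider columns are filled only for ``apply`` rows.  Times are decimal
    seconds.
Labels file
    CSV with header ``person_id,duration,outcome`` with ``outcome`` in
    ``{0, 1}``.

Durations always come from the labels file, never from the last event:
logs may be truncated.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Event",
    "ProcessRecord",
    "Dataset",
    "EventLogError",
    "ParseError",
    "ValidationError",
    "read_logs",
    "write_logs",
    "split",
    "ACTION_TYPES",
    "MARKER_TYPES",
    "EVENT_TYPES",
]

ACTION_TYPES = frozenset({"apply", "reset"})
MARKER_TYPES = frozenset({"start", "end"})
EVENT_TYPES = ACTION_TYPES | MARKER_TYPES

LOG_HEADER = ["person_id", "time", "etype", "top", "central", "bottom"]
LABELS_HEADER = ["person_id", "duration", "outcome"]


class EventLogError(ValueError):
    """Base class for event-log errors."""


class ParseError(EventLogError):
    """A malformed row in a log or labels file; the message names the line."""


class ValidationError(EventLogError):
    """Structurally parsable input that violates a record invariant."""


@dataclass(frozen=True)
class Event:
    """One time-stamped event.

    Parameters
    ----------
    time
        Seconds since task start, nonnegative.
    etype
        One of ``start``, ``apply``, ``reset``, ``end``.
    payload
        For ``apply`` events, the applied ``(top, central, bottom)`` slider
        triple; ``None`` otherwise.
    """

    time: float
    etype: str
    payload: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if not (isinstance(self.time, (int, float)) and math.isfinite(self.time)):
            raise ValidationError(f"event time must be a finite number, got {self.time!r}")
        if self.time < 0:
            raise ValidationError(f"event time must be >= 0, got {self.time}")
        if self.etype not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.etype!r}")
        if self.etype == "apply":
            if self.payload is None or len(self.payload) != 3:
                raise ValidationError("apply events carry exactly three slider values")
            object.__setattr__(self, "payload", tuple(int(v) for v in self.payload))
        elif self.payload is not None:
            raise ValidationError(f"{self.etype} events carry no payload")

    @property
    def is_action(self) -> bool:
        return self.etype in ACTION_TYPES


@dataclass(frozen=True)
class ProcessRecord:
    """One individual's event stream plus the labelled (duration, outcome)."""

    person_id: str
    events: tuple[Event, ...]
    duration: float
    outcome: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        if not (self.duration > 0 and math.isfinite(self.duration)):
            raise ValidationError(
                f"{self.person_id}: duration must be a positive finite number"
            )
        if self.outcome not in (0, 1):
            raise ValidationError(f"{self.person_id}: outcome must be 0 or 1")
        times = [e.time for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError(f"{self.person_id}: events not sorted by time")
        if any(t > self.duration for t in times):
            raise ValidationError(
                f"{self.person_id}: event time exceeds labelled duration"
            )
        starts = [e for e in self.events if e.etype == "start"]
        if len(starts) != 1 or starts[0].time != 0:
            raise ValidationError(
                f"{self.person_id}: need exactly one start event at time 0"
            )
        ends = [e for e in self.events if e.etype == "end"]
        if len(ends) > 1 or (ends and ends[0].time != self.duration):
            raise ValidationError(
                f"{self.person_id}: at most one end event, at time = duration"
            )

    @property
    def actions(self) -> tuple[Event, ...]:
        """The apply/reset events (start/end markers excluded)."""
        return tuple(e for e in self.events if e.is_action)


@dataclass(frozen=True)
class Dataset:
    """A collection of :class:`ProcessRecord` with unique person ids."""

    records: tuple[ProcessRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.person_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate person_id in dataset: {dup[:5]}")

    @property
    def N(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def person_ids(self) -> tuple[str, ...]:
        return tuple(r.person_id for r in self.records)

    @property
    def durations(self) -> np.ndarray:
        return np.array([r.duration for r in self.records], dtype=float)

    @property
    def outcomes(self) -> np.ndarray:
        return np.array([r.outcome for r in self.records], dtype=int)

    def subset(self, person_ids: Iterable[str]) -> "Dataset":
        wanted = set(person_ids)
        return Dataset(tuple(r for r in self.records if r.person_id in wanted))


def _fmt_time(t: float) -> str:
    """Format a time so that reading it back reproduces the float exactly."""
    if float(t) == int(t):
        return str(int(t))
    return repr(float(t))


def _parse_labels(labels_path: Path) -> dict[str, tuple[float, int]]:
    labels: dict[str, tuple[float, int]] = {}
    with open(labels_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{labels_path}: empty labels file") from None
        if [h.strip() for h in header] != LABELS_HEADER:
            raise ParseError(
                f"{labels_path}:1: expected header {','.join(LABELS_HEADER)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise ParseError(f"{labels_path}:{lineno}: expected 3 fields")
            pid = row[0].strip()
            try:
                duration = float(row[1])
                outcome = int(row[2])
            except ValueError:
                raise ParseError(
                    f"{labels_path}:{lineno}: malformed duration/outcome"
                ) from None
            if outcome not in (0, 1):
                raise ParseError(f"{labels_path}:{lineno}: outcome must be 0 or 1")
            if pid in labels:
                raise ValidationError(
                    f"{labels_path}:{lineno}: duplicate person_id {pid!r}"
                )
            labels[pid] = (duration, outcome)
    return labels


def _parse_log_rows(log_path: Path) -> dict[str, list[Event]]:
    events: dict[str, list[Event]] = {}
    with open(log_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return events  # empty log file is legal: starts are synthesized
        if [h.strip() for h in header] != LOG_HEADER:
            raise ParseError(f"{log_path}:1: expected header {','.join(LOG_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 6:
                raise ParseError(f"{log_path}:{lineno}: expected 6 fields")
            pid = row[0].strip()
            etype = row[2].strip()
            try:
                time = float(row[1])
            except ValueError:
                raise ParseError(f"{log_path}:{lineno}: malformed time {row[1]!r}") from None
            sliders = [c.strip() for c in row[3:6]]
            try:
                if etype == "apply":
                    if any(not c for c in sliders):
                        raise ParseError(
                            f"{log_path}:{lineno}: apply rows need all three slider values"
                        )
                    payload: tuple[int, int, int] | None = tuple(int(c) for c in sliders)
                else:
                    if any(sliders):
                        raise ParseError(
                            f"{log_path}:{lineno}: slider columns must be blank unless etype=apply"
                        )
                    payload = None
                event = Event(time=time, etype=etype, payload=payload)
            except ValueError as exc:
                if isinstance(exc, EventLogError) and not isinstance(exc, ValidationError):
                    raise
                raise ParseError(f"{log_path}:{lineno}: {exc}") from None
            events.setdefault(pid, []).append(event)
    return events


def read_logs(log_path: str | Path, labels_path: str | Path) -> Dataset:
    """Read a log CSV and a labels CSV into a validated :class:`Dataset`.

    One record is created per person in the labels file; a person appearing
    in the log but not in the labels is a validation error.  Events are
    stably re-sorted by time, and a record lacking a ``start`` event gets
    one synthesized at time 0.
    """
    log_path, labels_path = Path(log_path), Path(labels_path)
    labels = _parse_labels(labels_path)
    by_person = _parse_log_rows(log_path)

    orphans = sorted(set(by_person) - set(labels))
    if orphans:
        raise ValidationError(
            f"{log_path}: person(s) present in logs but not in labels: {orphans[:5]}"
        )

    records = []
    for pid, (duration, outcome) in labels.items():
        evs = sorted(by_person.get(pid, []), key=lambda e: e.time)  # stable
        bad = [e for e in evs if e.time > duration]
        if bad:
            raise ValidationError(
                f"{pid}: event at {bad[0].time} s exceeds labelled duration {duration} s"
            )
        if not any(e.etype == "start" for e in evs):
            evs.insert(0, Event(time=0.0, etype="start"))
        records.append(
            ProcessRecord(person_id=pid, events=tuple(evs), duration=duration, outcome=outcome)
        )
    return Dataset(tuple(records))


def write_logs(ds: Dataset, log_path: str | Path, labels_path: str | Path) -> None:
    """Write a dataset to the two-file CSV format; inverse of :func:`read_logs`."""
    log_path, labels_path = Path(log_path), Path(labels_path)
    with open(log_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(LOG_HEADER)
        for rec in ds:
            for e in rec.events:
                sliders = ["", "", ""] if e.payload is None else [str(v) for v in e.payload]
                writer.writerow([rec.person_id, _fmt_time(e.time), e.etype, *sliders])
    with open(labels_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(LABELS_HEADER)
        for rec in ds:
            writer.writerow([rec.person_id, _fmt_time(rec.duration), rec.outcome])


def split(ds: Dataset, fraction: float, seed: int) -> tuple[Dataset, Dataset]:
    """Random person-level partition into (train, test).

    The first part has ``floor(fraction * N)`` records; deterministic given
    ``seed``.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if ds.N == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.N)
    n_train = int(math.floor(fraction * ds.N))
    train_idx = set(perm[:n_train].tolist())
    train = tuple(r for i, r in enumerate(ds.records) if i in train_idx)
    test = tuple(r for i, r in enumerate(ds.records) if i not in train_idx)
    return Dataset(train), Dataset(test)
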