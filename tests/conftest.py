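import numpy as np
import pytest

from proclens import Event, ProcessRecord, SimConfig, simulate_dataset
from proclens.examples import example_dataset

SLIDER_VALUES = (-2, -1, 0, 1, 2)


@pytest.fixture(scope="session")
def table1():
    """The bundled single-student example record (4 actions, tau=61.5, success)."""
    return example_dataset().records[0]


def make_random_record(rng: np.random.Generator, person_id: str = "r0") -> ProcessRecord:
    """A random but valid record: mixed applies/resets, arbitrary payloads."""
    n_actions = int(rng.integers(0, 15))
    duration = float(rng.uniform(5.0, 300.0))
    times = np.sort(rng.uniform(0.0, duration * 0.95, size=n_actions))
    events = [Event(time=0.0, etype="start")]
    for t in times:
        if rng.random() < 0.2:
            events.append(Event(time=float(t), etype="reset"))
        else:
            payload = tuple(int(v) for v in rng.choice(SLIDER_VALUES, size=3))
            events.append(Event(time=float(t), etype="apply", payload=payload))
    if rng.random() < 0.5:
        events.append(Event(time=duration, etype="end"))
    return ProcessRecord(
        person_id=person_id,
        events=tuple(events),
        duration=duration,
        outcome=int(rng.integers(0, 2)),
    )


@pytest.fixture
def random_records():
    """Factory: n random records from a seeded generator."""

    def _make(n: int, seed: int = 0) -> list[ProcessRecord]:
        rng = np.random.default_rng(seed)
        return [make_random_record(rng, person_id=f"r{i}") for i in range(n)]

    return _make


@pytest.fixture(scope="session")
def sim_small():
    """A small synthetic dataset shared across tests (n=400)."""
    return simulate_dataset(SimConfig(n_individuals=400, seed=123))


@pytest.fixture(scope="session")
def sim_small_cfg():
    return SimConfig(n_individuals=400, seed=123)
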