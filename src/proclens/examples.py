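"""Accessors for the tiny example files shipped with the package."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .eventlog import Dataset, read_logs

__all__ = ["example_log_paths", "example_dataset", "default_sim_config_path"]


def _data_path(name: str) -> Path:
    return Path(resources.files("proclens").joinpath("data", name))


def example_log_paths() -> tuple[Path, Path]:
    """Paths of the bundled single-student example (log CSV, labels CSV).

    The example is the published single-student slider log: four panel
    actions between 29.5 s and 36.2 s, total duration 61.5 s, successful
    outcome.
    """
    return _data_path("table1_logs.csv"), _data_path("table1_labels.csv")


def example_dataset() -> Dataset:
    """The bundled single-student example, parsed and validated."""
    logs, labels = example_log_paths()
    return read_logs(logs, labels)


def default_sim_config_path() -> Path:
    """Path of the bundled default simulation configuration (YAML)."""
    return _data_path("sim_default.yaml")
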