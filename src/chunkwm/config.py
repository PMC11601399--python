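"""Experiment configuration: defaults, YAML loading, validation, manifests.

A single YAML file describes one experiment (task sizes, circuit layout,
learning and dopamine parameters, seeds).  Unknown keys are rejected and
missing keys are filled from the documented defaults, so a dumped config
always round-trips.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["ExperimentConfig", "load_config", "dump_config", "write_results"]


@dataclass
class ExperimentConfig:
    """Everything needed to train and evaluate one network condition.

    ``n_orientations`` defaults to the set size: each episode then presents
    every orientation in the inventory (in random order, with a random
    subset on lighter-load episodes), which is what makes an
    orientation-conditioned gating policy able to bind every item to a
    stripe.
    """

    # task
    set_size: int = 2
    n_orientations: int | None = None  # None -> set_size
    ring_size: int = 20
    tuning_width: float = 0.7
    variable_load: bool = True

    # circuit
    n_stripes: int = 2
    chunk_enabled: bool = True
    input_scale: float = 1.0
    top_down_scale: float = 0.4
    n_cycles: int = 30
    maintenance_leak: float = 1.0
    noise_sd: float = 0.1

    # learning
    lr_w: float = 0.2
    lr_sup: float = 0.05
    lr_v: float = 0.05
    w_max: float = 1.0
    tag_decay: float = 0.7
    closed_tag_gain: float = 0.5
    burst_gain: float = 0.6
    dip_gain: float = 0.6

    # schedule
    n_epochs: int = 500
    trials_per_epoch: int = 100
    eval_episodes: int = 500
    seeds: list = field(default_factory=lambda: [0])

    def __post_init__(self) -> None:
        if self.n_orientations is None:
            self.n_orientations = self.set_size
        self.validate()

    def validate(self) -> None:
        if self.set_size < 1:
            raise ValueError("set_size must be >= 1")
        if self.set_size > self.n_orientations:
            raise ValueError(
                f"set_size ({self.set_size}) must not exceed n_orientations "
                f"({self.n_orientations})"
            )
        if self.n_stripes < 1:
            raise ValueError("n_stripes must be >= 1")
        if self.n_epochs < 1 or self.trials_per_epoch < 1:
            raise ValueError("n_epochs and trials_per_epoch must be >= 1")
        if self.burst_gain < 0 or self.dip_gain < 0:
            raise ValueError("dopamine gains must be >= 0")
        if not 0.0 <= self.tag_decay <= 1.0:
            raise ValueError("tag_decay must lie in [0, 1]")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be distinct")

    def replace(self, **kwargs) -> "ExperimentConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> ExperimentConfig:
    """Load a YAML experiment config, rejecting unknown keys.

    An empty file yields the full default configuration.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    try:
        return ExperimentConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config {path}: {exc}") from exc


def dump_config(config: ExperimentConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return path


def write_results(records, path, format: str = "csv") -> Path:
    """Serialize a list of records (dataclasses or dicts) to CSV or JSON.

    Non-responses keep an explicit null response angle.  Records must be
    non-empty and share a schema.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    rows = []
    for r in records:
        if dataclasses.is_dataclass(r):
            r = dataclasses.asdict(r)
        elif not isinstance(r, dict):
            raise TypeError(f"unsupported record type {type(r)!r}")
        rows.append(
            {
                k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
                for k, v in r.items()
            }
        )
    keys = set(rows[0])
    for row in rows:
        if set(row) != keys:
            raise ValueError("records have inconsistent schemas")
    path = Path(path)
    if format == "csv":
        pd.DataFrame(rows).to_csv(path, index=False)
    elif format == "json":
        path.write_text(json.dumps(rows, indent=1, default=float))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
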