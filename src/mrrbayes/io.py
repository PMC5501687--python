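"""File formats: daily-count CSV with a JSON metadata sidecar, YAML configs.

A dataset on disk is a plain rectangular CSV with header
``day,marked_captured,unmarked_captured`` (days 1..D, ascending, no gaps)
plus a sidecar JSON file — same path with an extra ``.json`` suffix —
holding the scalar metadata (``N``, ``n_pupae``, ``f_a``, ``tau``, ``s``,
``J``).  ``read_dataset(write_dataset(d, path))`` round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    MCMCConfig,
    MRRDataset,
    PriorSet,
    SimulationConfig,
    ValidationError,
    validate_dataset,
)

__all__ = [
    "read_dataset",
    "write_dataset",
    "sidecar_path",
    "read_simulation_config",
    "write_simulation_config",
]

_HEADER = ["day", "marked_captured", "unmarked_captured"]
_META_FIELDS = ("N", "n_pupae", "f_a", "tau", "s", "J")


def sidecar_path(path: Union[str, Path]) -> Path:
    return Path(str(path) + ".json")


def write_dataset(dataset: MRRDataset, path: Union[str, Path]) -> Path:
    """Write the count table to ``path`` and metadata to its JSON sidecar."""
    path = Path(path)
    validate_dataset(dataset)
    table = pd.DataFrame(
        {
            "day": np.arange(1, dataset.D + 1),
            "marked_captured": dataset.m,
            "unmarked_captured": dataset.u,
        }
    )
    table.to_csv(path, index=False)
    meta = {k: getattr(dataset, k) for k in _META_FIELDS}
    sidecar_path(path).write_text(json.dumps(meta, indent=1) + "\n")
    return path


def read_dataset(path: Union[str, Path]) -> MRRDataset:
    """Read a dataset written by :func:`write_dataset`; validates on load.

    Raises :class:`ValidationError` naming the offending line for malformed
    headers, day gaps or negative counts, and for missing metadata.
    """
    path = Path(path)
    table = pd.read_csv(path)
    if list(table.columns) != _HEADER:
        raise ValidationError(
            f"{path}: expected header {','.join(_HEADER)}, got "
            f"{','.join(map(str, table.columns))}"
        )
    if len(table) == 0:
        raise ValidationError(f"{path}: no data rows")
    for col in _HEADER:
        vals = table[col]
        if not np.issubdtype(vals.dtype, np.number) or np.any(vals != np.floor(vals)):
            raise ValidationError(f"{path}: non-integer values in column {col}")
    days = table["day"].to_numpy(int)
    expected = np.arange(1, len(days) + 1)
    if not np.array_equal(days, expected):
        bad = int(np.argmax(days != expected))
        raise ValidationError(
            f"{path}: day gap or disorder at line {bad + 2}: "
            f"found day {days[bad]}, expected {expected[bad]}"
        )
    for col in ("marked_captured", "unmarked_captured"):
        neg = table.index[table[col] < 0]
        if len(neg):
            raise ValidationError(
                f"{path}: negative count in {col} at line {int(neg[0]) + 2}"
            )
    meta_file = sidecar_path(path)
    if not meta_file.exists():
        raise ValidationError(f"missing metadata sidecar {meta_file}")
    meta = json.loads(meta_file.read_text())
    if "N" not in meta:
        raise ValidationError(f"{meta_file}: missing required field 'N'")
    kwargs = {k: meta[k] for k in _META_FIELDS if meta.get(k) is not None}
    return validate_dataset(
        MRRDataset(
            m=table["marked_captured"].to_numpy(int),
            u=table["unmarked_captured"].to_numpy(int),
            **kwargs,
        )
    )


def read_simulation_config(path: Union[str, Path]) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML mapping."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: expected a YAML mapping")
    unknown = set(raw) - set(SimulationConfig.field_names())
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    return SimulationConfig(**raw)


def write_simulation_config(cfg: SimulationConfig, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False))
    return path


def priors_from_mapping(raw: dict) -> PriorSet:
    return PriorSet(**raw)


def mcmc_from_mapping(raw: dict) -> MCMCConfig:
    return MCMCConfig(**raw)
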