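"""Delimited-text and configuration I/O.

Observations travel as one CSV row per jar x occasion; spectra as
wavenumber/absorbance CSVs; run configuration as a plain YAML mapping
mirroring :class:`~litterfate.synthetic_data.SimulationConfig` /
:class:`~litterfate.synthetic_data.ExperimentDesign`.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .synthetic_data import (OBSERVATION_COLUMNS, ExperimentDesign,
                             LitterBatch, NoiseModel, SimulationConfig)

__all__ = ["read_observations", "write_observations", "load_config",
           "save_config"]


def read_observations(path) -> pd.DataFrame:
    """Read a jar-observations CSV, checking the column contract."""
    obs = pd.read_csv(path)
    missing = [c for c in OBSERVATION_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"{path}: missing observation columns {missing}")
    return obs


def write_observations(obs: pd.DataFrame, path) -> None:
    obs.to_csv(path, index=False, float_format="%.10g")


def save_config(design: ExperimentDesign, config: SimulationConfig, path) -> None:
    """Write design + simulation configuration to one YAML file."""
    payload = {
        "design": asdict(design) | {
            "treatments": [asdict(t) for t in design.treatments]},
        "config": asdict(config),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_config(path) -> tuple[ExperimentDesign, SimulationConfig]:
    """Read a YAML run configuration written by :func:`save_config`."""
    payload = yaml.safe_load(Path(path).read_text())
    d = dict(payload.get("design", {}))
    if "treatments" in d:
        d["treatments"] = tuple(LitterBatch(**t) for t in d["treatments"])
    c = dict(payload.get("config", {}))
    if "noise" in c and isinstance(c["noise"], dict):
        c["noise"] = NoiseModel(**c["noise"])
    if "months" in c:
        c["months"] = tuple(float(m) for m in c["months"])
    return ExperimentDesign(**d), SimulationConfig(**c)
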