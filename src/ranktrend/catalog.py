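"""Bundled simulation-study configurations and published reference cells."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .simulate import ScenarioSpec

__all__ = [
    "StudyConfig",
    "available_configs",
    "load_study_config",
    "load_reference",
    "config_hash",
]


@dataclass(frozen=True)
class StudyConfig:
    """One simulation study: a calibration null, scenarios, and size grids."""

    name: str
    alpha: float
    sizes_list: tuple
    calibration: ScenarioSpec
    scenarios: tuple

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        sizes_list = tuple(tuple(int(n) for n in s) for s in d["sizes_list"])
        alpha = float(d.get("alpha", 0.05))
        default_sizes = sizes_list[0]
        calibration = ScenarioSpec.from_dict(
            {"name": "calibration", **d["calibration"]},
            default_sizes=default_sizes, alpha=alpha)
        scenarios = tuple(
            ScenarioSpec.from_dict(s, default_sizes=default_sizes, alpha=alpha)
            for s in d["scenarios"]
        )
        return cls(str(d["name"]), alpha, sizes_list, calibration, scenarios)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "alpha": self.alpha,
            "sizes_list": [list(s) for s in self.sizes_list],
            "calibration": {"groups": [g.to_dict() for g in self.calibration.dists]},
            "scenarios": [s.to_dict() for s in self.scenarios],
        }


def _scenario_dir():
    return resources.files("ranktrend").joinpath("scenarios")


def available_configs() -> list[str]:
    """Names of the bundled study configurations."""
    return sorted(p.name[:-5] for p in _scenario_dir().iterdir()
                  if p.name.endswith(".yaml"))


def load_study_config(source) -> StudyConfig:
    """Load a study config from a bundled name (e.g. ``table1``) or a file path."""
    path = Path(source)
    if path.suffix in (".yaml", ".yml", ".json") and path.exists():
        text = path.read_text()
    else:
        res = _scenario_dir().joinpath(f"{source}.yaml")
        if not res.is_file():
            raise FileNotFoundError(
                f"no config file {source!r} and no bundled config of that name "
                f"(available: {', '.join(available_configs())})"
            )
        text = res.read_text()
    return StudyConfig.from_dict(yaml.safe_load(text))


def load_reference(name: str) -> Optional[pd.DataFrame]:
    """Published benchmark rates for a bundled study, as a long DataFrame.

    Returns None when no reference cells are bundled for ``name``.  Columns:
    scenario, sizes, test, rate.
    """
    res = resources.files("ranktrend").joinpath("data/reference_tables.yaml")
    tables = yaml.safe_load(res.read_text())
    if name not in tables:
        return None
    entry = tables[name]
    tests = entry["tests"]
    rows = []
    for scenario, by_sizes in entry["cells"].items():
        for sizes, rates in by_sizes.items():
            for test, rate in zip(tests, rates):
                rows.append({"scenario": str(scenario), "sizes": str(sizes),
                             "test": test, "rate": float(rate)})
    return pd.DataFrame(rows)


def config_hash(config: StudyConfig) -> str:
    """Stable digest of a study configuration for run logs."""
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
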