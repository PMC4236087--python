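"""Monte-Carlo size/power experiments for the five trend tests.

The protocol: for each sample-size configuration, calibrate every test's
rejection cutpoint at the empirical 95th percentile of its statistic over
B_null simulated null datasets, then estimate each scenario's rejection rate
over B_alt fresh datasets.  All tests see identical datasets (common random
numbers) in both phases, which removes between-test simulation noise from the
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._batch import TEST_NAMES, batch_statistics
from .core import GroupedSample
from .resampling import calibrate_cutpoints

__all__ = [
    "GroupDist",
    "ScenarioSpec",
    "PowerTable",
    "generate_dataset",
    "generate_matrix",
    "power_study",
    "table_report",
]

FAMILIES = ("normal", "t3", "exponential")


@dataclass(frozen=True)
class GroupDist:
    """Sampling distribution for one group.

    ``normal``     — mean ``mean``, standard deviation ``sd``;
    ``t3``         — ``mean`` plus a Student-t variate with 3 df;
    ``exponential``— exponential with mean ``mean`` (must be positive).
    """

    family: str
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.family == "exponential" and self.mean <= 0:
            raise ValueError("exponential family needs a positive mean")
        if self.family == "normal" and self.sd <= 0:
            raise ValueError("normal family needs a positive sd")

    def draw(self, rng: np.random.Generator, shape) -> np.ndarray:
        if self.family == "normal":
            return self.mean + self.sd * rng.standard_normal(shape)
        if self.family == "t3":
            return self.mean + rng.standard_t(3, size=shape)
        return rng.exponential(self.mean, size=shape)

    def to_dict(self) -> dict:
        d = {"family": self.family, "mean": self.mean}
        if self.family == "normal":
            d["sd"] = self.sd
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroupDist":
        return cls(family=d["family"], mean=float(d.get("mean", 0.0)),
                   sd=float(d.get("sd", 1.0)))


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation configuration: per-group distributions plus sizes."""

    name: str
    dists: tuple
    sizes: tuple
    alpha: float = 0.05
    null: bool = False

    def __post_init__(self):
        object.__setattr__(self, "dists", tuple(self.dists))
        object.__setattr__(self, "sizes", tuple(int(n) for n in self.sizes))
        if len(self.dists) != len(self.sizes):
            raise ValueError("one distribution spec per group is required")
        if len(self.dists) < 2:
            raise ValueError("need k >= 2 groups")
        if any(n < 1 for n in self.sizes):
            raise ValueError("every group size must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def k(self) -> int:
        return len(self.dists)

    @property
    def total_n(self) -> int:
        return int(sum(self.sizes))

    def with_sizes(self, sizes: Sequence[int]) -> "ScenarioSpec":
        if len(sizes) != self.k:
            raise ValueError("sizes length must match the number of groups")
        return replace(self, sizes=tuple(int(n) for n in sizes))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "groups": [d.to_dict() for d in self.dists],
            "sizes": list(self.sizes),
            "alpha": self.alpha,
            "null": self.null,
        }

    @classmethod
    def from_dict(cls, d: dict, default_sizes: Optional[Sequence[int]] = None,
                  alpha: float = 0.05) -> "ScenarioSpec":
        sizes = d.get("sizes", default_sizes)
        if sizes is None:
            raise ValueError("scenario needs sizes (explicit or default)")
        return cls(
            name=str(d.get("name", "scenario")),
            dists=tuple(GroupDist.from_dict(g) for g in d["groups"]),
            sizes=tuple(sizes),
            alpha=float(d.get("alpha", alpha)),
            null=bool(d.get("null", False)),
        )


def generate_matrix(spec: ScenarioSpec, replicates: int,
                    rng: np.random.Generator) -> np.ndarray:
    """(replicates, N) matrix of pooled datasets, columns blocked by group."""
    cols = [dist.draw(rng, (int(replicates), n))
            for dist, n in zip(spec.dists, spec.sizes)]
    return np.concatenate(cols, axis=1)


def generate_dataset(spec: ScenarioSpec, rng: np.random.Generator) -> GroupedSample:
    """One dataset drawn from the scenario, as a GroupedSample."""
    labels = tuple(f"g{i + 1}" for i in range(spec.k))
    return GroupedSample(
        labels, [dist.draw(rng, n) for dist, n in zip(spec.dists, spec.sizes)]
    )


@dataclass
class PowerTable:
    """Estimated rejection rates, one row per (scenario, sizes, test)."""

    frame: pd.DataFrame
    b_null: int
    b_alt: int
    seed: Optional[int] = None

    COLUMNS = ("scenario", "sizes", "test", "rate", "replicates", "b_null", "seed")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PowerTable":
        frame = pd.read_csv(path, dtype={"sizes": str, "scenario": str, "test": str})
        b_null = int(frame["b_null"].iloc[0]) if len(frame) else 0
        b_alt = int(frame["replicates"].iloc[0]) if len(frame) else 0
        seed = frame["seed"].iloc[0] if len(frame) else None
        seed = None if pd.isna(seed) else int(seed)
        return cls(frame, b_null, b_alt, seed)


def sizes_key(sizes: Sequence[int]) -> str:
    return "-".join(str(int(n)) for n in sizes)


def power_study(null_spec: ScenarioSpec, alt_specs: Sequence[ScenarioSpec],
                sizes_list: Sequence[Sequence[int]],
                tests: Sequence[str] = TEST_NAMES,
                b_null: int = 20_000, b_alt: int = 10_000,
                seed: Optional[int] = None) -> PowerTable:
    """Estimate size/power for every (scenario, sizes, test) cell.

    ``null_spec`` defines the calibration draws (the shared null used for the
    cutpoints); ``alt_specs`` are the scenarios whose rejection rates are
    reported and may include a null-type scenario for the size row.  Dataset
    streams are derived deterministically from ``seed`` per sizes
    configuration and per scenario, so adding or removing tests never changes
    the data any test sees.
    """
    if b_null < 100 or b_alt < 100:
        raise ValueError("b_null and b_alt must both be >= 100")
    tests = tuple(tests)
    root = np.random.SeedSequence(seed)
    rows = []
    for cfg_idx, sizes in enumerate(sizes_list):
        cfg_seed = root.spawn(1)[0]
        streams = cfg_seed.spawn(1 + len(alt_specs))
        cuts = calibrate_cutpoints(
            null_spec.with_sizes(sizes), tests=tests, replicates=b_null,
            seed=np.random.default_rng(streams[0]),
        )
        for s_idx, spec in enumerate(alt_specs):
            spec_sized = spec.with_sizes(sizes)
            rng = np.random.default_rng(streams[1 + s_idx])
            values = generate_matrix(spec_sized, b_alt, rng)
            stats = batch_statistics(values, spec_sized.sizes, tests=tests)
            for name in tests:
                rate = float(np.mean(stats[name] > cuts[name]))
                rows.append({
                    "scenario": spec.name,
                    "sizes": sizes_key(sizes),
                    "test": name,
                    "rate": rate,
                    "replicates": b_alt,
                    "b_null": b_null,
                    "seed": seed,
                })
    return PowerTable(pd.DataFrame(rows, columns=list(PowerTable.COLUMNS)),
                      b_null, b_alt, seed)


def table_report(power_table: PowerTable, reference: pd.DataFrame,
                 tolerance: float = 0.02) -> pd.DataFrame:
    """Cell-by-cell comparison of estimated rates against reference values.

    ``reference`` needs columns scenario, sizes, test, rate.  Cells present in
    the estimates but absent from the reference are kept and flagged as
    uncompared rather than dropped.
    """
    est = power_table.frame[["scenario", "sizes", "test", "rate"]].rename(
        columns={"rate": "estimate"})
    ref = reference[["scenario", "sizes", "test", "rate"]].rename(
        columns={"rate": "reference"})
    merged = est.merge(ref, on=["scenario", "sizes", "test"], how="left")
    merged["deviation"] = (merged["estimate"] - merged["reference"]).abs()
    merged["compared"] = merged["reference"].notna()
    merged["within_tolerance"] = pd.array(
        merged["deviation"] <= tolerance, dtype="boolean")
    merged.loc[~merged["compared"], "within_tolerance"] = pd.NA
    return merged
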