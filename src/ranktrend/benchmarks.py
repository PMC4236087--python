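"""Headline benchmark cells reproduced by the acceptance tooling.

Each target names one (study, scenario, sizes, test) cell of the bundled
reference tables.  Targets sharing a study and sizes configuration are
computed from one calibrated run so they see common random numbers, exactly
like a full study would.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .catalog import load_reference, load_study_config
from .simulate import power_study, sizes_key

__all__ = ["TARGETS", "run_benchmarks", "reference_value"]

TARGETS = (
    {"id": "t1", "table": "table1", "scenario": "null", "sizes": (10, 10, 10), "test": "new"},
    {"id": "t2", "table": "table1", "scenario": "a", "sizes": (10, 10, 10), "test": "new"},
    {"id": "t3", "table": "table1", "scenario": "a", "sizes": (10, 10, 10), "test": "jt"},
    {"id": "t4", "table": "table1", "scenario": "c", "sizes": (30, 20, 10), "test": "tm"},
    {"id": "t5", "table": "table2", "scenario": "d", "sizes": (30, 20, 10), "test": "new"},
    {"id": "t6", "table": "table3", "scenario": "b", "sizes": (30, 20, 10), "test": "new"},
    {"id": "t7", "table": "table4", "scenario": "null", "sizes": (30, 20, 10), "test": "new"},
    {"id": "t8", "table": "table5", "scenario": "A", "sizes": (8, 8, 8, 8), "test": "new"},
    {"id": "t9", "table": "table5", "scenario": "C", "sizes": (20, 20, 10, 10), "test": "cu"},
    {"id": "t10", "table": "table8", "scenario": "B", "sizes": (20, 20, 10, 10), "test": "new"},
)


def reference_value(target: dict) -> float:
    """Published rate for one target cell, from the bundled reference tables."""
    ref = load_reference(target["table"])
    row = ref[(ref["scenario"] == target["scenario"])
              & (ref["sizes"] == sizes_key(target["sizes"]))
              & (ref["test"] == target["test"])]
    if len(row) != 1:
        raise LookupError(f"no unique reference cell for {target['id']}")
    return float(row["rate"].iloc[0])


def run_benchmarks(b_null: int = 20_000, b_alt: int = 10_000,
                   seed: Optional[int] = None) -> dict[str, dict]:
    """Recompute every target cell from scratch.

    Returns ``{target id: {"value": rate, "n": b_alt}}``.  One calibration is
    run per (study, sizes) pair and shared by its targets.
    """
    groups: dict[tuple, list[dict]] = {}
    for t in TARGETS:
        groups.setdefault((t["table"], t["sizes"]), []).append(t)

    rng = np.random.default_rng(seed)
    group_seeds = {key: int(s) for key, s in
                   zip(sorted(groups), rng.integers(2 ** 31, size=len(groups)))}

    out: dict[str, dict] = {}
    for key in sorted(groups):
        table_name, sizes = key
        members = groups[key]
        study = load_study_config(table_name)
        wanted = {t["scenario"] for t in members}
        scenarios = [s for s in study.scenarios if s.name in wanted]
        tests = tuple(sorted({t["test"] for t in members}))
        table = power_study(
            study.calibration, scenarios, [sizes], tests=tests,
            b_null=b_null, b_alt=b_alt, seed=group_seeds[key],
        )
        frame = table.frame.set_index(["scenario", "test"])
        for t in members:
            rate = float(frame.loc[(t["scenario"], t["test"]), "rate"])
            out[t["id"]] = {"value": rate, "n": b_alt}
    return out
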