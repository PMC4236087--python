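"""Reading long-format group/value tables."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import GroupedSample

__all__ = ["read_long_csv"]


def read_long_csv(path, group_order: Sequence[str],
                  group_col: str = "group",
                  value_col: str = "value") -> GroupedSample:
    """Read a long-format CSV (one row per observation) into a GroupedSample.

    ``group_order`` supplies the hypothesized ordering of the group labels —
    it is scientific input and is never inferred by sorting.  Rows whose label
    is not in ``group_order`` are an error, as is a declared group with no
    observations.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    group_order = [str(g) for g in group_order]
    if len(group_order) < 2:
        raise ValueError("group_order must list at least 2 groups")
    frame = pd.read_csv(path, dtype={group_col: str})
    for col in (group_col, value_col):
        if col not in frame.columns:
            raise ValueError(f"missing column {col!r} in {path} "
                             f"(found: {list(frame.columns)})")
    if frame.empty:
        raise ValueError(f"{path} holds no observations")
    values = pd.to_numeric(frame[value_col], errors="coerce")
    if values.isna().any():
        rows = (values.isna()).to_numpy().nonzero()[0][:5] + 2  # 1-based + header
        raise ValueError(f"unparseable values near line(s) {list(rows)} of {path}")
    labels = frame[group_col].astype(str)
    unknown = sorted(set(labels) - set(group_order))
    if unknown:
        raise ValueError(
            f"labels {unknown} in {path} are not in the declared group order "
            f"{group_order}"
        )
    grouped = {g: values[labels == g].to_numpy(dtype=float) for g in group_order}
    empty = [g for g, v in grouped.items() if v.size == 0]
    if empty:
        raise ValueError(f"declared group(s) with no observations: {empty}")
    return GroupedSample(group_order, [grouped[g] for g in group_order])
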