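"""Vectorized evaluation of the trend statistics over batches of datasets.

Used by the permutation and power-study engines, where tens of thousands of
datasets share one composition (n_1..n_k).  Results agree exactly with the
scalar functions in :mod:`ranktrend.core` (asserted in the test suite).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

TEST_NAMES = ("jt", "mjt", "tm", "cu", "new")

# broadcast buffers are (chunk, n_i, n_j); keep them small
_CHUNK = 4096


def group_slices(sizes) -> list[slice]:
    edges = np.concatenate(([0], np.cumsum(sizes)))
    return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def batch_rank(values: np.ndarray) -> np.ndarray:
    """Row-wise pooled midranks of a (B, N) value matrix."""
    return rankdata(values, axis=1, method="average")


def _chunk_statistics(R: np.ndarray, slices: list[slice]) -> dict[str, np.ndarray]:
    B = R.shape[0]
    k = len(slices)
    out = {name: np.zeros(B) for name in TEST_NAMES}
    for i in range(k):
        ri = R[:, slices[i]]
        for j in range(i + 1, k):
            rj = R[:, slices[j]]
            diff = rj[:, None, :] - ri[:, :, None]
            u = (diff > 0).sum(axis=(1, 2)) + 0.5 * (diff == 0).sum(axis=(1, 2))
            out["jt"] += u
            out["mjt"] += (j - i) * u
            out["new"] += np.where(diff > 0, diff, 0.0).sum(axis=(1, 2))
    out["cu"] = sum(
        (l + 1) * R[:, sl].sum(axis=1) for l, sl in enumerate(slices)
    )
    # increasing-chain DP for TM, carried across groups
    counts = np.ones((B, slices[0].stop - slices[0].start))
    prev = np.sort(R[:, slices[0]], axis=1)
    for i in range(1, k):
        cur = np.sort(R[:, slices[i]], axis=1)
        lt = prev[:, :, None] < cur[:, None, :]
        counts = np.einsum("bun,bu->bn", lt, counts)
        prev = cur
    out["tm"] = counts.sum(axis=1)
    return out


def batch_statistics(values: np.ndarray, sizes,
                     tests=TEST_NAMES) -> dict[str, np.ndarray]:
    """Evaluate the requested statistics for every row of ``values``.

    Parameters
    ----------
    values
        (B, N) matrix; each row is one pooled dataset laid out in group order.
    sizes
        Composition (n_1..n_k) shared by all rows.
    tests
        Names from ``TEST_NAMES``; all five are computed internally (they share
        the pairwise rank-difference tensors), the dict is filtered on return.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] != int(np.sum(sizes)):
        raise ValueError("row length does not match sum of group sizes")
    unknown = set(tests) - set(TEST_NAMES)
    if unknown:
        raise ValueError(f"unknown tests: {sorted(unknown)}")
    slices = group_slices(sizes)
    parts: list[dict[str, np.ndarray]] = []
    for start in range(0, values.shape[0], _CHUNK):
        R = batch_rank(values[start:start + _CHUNK])
        parts.append(_chunk_statistics(R, slices))
    return {
        name: np.concatenate([p[name] for p in parts]) for name in tests
    }
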