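# ranktrend

Rank-based trend tests for the k-sample ordered-alternative problem: are the
location parameters of k independent groups nondecreasing along a prespecified
group order?

Five statistics are implemented, all computed from one pooled ranking per
dataset:

| key   | statistic |
|-------|-----------|
| `jt`  | Jonckheere–Terpstra: sum of Mann–Whitney counts over group pairs i\<j |
| `mjt` | modified JT: each Mann–Whitney count weighted by the group distance j−i |
| `tm`  | Terpstra–Magel: number of strictly increasing k-tuplets (one observation per group) |
| `cu`  | Cuzick: group rank-sums weighted by the group number 1..k |
| `new` | positive rank-difference statistic: over every cross-group pair, the positive part of the pooled-rank difference |

For the rank-difference statistic the package provides its exact null mean and
variance in closed form (verified against exhaustive enumeration) and the
resulting asymptotic-normal test. All five tests support exact-enumeration and
Monte-Carlo permutation inference, and a vectorized simulation engine
reproduces calibrated size/power studies: cutpoints are set at the empirical
95th percentile of each statistic over shared simulated null datasets, and
rejection rates are estimated over shared alternative datasets (common random
numbers across tests).

## Library quick start

```python
import numpy as np
import ranktrend as rt

sample = rt.GroupedSample(
    ["placebo", "low", "high"],
    [np.random.normal(0, 1, 10), np.random.normal(0.5, 1, 10),
     np.random.normal(1.0, 1, 10)],
)

rt.asymptotic_test(sample)                    # closed-form moments + normal tail
rt.permutation_pvalue(sample, "jt", replicates=20_000, seed=1)
rt.exact_pvalue(sample.reversed(), "new")     # small samples only

rt.new_mean_null((10, 10, 10)), rt.new_variance_null((10, 10, 10))
rt.exact_null_distribution((2, 2, 2), "new")  # full enumerated null
```

## CLI

Test a long-format CSV (`group,value`, one observation per row). The group
order is scientific input — pass it explicitly:

```bash
ranktrend test --input doses.csv --group-order 0,10,20,40 \
    --test all --method permutation --n-perm 20000 --seed 1 --out report.json

ranktrend test --input doses.csv --group-order 0,10,20,40 \
    --test new --method asymptotic
```

Run a bundled size/power study (`table1`..`table8`, covering normal, shifted-t
with 3 df, exponential and mixed normal/exponential scenarios for k = 3 and
k = 4) and compare against the bundled reference cells:

```bash
ranktrend simulate --config table1 --b-null 20000 --b-alt 10000 \
    --seed 1 --out-dir results/table1
```

Custom studies use the same YAML schema as the files in
`src/ranktrend/scenarios/`.

## Layout

- `core.py` — `GroupedSample`/`RankedSample`, pooled ranking, the five statistics
- `inference.py` — exact null moments, standardization, asymptotic test, CDF diagnostic
- `resampling.py` — exact enumeration, permutation p-values, cutpoint calibration
- `simulate.py` — scenario specs, dataset generation, power studies, comparison reports
- `catalog.py` / `scenarios/` / `data/` — bundled study configs and reference cells
- `io.py`, `cli.py` — CSV ingestion and the `ranktrend` command
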