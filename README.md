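# lotqa

Quality-assurance analysis of **leaf-open-time (LOT) attainment** for
helical tomotherapy deliveries with a binary multileaf collimator (MLC).

On platforms such as the Radixact, fluence is modulated by how long each of
64 binary leaves stays open during each of the 51 projections per gantry
rotation.  An optical position sensor in the treatment head reports the LOT
actually delivered at ~3 ms resolution, so plan execution can be audited
event by event.  This package is for medical physicists who want that audit
as a reproducible pipeline: it simulates planned and measured LOT
sinograms, computes the attainment statistic, and runs the surrounding QA
statistics (aggregation, outlier screening, correlation with gamma pass
rates, fraction-trend monitoring).

## The statistic

Pair every planned leaf opening with its measured counterpart by
(projection, leaf), take Δ = measured − planned (ms), and histogram the Δs
in bins of width *w* (default 5 ms).  The attainment rate is

    η = ΔLOT(0) / Σ_t ΔLOT(t)

— the fraction of planned openings that landed in the zero bin
(|Δ| ≤ w/2).  The denominator counts *all* planned openings, including ones
the MLC failed to execute; zero-LOT plan entries are never events.  Details
and conventions (tie-breaking, signed differences, rounding) are in
[docs/methods.md](docs/methods.md).

## Worked example

A delivery of 12 160 planned openings of which 11 736 were executed within
the zero bin:

```python
import numpy as np
from lotqa import PlannedSinogram, MeasuredSinogram, compute_attainment

lot = np.full((190, 64), 200.0)            # 12 160 planned events
plan = PlannedSinogram("example", lot, 500.0)
measured = lot.ravel().copy()
measured[11_736:] -= 10.0                  # 424 events miss by two bins
meas = MeasuredSinogram("example", 1, measured.reshape(lot.shape), 500.0,
                        sensor_resolution_ms=1e-9)
res = compute_attainment(plan, meas, bin_width_ms=5.0)
print(f"attainment: {res.eta_percent}% ({res.zero_count}/{res.total_planned_events})")
```

prints

```
attainment: 96.513% (11736/12160)
```

i.e. 96.5 % of the planned leaf openings were delivered within ±2.5 ms.

A synthetic six-site cohort under the default (realistic) error model:

```python
from lotqa import generate_cohort, summarize, spearman
from lotqa.simulate import default_cohort_specs

specs = default_cohort_specs(n_plans_per_site=2, n_fractions=5)
_, _, table = generate_cohort(specs, seed=1)
for s in summarize(table, group_by="site"):
    print(f"{s.group_label:8s} n={s.n:2d} mean={s.mean:6.3f}% sd={s.sd:.3f}")
corr = spearman(table["eta_percent"], table["gamma_delta4"])
print(f"rho={corr.rho:.3f} ({corr.strength})")
```

```
chest    n=10 mean=92.397% sd=2.361
head     n=10 mean=91.500% sd=3.035
hn       n=10 mean=92.857% sd=1.735
pelvis   n=10 mean=92.756% sd=1.581
prostate n=10 mean=92.218% sd=3.383
sbrt     n=10 mean=92.646% sd=1.741
rho=0.963 (very_strong)
```

Mean attainment sits in the low 90s per site — a well-behaved machine —
and the synthetic gamma pass rates track attainment strongly, by
construction.

## Command line

```bash
lotqa simulate --seed 1 --out-dir run/          # sinogram + session CSVs
lotqa analyze  --in-dir run/                    # summary/correlation/Welch/trend tables
lotqa report   --in-dir run/                    # plain-text report
```

Every run writes a manifest (config hash, seed, output hashes); identical
config and seed reproduce byte-identical outputs.  Key analysis choices are
flags: `--bin-width-ms`, `--fence-multiplier`, `--aggregation
{session,plan}`.

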