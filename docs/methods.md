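# Methods

## The statistic

A helical tomotherapy delivery modulates fluence by opening and closing 64
binary MLC leaves once per gantry projection (51 projections per rotation).
The plan prescribes, for every (projection, leaf) cell, a leaf-open time
(LOT) in milliseconds; the machine's optical position sensor reports the LOT
actually delivered, quantized at its ~3.0 ms temporal resolution.

The **LOT attainment rate** summarizes how faithfully the machine executed
the plan.  Pair every planned opening with its measured counterpart by
(projection, leaf) index, form Δ = measured − planned, and bin the Δ values
on a symmetric grid of width *w* centered at 0.  Then

    η = ΔLOT(0) / Σ_t ΔLOT(t)

i.e. the fraction of planned openings whose difference falls in the zero
bin (|Δ| ≤ w/2).  The denominator is the number of planned openings —
including openings the machine never executed (measured LOT 0, Δ = −planned)
— so η is penalized by dropped events.  Measured openings with no planned
counterpart are reported in a side channel (`extra_measured_events`) and
never enter η.  Cells with planned LOT 0 are not events at all: a leaf that
was never meant to open contributes nothing to either count.

Numerical conventions, fixed for reproducibility:

- Bin width *w* defaults to 5 ms, so "attained" means |Δ| ≤ 2.5 ms.
  Configurable; η is invariant under joint rescaling of LOTs and *w*.
- Δ is kept signed (latency can run early or late); an absolute-value mode
  is available via `difference_histogram(..., absolute=True)`.
- An event goes to the bin whose center is nearest; a boundary tie
  (|Δ| exactly halfway) resolves toward zero.  Two overflow bins absorb
  |Δ| beyond the grid (default ±20 bins).
- `eta_percent` is reported rounded to 3 decimals, the precision at which
  the statistic is conventionally quoted (e.g. 96.513%).
- An all-zero plan makes η undefined; the attainment routine raises
  `UndefinedStatisticError` rather than returning a sentinel.

## The synthetic-delivery generator

No clinical telemetry is distributable, so the package generates it.  Plans
are drawn from six site archetypes (prostate, pelvis, head, chest, H&N,
SBRT) parameterized by field width, pitch, modulation factor, beam-on time
and gantry period — values typical of clinical cohorts for each site (e.g.
SBRT: pitch 0.178, modulation factor 2.0, beam-on 450.93 s, gantry period
33.18 s, giving 693 projections of 650.6 ms).  Projection count is
`round(beam_on_time / (gantry_period / 51))`.

Within a plan, leaves in the open band (default: the central 32 of 64
leaves) open with probability 0.7 per projection.  Nonzero LOTs are sampled
from a Beta(1.5, 3) shape scaled to the projection duration and then
affinely rescaled — iterated to a fixed point under clipping — so the
realized modulation factor (max nonzero LOT / mean nonzero LOT) lands
within ±10 % of the request; a request of exactly 1 yields constant LOTs.
These distributional choices are plausible stand-ins, not reconstructions
of any clinical plan library.

The measurement error model applies, per fraction:

| parameter | meaning | default |
|---|---|---|
| `latency_mean_ms` | systematic timing shift | 0.0 ms |
| `latency_sd_ms` | fraction-to-fraction systematic variation (one draw per fraction) | 0.5 ms |
| `jitter_sd_ms` | per-event Gaussian noise | 1.0 ms |
| `drop_probability` | chance a planned opening is not executed | 5·10⁻⁴ |
| `sensor_resolution_ms` | quantization step of the optical sensor | 3.0 ms |

measured = planned + latency + jitter, clamped to [0, projection duration],
then quantized to the nearest multiple of the sensor resolution (ties round
half away from zero; the result is capped at the largest multiple below the
projection duration, so both the range and the multiple-of-resolution
invariants hold).  Clamping precedes quantization.  Dropped openings are
recorded as LOT 0 but remain planned events.  The defaults were chosen once
as clinically realistic — a well-behaved machine whose per-fraction
attainment lands in the low-to-mid 90 % range with occasional dips when the
fraction's latency draw is large.

The generator draws standard-normal/uniform variates first and scales them
by the SDs afterwards, from `default_rng([seed, fraction_index])` in a
documented order.  Two consequences: identical seeds reproduce cohorts
bit-for-bit, and error models differing only in their SDs share underlying
random numbers, which makes mean η *deterministically* non-increasing in
the jitter SD (each event's Δ moves monotonically away from its zero-error
value, and clamping and quantization are monotone maps).

Synthetic gamma pass rates are generated as
`100 − slope·(100·(1−η)) − |noise|` (slope 0.8, noise SD 0.5) purely to
exercise the correlation machinery; real gamma analysis is an external
measurement this package only consumes as input columns.  Detector signals
sit at baseline 1.0 with 0.5 % noise; trend scenarios depress listed
fractions by a chosen depth and simultaneously inflate that fraction's
jitter SD by `100·depth` ms so attainment co-declines with the signal.

What passing tests on this generator do **not** show: that clinical
deliveries follow Beta-shaped LOT distributions, that real latency is
Gaussian, or that real gamma pass rates are linear in η.  The generator
validates the *machinery* (binning, counting, aggregation, statistics), not
any clinical claim.

## QA statistics

- **Aggregation** pools individual sessions within a group (plan / site /
  all): n, mean, sample SD (ddof 1; a singleton group reports SD 0 with a
  logged warning), IQR, and IQR-fence outliers.  Plan-mean aggregation is
  available (`aggregation="plan"`) because cohort summaries can reasonably
  be taken over either sessions or plan means; session pooling is the
  default.
- **Outliers**: quartiles by linear interpolation between order statistics
  (the common "type 7" estimator — fixed because fence positions depend on
  it), fences at Q1 − 1.5·IQR and Q3 + 1.5·IQR, outliers strictly outside.
  Low-side outliers are the QA-relevant ones.
- **Spearman correlation** with the conventional five-level strength
  labels on |ρ|: <0.2 very weak, <0.4 weak, <0.6 moderate, <0.8 strong,
  ≥0.8 very strong (right-open intervals).  p-values are exact —
  exhaustive over all n! rank permutations — for n ≤ 9, and use the
  t-approximation with n−2 df above that.  Ties get average ranks.
- **Welch's t** (unequal variances, Welch–Satterthwaite df, two-sided)
  compares each site's sessions against the pooled cohort; significance
  level 0.05; no multiple-testing correction by default (a deliberate
  mirror of single-table QA reporting; apply Holm externally if desired).
- **Fraction-trend monitoring** flags fractions where the detector signal
  AND the attainment rate both fall below median − z·(scaled MAD) of their
  own series (z = 3 by default).  Median/MAD rather than mean/SD because
  treatment courses are short (≲10 fractions) and the anomalies being
  sought would otherwise inflate the spread estimate.  Both conditions are
  required: an attainment dip with a healthy detector signal is not flagged.

## Problem sizes and determinism

Unit and acceptance tests run on plans of tens of projections (hundreds of
events) except where a property needs statistics, where the SBRT archetype
(~15 000 events) is used; the whole suite completes in a few seconds.  The
acceptance script simulates the full six-site cohort (2 plans per site,
5 fractions, ~10–20 k events per plan) in about a second.  All randomness
flows from explicit seeds; file writers use stable ordering and fixed float
formatting (percents at 3 decimals, LOTs at shortest round-trip precision)
so identical runs are byte-identical.

## Known limitations

- No dose: η measures timing fidelity of the MLC, not delivered dose, and
  no causal link to gamma pass rates is modeled beyond the synthetic
  exercise link.
- Planned-LOT distributions per site are invented archetypes.
- The error model has no leaf-index structure (no sticky individual leaf)
  and no intra-fraction drift; latency is constant within a fraction.
- Extra measured openings (planned 0, measured > 0) are counted but no
  generator path produces them; the reader accepts them from external data.
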