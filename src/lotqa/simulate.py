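"""Synthetic helical binary-MLC deliveries.

A helical tomotherapy delivery is described by a *sinogram*: a matrix of
leaf-open times (LOTs, in milliseconds), one row per gantry projection and
one column per binary leaf (64 leaves, 51 projections per rotation on the
Radixact platform).  This module generates planned sinograms from per-site
plan archetypes (field width, pitch, modulation factor, beam-on time,
gantry period) and distorts them with a parameterized leaf-timing error
model — per-fraction latency, per-event jitter, dropped openings — followed
by quantization at the optical position sensor's ~3.0 ms temporal
resolution.  It stands in for delivery telemetry that clinical systems
record but do not publish.

RNG contract
------------
``apply_error_model`` draws from ``default_rng([model.seed, fraction_index])``
in this fixed order: (1) one standard normal for the fraction-level latency,
(2) one standard normal per planned-nonzero event for jitter, row-major,
(3) one uniform per planned-nonzero event for drops.  Standard draws are
scaled by the model's SDs afterwards, so two models differing only in their
SDs share the same underlying random numbers (common random numbers).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError

SITES = ("prostate", "pelvis", "head", "chest", "hn", "sbrt")

#: Per-site plan archetypes: cohort means of field width (cm), pitch,
#: modulation factor, beam-on time (s) and gantry period (s) typical of
#: clinical helical-tomotherapy plans for each site.
DEFAULT_SITE_ARCHETYPES: dict[str, dict[str, float]] = {
    "prostate": dict(field_width_cm=2.5, pitch=0.414, modulation_factor=2.0,
                     beam_on_time_s=238.18, gantry_period_s=27.17),
    "pelvis": dict(field_width_cm=2.5, pitch=0.437, modulation_factor=2.1,
                   beam_on_time_s=302.01, gantry_period_s=16.34),
    "head": dict(field_width_cm=2.5, pitch=0.442, modulation_factor=2.4286,
                 beam_on_time_s=154.07, gantry_period_s=14.51),
    "chest": dict(field_width_cm=2.5, pitch=0.433, modulation_factor=2.0333,
                  beam_on_time_s=330.88, gantry_period_s=17.15),
    "hn": dict(field_width_cm=2.5, pitch=0.433, modulation_factor=2.64,
               beam_on_time_s=273.68, gantry_period_s=14.68),
    "sbrt": dict(field_width_cm=2.5, pitch=0.178, modulation_factor=2.0,
                 beam_on_time_s=450.93, gantry_period_s=33.18),
}

MODULATION_TOLERANCE = 0.10  # realized MF must be within +-10% of requested


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlanParameters:
    """Archetype parameters of one helical plan.

    ``open_leaf_band`` is a half-open ``(lo, hi)`` pair of leaf indices
    delimiting the leaves eligible to open; it defaults to the central half
    of the 64-leaf bank.
    """

    plan_id: str
    site: str
    field_width_cm: float
    pitch: float
    modulation_factor: float
    gantry_period_s: float
    beam_on_time_s: float
    n_leaves: int = 64
    projections_per_rotation: int = 51
    open_leaf_band: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ParameterError(f"unknown site {self.site!r}; expected one of {SITES}")
        if self.modulation_factor < 1:
            raise ParameterError(f"modulation_factor must be >= 1, got {self.modulation_factor}")
        if self.pitch <= 0:
            raise ParameterError(f"pitch must be > 0, got {self.pitch}")
        if self.gantry_period_s <= 0:
            raise ParameterError(f"gantry_period_s must be > 0, got {self.gantry_period_s}")
        if self.beam_on_time_s <= 0:
            raise ParameterError(f"beam_on_time_s must be > 0, got {self.beam_on_time_s}")
        if self.n_leaves < 1 or self.projections_per_rotation < 1:
            raise ParameterError("n_leaves and projections_per_rotation must be >= 1")
        band = self.open_leaf_band
        if band is None:
            quarter = self.n_leaves // 4
            band = (quarter, self.n_leaves - quarter)
            object.__setattr__(self, "open_leaf_band", band)
        lo, hi = band
        if not (0 <= lo < hi <= self.n_leaves):
            raise ParameterError(f"open_leaf_band {band} not within [0, {self.n_leaves}]")
        if self.n_projections < 1:
            raise ParameterError(
                f"plan spans {self.n_projections} projections; need at least 1 "
                f"(beam_on_time_s={self.beam_on_time_s}, projection "
                f"duration={self.projection_duration_s:.4f} s)")

    @property
    def projection_duration_s(self) -> float:
        return self.gantry_period_s / self.projections_per_rotation

    @property
    def projection_duration_ms(self) -> float:
        return self.projection_duration_s * 1000.0

    @property
    def n_projections(self) -> int:
        return int(round(self.beam_on_time_s / self.projection_duration_s))


@dataclass(frozen=True)
class PlannedSinogram:
    """Planned LOT matrix (ms), projections x leaves, for one plan."""

    plan_id: str
    lot_ms: np.ndarray
    projection_duration_ms: float

    def __post_init__(self) -> None:
        lot = np.asarray(self.lot_ms, dtype=float)
        object.__setattr__(self, "lot_ms", lot)
        if lot.ndim != 2:
            raise ValidationError(f"lot_ms must be 2-D, got shape {lot.shape}")
        if np.any(lot < 0):
            raise ValidationError("planned LOTs must be >= 0")
        if np.any(lot > self.projection_duration_ms * (1 + 1e-9)):
            raise ValidationError("planned LOTs must not exceed the projection duration")
        # an all-zero matrix is representable (so files round-trip) but any
        # attainment computed from it raises UndefinedStatisticError

    @property
    def n_events(self) -> int:
        """Number of planned leaf openings (nonzero entries)."""
        return int(np.count_nonzero(self.lot_ms))

    @property
    def realized_modulation_factor(self) -> float:
        nz = self.lot_ms[self.lot_ms > 0]
        return float(nz.max() / nz.mean())


@dataclass(frozen=True)
class MeasuredSinogram:
    """Telemetry-measured LOT matrix for one treatment fraction.

    Every entry is an integer multiple of the optical sensor's temporal
    resolution; ``detector_signal`` is the fraction's relative exit-detector
    signal (baseline 1.0).
    """

    plan_id: str
    fraction_index: int
    lot_ms: np.ndarray
    projection_duration_ms: float
    sensor_resolution_ms: float = 3.0
    detector_signal: float = 1.0

    def __post_init__(self) -> None:
        lot = np.asarray(self.lot_ms, dtype=float)
        object.__setattr__(self, "lot_ms", lot)
        if self.fraction_index < 1:
            raise ValidationError(f"fraction_index must be >= 1, got {self.fraction_index}")
        if lot.ndim != 2:
            raise ValidationError(f"lot_ms must be 2-D, got shape {lot.shape}")
        if np.any(lot < 0) or np.any(lot > self.projection_duration_ms * (1 + 1e-9)):
            raise ValidationError("measured LOTs must lie in [0, projection_duration_ms]")
        res = self.sensor_resolution_ms
        if res <= 0:
            raise ValidationError("sensor_resolution_ms must be > 0")
        multiples = np.round(lot / res)
        if not np.allclose(lot, multiples * res, atol=1e-6):
            raise ValidationError(
                "measured LOTs must be integer multiples of the sensor resolution")


@dataclass(frozen=True)
class ErrorModel:
    """Leaf-timing error model applied between plan and telemetry.

    latency is drawn once per fraction (a systematic plan-level delay),
    jitter once per leaf opening; a dropped opening is recorded as LOT 0
    but remains a planned event for the attainment denominator.
    """

    latency_mean_ms: float = 0.0
    latency_sd_ms: float = 0.0
    jitter_sd_ms: float = 0.0
    drop_probability: float = 0.0
    sensor_resolution_ms: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latency_sd_ms < 0 or self.jitter_sd_ms < 0:
            raise ParameterError("latency_sd_ms and jitter_sd_ms must be >= 0")
        if not 0.0 <= self.drop_probability <= 1.0:
            raise ParameterError(f"drop_probability must be in [0,1], got {self.drop_probability}")
        if self.sensor_resolution_ms <= 0:
            raise ParameterError("sensor_resolution_ms must be > 0")


# ---------------------------------------------------------------------------
# plan generation
# ---------------------------------------------------------------------------

def _rescale_to_modulation_factor(values: np.ndarray, target_mf: float,
                                  peak_ms: float, floor_ms: float,
                                  ceil_ms: float) -> np.ndarray:
    """Affinely rescale positive samples so max/mean hits ``target_mf``.

    The affine map sets the sample maximum to ``peak_ms`` and the mean to
    ``peak_ms / target_mf``; clipping to [floor, ceil] perturbs the ratio,
    so the map is iterated to a fixed point.
    """
    if target_mf == 1.0:
        return np.full_like(values, peak_ms)
    v = values.astype(float).copy()
    target_mean = peak_ms / target_mf
    for _ in range(25):
        vmax, vmean = v.max(), v.mean()
        if vmax - vmean <= 1e-12:  # degenerate spread: cannot widen affinely
            break
        alpha = (peak_ms - target_mean) / (vmax - vmean)
        v = np.clip(alpha * (v - vmean) + target_mean, floor_ms, ceil_ms)
        mf = v.max() / v.mean()
        if abs(mf - target_mf) / target_mf < 1e-3:
            break
    return v


def generate_plan(params: PlanParameters, seed: int,
                  open_probability: float = 0.7,
                  beta_a: float = 1.5, beta_b: float = 3.0) -> PlannedSinogram:
    """Generate a planned sinogram for one plan archetype.

    Openings are restricted to ``params.open_leaf_band``; each eligible
    (projection, leaf) cell opens with probability ``open_probability``.
    Nonzero LOTs are drawn from a Beta(a, b) shape scaled to the projection
    duration, then affinely rescaled so the realized modulation factor
    (max nonzero LOT / mean nonzero LOT) lands within 10% of the request.
    Deterministic for a fixed seed.
    """
    if not 0.0 < open_probability <= 1.0:
        raise ParameterError(f"open_probability must be in (0,1], got {open_probability}")
    rng = np.random.default_rng(seed)
    n_proj = params.n_projections
    duration = params.projection_duration_ms
    lo, hi = params.open_leaf_band

    mask = np.zeros((n_proj, params.n_leaves), dtype=bool)
    mask[:, lo:hi] = rng.random((n_proj, hi - lo)) < open_probability
    if not mask.any():
        mask[n_proj // 2, (lo + hi) // 2] = True

    n_open = int(mask.sum())
    raw = rng.beta(beta_a, beta_b, size=n_open)
    peak = 0.9 * duration
    floor = max(1.0, 0.005 * duration)
    values = _rescale_to_modulation_factor(raw, params.modulation_factor,
                                           peak, floor, duration)
    lot = np.zeros((n_proj, params.n_leaves))
    lot[mask] = values
    sino = PlannedSinogram(params.plan_id, lot, duration)
    mf = sino.realized_modulation_factor
    if abs(mf - params.modulation_factor) / params.modulation_factor > MODULATION_TOLERANCE:
        raise ParameterError(
            f"could not realize modulation factor {params.modulation_factor} "
            f"(achieved {mf:.3f}); too few openings or infeasible request")
    return sino


# ---------------------------------------------------------------------------
# error model
# ---------------------------------------------------------------------------

def quantize_to_resolution(values: np.ndarray, resolution_ms: float,
                           max_ms: float | None = None) -> np.ndarray:
    """Round to the nearest multiple of the sensor resolution.

    Ties round half away from zero.  If ``max_ms`` is given the result is
    capped at the largest multiple of the resolution not exceeding it, so
    quantized values never leave the physical [0, projection duration] range.
    """
    v = np.asarray(values, dtype=float)
    q = np.floor(v / resolution_ms + 0.5) * resolution_ms
    if max_ms is not None:
        q = np.minimum(q, np.floor(max_ms / resolution_ms) * resolution_ms)
    return q


def apply_error_model(plan: PlannedSinogram, model: ErrorModel,
                      fraction_index: int,
                      detector_signal: float = 1.0) -> MeasuredSinogram:
    """Distort a planned sinogram into one fraction's measured sinogram.

    For each planned opening: with probability ``drop_probability`` the
    measured LOT is 0; otherwise measured = planned + latency + jitter,
    clamped to [0, projection duration] and quantized to the sensor
    resolution.  Planned-zero cells stay zero.  See the module docstring
    for the RNG draw order (the determinism contract).
    """
    if fraction_index < 1:
        raise ParameterError(f"fraction_index must be >= 1, got {fraction_index}")
    rng = np.random.default_rng([model.seed, fraction_index])
    nz = plan.lot_ms > 0
    n = int(nz.sum())

    latency = model.latency_mean_ms + model.latency_sd_ms * rng.standard_normal()
    jitter = model.jitter_sd_ms * rng.standard_normal(n)
    dropped = rng.random(n) < model.drop_probability

    raw = plan.lot_ms[nz] + latency + jitter
    raw[dropped] = 0.0
    clamped = np.clip(raw, 0.0, plan.projection_duration_ms)
    quantized = quantize_to_resolution(clamped, model.sensor_resolution_ms,
                                       max_ms=plan.projection_duration_ms)
    lot = np.zeros_like(plan.lot_ms)
    lot[nz] = quantized
    return MeasuredSinogram(plan.plan_id, fraction_index, lot,
                            plan.projection_duration_ms,
                            sensor_resolution_ms=model.sensor_resolution_ms,
                            detector_signal=detector_signal)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

SESSION_COLUMNS = ["plan_id", "site", "fraction", "eta_percent",
                   "gamma_delta4", "gamma_film_cor", "gamma_film_sag",
                   "detector_signal", "phase"]


def _synthetic_gamma(eta: float, slope: float, noise: float) -> float:
    """Gamma pass rate linked linearly to attainment: 100 - slope*(100*(1-eta)) - noise."""
    return float(np.clip(100.0 - slope * (100.0 * (1.0 - eta)) - noise, 0.0, 100.0))


def generate_cohort(site_specs: Sequence[tuple[PlanParameters, ErrorModel, int]],
                    seed: int, bin_width_ms: float = 5.0,
                    gamma_slope: float = 0.8, gamma_noise_sd: float = 0.5,
                    detector_noise_sd: float = 0.005,
                    phase: str = "treatment",
                    ) -> tuple[list[PlannedSinogram], list[MeasuredSinogram], pd.DataFrame]:
    """Simulate a cohort of plans and fractions and assemble the session table.

    Each spec is (plan parameters, error model, number of fractions).  The
    session table has one row per measured fraction with the attainment rate
    (computed through the difference histogram at ``bin_width_ms``),
    synthetic gamma pass rates correlated with attainment, and detector
    signals.  Fully deterministic under ``seed``; the error models' own
    seeds are re-derived from it.
    """
    from .attainment import compute_attainment  # deferred: avoids import cycle

    specs = list(site_specs)
    if not specs:
        raise ParameterError("site_specs must contain at least one plan")
    for _, _, n_fractions in specs:
        if n_fractions < 1:
            raise ParameterError("n_fractions must be >= 1")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(specs))
    planned: list[PlannedSinogram] = []
    measured: list[MeasuredSinogram] = []
    rows = []
    for (params, model, n_fractions), child in zip(specs, children):
        plan_seed, model_seed, aux_seed = (int(s) for s in
                                           child.generate_state(3) >> np.uint32(1))
        plan = generate_plan(params, plan_seed)
        planned.append(plan)
        model = dataclasses.replace(model, seed=model_seed)
        aux = np.random.default_rng(aux_seed)
        for frac in range(1, n_fractions + 1):
            signal = 1.0 + detector_noise_sd * aux.standard_normal()
            meas = apply_error_model(plan, model, frac, detector_signal=signal)
            measured.append(meas)
            result = compute_attainment(plan, meas, bin_width_ms)
            noise = gamma_noise_sd * np.abs(aux.standard_normal(3))
            rows.append({
                "plan_id": params.plan_id, "site": params.site, "fraction": frac,
                "eta_percent": result.eta_percent,
                "gamma_delta4": _synthetic_gamma(result.eta, gamma_slope, noise[0]),
                "gamma_film_cor": _synthetic_gamma(result.eta, gamma_slope * 0.9, noise[1]),
                "gamma_film_sag": _synthetic_gamma(result.eta, gamma_slope * 0.9, noise[2]),
                "detector_signal": signal, "phase": phase,
            })
    table = pd.DataFrame(rows, columns=SESSION_COLUMNS)
    return planned, measured, table


def generate_detector_trend(n_fractions: int, anomaly_fractions: Iterable[int],
                            anomaly_depth: float, seed: int,
                            noise_sd: float = 0.01) -> np.ndarray:
    """Per-fraction relative exit-detector signals with optional anomalies.

    Baseline 1.0 with Gaussian noise; fractions listed in
    ``anomaly_fractions`` (1-based) are depressed by ``anomaly_depth``
    (e.g. depth 0.1 -> ~0.9x baseline), emulating days on which the exit
    signal and the attainment rate co-decline.
    """
    anomalies = set(anomaly_fractions)
    if n_fractions < 1:
        raise ParameterError("n_fractions must be >= 1")
    if not anomalies <= set(range(1, n_fractions + 1)):
        raise ParameterError(f"anomaly_fractions {sorted(anomalies)} outside 1..{n_fractions}")
    if not 0.0 <= anomaly_depth < 1.0:
        raise ParameterError(f"anomaly_depth must be in [0,1), got {anomaly_depth}")
    rng = np.random.default_rng(seed)
    signals = 1.0 + noise_sd * rng.standard_normal(n_fractions)
    for frac in anomalies:
        signals[frac - 1] *= 1.0 - anomaly_depth
    return signals


def generate_trend_scenario(params: PlanParameters, model: ErrorModel,
                            n_fractions: int, anomaly_fractions: Iterable[int],
                            anomaly_depth: float, seed: int,
                            noise_sd: float = 0.01,
                            bin_width_ms: float = 5.0) -> pd.DataFrame:
    """One plan's session table with detector/attainment co-decline anomalies.

    Anomalous fractions get both a depressed detector signal (via
    ``generate_detector_trend``) and an inflated jitter SD
    (``+ 100*anomaly_depth`` ms), so attainment co-declines with the signal —
    the pattern the fraction-trend monitor is built to flag.
    """
    from .attainment import compute_attainment

    anomalies = set(anomaly_fractions)
    signals = generate_detector_trend(n_fractions, anomalies, anomaly_depth,
                                      seed, noise_sd)
    ss = np.random.SeedSequence(seed)
    plan_seed, model_seed = (int(s) for s in ss.generate_state(2) >> np.uint32(1))
    plan = generate_plan(params, plan_seed)
    inflated = dataclasses.replace(
        model, jitter_sd_ms=model.jitter_sd_ms + 100.0 * anomaly_depth,
        seed=model_seed)
    base = dataclasses.replace(model, seed=model_seed)
    rows = []
    for frac in range(1, n_fractions + 1):
        m = inflated if frac in anomalies else base
        meas = apply_error_model(plan, m, frac, detector_signal=float(signals[frac - 1]))
        result = compute_attainment(plan, meas, bin_width_ms)
        rows.append({"plan_id": params.plan_id, "site": params.site,
                     "fraction": frac, "eta_percent": result.eta_percent,
                     "gamma_delta4": np.nan, "gamma_film_cor": np.nan,
                     "gamma_film_sag": np.nan,
                     "detector_signal": float(signals[frac - 1]),
                     "phase": "treatment"})
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def default_cohort_specs(n_plans_per_site: int = 2, n_fractions: int = 5,
                         error_model: ErrorModel | None = None,
                         ) -> list[tuple[PlanParameters, ErrorModel, int]]:
    """Site-archetype cohort: ``n_plans_per_site`` plans for each of the six sites."""
    model = error_model if error_model is not None else ErrorModel(
        latency_mean_ms=0.0, latency_sd_ms=0.5, jitter_sd_ms=1.0,
        drop_probability=0.0005)
    specs = []
    for site in SITES:
        arch = DEFAULT_SITE_ARCHETYPES[site]
        for k in range(n_plans_per_site):
            params = PlanParameters(plan_id=f"{site}-{k + 1:02d}", site=site, **arch)
            specs.append((params, model, n_fractions))
    return specs
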