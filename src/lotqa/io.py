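"""File interchange: sinogram CSV, session CSV, cohort-config JSON.

All writers are deterministic — stable row order, fixed float formatting —
so identical inputs produce byte-identical files and runs can be audited by
hash.  The sinogram dialect is a sparse long format (one row per nonzero
event: zero LOTs are omitted, which also encodes the rule that a closed
leaf is not an event), preceded by ``# key=value`` metadata lines that
carry the dense-matrix shape and, for measured fractions, the sensor
resolution and detector signal.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError
from .simulate import (DEFAULT_SITE_ARCHETYPES, SITES, ErrorModel,
                       MeasuredSinogram, PlanParameters, PlannedSinogram)

SINOGRAM_COLUMNS = ["plan_id", "fraction", "projection", "leaf", "lot_ms"]
SESSION_COLUMNS = ["plan_id", "site", "fraction", "eta_percent",
                   "gamma_delta4", "gamma_film_cor", "gamma_film_sag",
                   "detector_signal", "phase"]
_SESSION_REQUIRED = ["plan_id", "site", "fraction", "eta_percent"]
_PERCENT_COLUMNS = ["eta_percent", "gamma_delta4", "gamma_film_cor", "gamma_film_sag"]


# ---------------------------------------------------------------------------
# sinogram CSV
# ---------------------------------------------------------------------------

def write_sinogram_csv(sinogram: PlannedSinogram | MeasuredSinogram,
                       path: str | Path) -> None:
    """Write one sinogram in the sparse long dialect (fraction 0 = plan)."""
    is_measured = isinstance(sinogram, MeasuredSinogram)
    fraction = sinogram.fraction_index if is_measured else 0
    lines = ["# lotqa-sinogram v1",
             f"# n_projections={sinogram.lot_ms.shape[0]}",
             f"# n_leaves={sinogram.lot_ms.shape[1]}",
             f"# projection_duration_ms={float(sinogram.projection_duration_ms)!r}"]
    if is_measured:
        lines.append(f"# sensor_resolution_ms={float(sinogram.sensor_resolution_ms)!r}")
        lines.append(f"# detector_signal={float(sinogram.detector_signal)!r}")
    lines.append(",".join(SINOGRAM_COLUMNS))
    rows, cols = np.nonzero(sinogram.lot_ms)
    for r, c in zip(rows, cols):  # np.nonzero is row-major, hence sorted
        lines.append(f"{sinogram.plan_id},{fraction},{r},{c},"
                     f"{float(sinogram.lot_ms[r, c])!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_sinogram_csv(path: str | Path) -> PlannedSinogram | MeasuredSinogram:
    """Read a sinogram CSV; fraction 0 yields a planned sinogram.

    Absent (projection, leaf) rows are zero.  Duplicate event rows, negative
    LOTs and out-of-range indices are rejected with errors naming the
    offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such sinogram file: {path}")
    meta = _read_metadata(path)
    for key in ("n_projections", "n_leaves", "projection_duration_ms"):
        if key not in meta:
            raise FormatError(f"{path}: missing '# {key}=' metadata line")
    n_proj = int(meta["n_projections"])
    n_leaves = int(meta["n_leaves"])
    duration = float(meta["projection_duration_ms"])

    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if list(df.columns) != SINOGRAM_COLUMNS:
        raise FormatError(f"{path}: header {list(df.columns)} != {SINOGRAM_COLUMNS}")
    dup = df.duplicated(subset=["projection", "leaf"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FormatError(f"{path}: duplicate event row (projection={int(row.projection)}, "
                          f"leaf={int(row.leaf)})")
    if (df["lot_ms"] < 0).any():
        row = df[df["lot_ms"] < 0].iloc[0]
        raise ValidationError(f"{path}: negative LOT {row.lot_ms} at "
                              f"(projection={int(row.projection)}, leaf={int(row.leaf)})")
    bad_leaf = ~df["leaf"].between(0, n_leaves - 1)
    if bad_leaf.any():
        raise ValidationError(f"{path}: leaf index {int(df[bad_leaf].iloc[0].leaf)} "
                              f"outside [0, {n_leaves - 1}]")
    bad_proj = ~df["projection"].between(0, n_proj - 1)
    if bad_proj.any():
        raise ValidationError(f"{path}: projection index "
                              f"{int(df[bad_proj].iloc[0].projection)} outside [0, {n_proj - 1}]")
    if df["plan_id"].nunique() > 1 or df["fraction"].nunique() > 1:
        raise FormatError(f"{path}: mixed plan_id or fraction values in one file")

    lot = np.zeros((n_proj, n_leaves))
    lot[df["projection"].to_numpy(), df["leaf"].to_numpy()] = df["lot_ms"].to_numpy()
    plan_id = str(df["plan_id"].iloc[0]) if len(df) else "unknown"
    fraction = int(df["fraction"].iloc[0]) if len(df) else 0
    if fraction == 0:
        return PlannedSinogram(plan_id, lot, duration)
    return MeasuredSinogram(
        plan_id, fraction, lot, duration,
        sensor_resolution_ms=float(meta.get("sensor_resolution_ms", 3.0)),
        detector_signal=float(meta.get("detector_signal", 1.0)))


# ---------------------------------------------------------------------------
# session CSV
# ---------------------------------------------------------------------------

def write_session_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a session table; percent columns carry exactly 3 decimals."""
    df = table.copy()
    for col in SESSION_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[SESSION_COLUMNS]
    lines = [",".join(SESSION_COLUMNS)]
    for _, row in df.iterrows():
        cells = [str(row.plan_id), str(row.site), str(int(row.fraction))]
        for col in _PERCENT_COLUMNS:
            v = row[col]
            cells.append("" if pd.isna(v) else f"{v:.3f}")
        sig = row.detector_signal
        cells.append("" if pd.isna(sig) else f"{sig:.6f}")
        cells.append("" if pd.isna(row.phase) else str(row.phase))
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_session_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a session table.

    Missing optional columns (gammas, detector signal, phase) become absent
    values; out-of-range percentages are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such session file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in _SESSION_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    for col in SESSION_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[SESSION_COLUMNS]
    for col in _PERCENT_COLUMNS:
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 100)).any():
            bad = vals[(vals < 0) | (vals > 100)].iloc[0]
            raise ValidationError(f"{path}: {col} value {bad} outside [0, 100]")
    return df


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------

_ARCHETYPE_KEYS = {"field_width_cm", "pitch", "modulation_factor",
                   "beam_on_time_s", "gantry_period_s", "n_leaves",
                   "projections_per_rotation", "open_leaf_band"}
_ERROR_KEYS = {"latency_mean_ms", "latency_sd_ms", "jitter_sd_ms",
               "drop_probability", "sensor_resolution_ms", "seed"}
_ANALYSIS_KEYS = {"aggregation", "fence_multiplier", "signal_threshold_z",
                  "eta_threshold_z", "gamma_slope", "gamma_noise_sd",
                  "detector_noise_sd"}


@dataclass(frozen=True)
class CohortConfig:
    """Everything a simulation + analysis run needs, JSON round-trippable."""

    site_archetypes: dict[str, dict[str, Any]] = field(
        default_factory=lambda: {s: dict(a) for s, a in DEFAULT_SITE_ARCHETYPES.items()})
    error_model: dict[str, Any] = field(default_factory=lambda: {
        "latency_mean_ms": 0.0, "latency_sd_ms": 0.5, "jitter_sd_ms": 1.0,
        "drop_probability": 0.0005, "sensor_resolution_ms": 3.0})
    seed: int = 0
    n_plans_per_site: int = 2
    n_fractions: int = 5
    bin_width_ms: float = 5.0
    analysis: dict[str, Any] = field(default_factory=lambda: {
        "aggregation": "session", "fence_multiplier": 1.5,
        "signal_threshold_z": 3.0, "eta_threshold_z": 3.0,
        "gamma_slope": 0.8, "gamma_noise_sd": 0.5, "detector_noise_sd": 0.005})

    def __post_init__(self) -> None:
        for site, arch in self.site_archetypes.items():
            if site not in SITES:
                raise ConfigurationError(f"unknown site {site!r} in config")
            unknown = set(arch) - _ARCHETYPE_KEYS
            if unknown:
                raise ConfigurationError(f"unknown archetype keys for {site}: {sorted(unknown)}")
        unknown = set(self.error_model) - _ERROR_KEYS
        if unknown:
            raise ConfigurationError(f"unknown error-model keys: {sorted(unknown)}")
        unknown = set(self.analysis) - _ANALYSIS_KEYS
        if unknown:
            raise ConfigurationError(f"unknown analysis keys: {sorted(unknown)}")
        if self.n_plans_per_site < 1 or self.n_fractions < 1:
            raise ConfigurationError("n_plans_per_site and n_fractions must be >= 1")
        if self.bin_width_ms <= 0:
            raise ConfigurationError("bin_width_ms must be > 0")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n",
                              encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"no such config file: {path}")
        try:
            data = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON ({exc})") from exc
        return cls.from_dict(data)

    def cohort_specs(self) -> list[tuple[PlanParameters, ErrorModel, int]]:
        """Expand the config into (plan, error model, n_fractions) triples."""
        model = ErrorModel(**self.error_model)
        specs = []
        for site in sorted(self.site_archetypes):
            arch = dict(self.site_archetypes[site])
            if arch.get("open_leaf_band") is not None:
                arch["open_leaf_band"] = tuple(arch["open_leaf_band"])
            for k in range(self.n_plans_per_site):
                params = PlanParameters(plan_id=f"{site}-{k + 1:02d}", site=site, **arch)
                specs.append((params, model, self.n_fractions))
        return specs
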