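"""Cohort-level QA statistics for attainment rates.

Aggregates attainment across fractions, plans and sites; screens outliers
with box-plot IQR fences; correlates attainment with gamma pass rates
(Spearman, with the conventional five-level strength classification) and
compares site means against the whole cohort (Welch's t); and flags
treatment fractions where the exit-detector signal and the attainment rate
decline together.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (ConfigurationError, InsufficientDataError,
                     ParameterError, UndefinedStatisticError)

logger = logging.getLogger("lotqa")

DEFAULT_FENCE_MULTIPLIER = 1.5
SIGNIFICANCE_LEVEL = 0.05
#: |rho| cutpoints between the five strength classes (right-open intervals).
STRENGTH_CUTPOINTS = (0.2, 0.4, 0.6, 0.8)
STRENGTH_LABELS = ("very_weak", "weak", "moderate", "strong", "very_strong")
_MAD_SCALE = 1.4826  # normal-consistency constant for the MAD


# ---------------------------------------------------------------------------
# aggregation and outliers
# ---------------------------------------------------------------------------

class IQROutliers(NamedTuple):
    iqr: float
    fences: tuple[float, float]
    outlier_indices: list[int]


@dataclass(frozen=True)
class GroupSummary:
    group_label: str
    n: int
    mean: float
    sd: float
    iqr: float
    outliers: list[tuple[str, int, float]] = field(default_factory=list)


def iqr_outliers(values: Sequence[float],
                 fence_multiplier: float = DEFAULT_FENCE_MULTIPLIER) -> IQROutliers:
    """Box-plot outlier screen.

    Quartiles use linear interpolation between order statistics (the
    ubiquitous "type 7" estimator); fences sit at Q1 - m*IQR and
    Q3 + m*IQR, and outliers are values strictly outside them.  Low-side
    outliers are the QA-relevant ones — they mark attainment-degrading
    sessions.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise InsufficientDataError(
            f"IQR outlier screen needs at least 4 values, got {v.size}")
    q1, q3 = np.percentile(v, [25, 75])  # linear interpolation (type 7)
    iqr = float(q3 - q1)
    lo, hi = q1 - fence_multiplier * iqr, q3 + fence_multiplier * iqr
    idx = np.flatnonzero((v < lo) | (v > hi))
    return IQROutliers(iqr, (float(lo), float(hi)), idx.tolist())


def summarize(records: pd.DataFrame, group_by: str = "site",
              fence_multiplier: float = DEFAULT_FENCE_MULTIPLIER,
              aggregation: str = "session") -> list[GroupSummary]:
    """Per-group attainment summaries: n, mean, sample SD, IQR, IQR outliers.

    ``group_by`` is one of {"plan", "site", "all"}.  The default "session"
    aggregation pools individual sessions within each group; "plan" first
    averages each plan's sessions and summarizes the plan means.  Groups are
    returned ordered by label; a single-session group reports SD 0 with a
    logged warning.
    """
    if records.empty:
        raise ParameterError("records must be non-empty")
    if records["eta_percent"].isna().any():
        raise ParameterError("every record needs eta_percent")
    if aggregation not in ("session", "plan"):
        raise ParameterError(f"unknown aggregation {aggregation!r}")
    key = {"plan": "plan_id", "site": "site", "all": None}.get(group_by, "missing")
    if key == "missing":
        raise ParameterError(f"group_by must be plan, site or all, got {group_by!r}")

    df = records.sort_values(["plan_id", "fraction"], kind="stable")
    groups = [("all", df)] if key is None else sorted(df.groupby(key), key=lambda g: str(g[0]))
    out = []
    for label, g in groups:
        if aggregation == "plan":
            pooled = g.groupby("plan_id")["eta_percent"].mean()
            values = pooled.to_numpy()
            ids = [(pid, -1, float(v)) for pid, v in pooled.items()]
        else:
            values = g["eta_percent"].to_numpy(dtype=float)
            ids = list(zip(g["plan_id"], g["fraction"].astype(int),
                           g["eta_percent"].astype(float)))
        n = values.size
        if n == 1:
            logger.warning("group %r has a single value; SD reported as 0", label)
            sd = 0.0
        else:
            sd = float(np.std(values, ddof=1))
        if n >= 4:
            res = iqr_outliers(values, fence_multiplier)
            iqr, outliers = res.iqr, [ids[i] for i in res.outlier_indices]
        else:
            q1, q3 = np.percentile(values, [25, 75]) if n > 1 else (values[0], values[0])
            iqr = float(q3 - q1)
            outliers = []
        out.append(GroupSummary(str(label), int(n), float(np.mean(values)),
                                sd, float(iqr), outliers))
    return out


def summaries_to_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    rows = [{"group": s.group_label, "n": s.n, "mean": s.mean, "sd": s.sd,
             "iqr": s.iqr,
             "n_outliers": len(s.outliers),
             "outliers": ";".join(f"{p}:f{f}:{v:.3f}" for p, f, v in s.outliers)}
            for s in summaries]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    strength: str
    n: int


def classify_strength(rho: float) -> str:
    """Five-level label for |rho|: <0.2 very_weak, <0.4 weak, <0.6 moderate,
    <0.8 strong, otherwise very_strong."""
    a = abs(rho)
    if not a <= 1 + 1e-12:
        raise ParameterError(f"|rho| must be <= 1, got {rho}")
    for cut, label in zip(STRENGTH_CUTPOINTS, STRENGTH_LABELS):
        if a < cut:
            return label
    return STRENGTH_LABELS[-1]


def _rank_pearson(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    return float(rxc @ ryc) / denom


EXACT_PERMUTATION_MAX_N = 9


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with exact small-sample p-values.

    rho is the Pearson correlation of average ranks (ties averaged).  The
    two-sided p-value enumerates all n! rank permutations exactly for
    n <= 9; larger samples use the usual t approximation with n-2 degrees
    of freedom.  Constant input makes the correlation undefined.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ParameterError(f"length mismatch: {xv.size} vs {yv.size}")
    n = xv.size
    if n < 3:
        raise InsufficientDataError(f"Spearman needs n >= 3, got {n}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    rx = sps.rankdata(xv)
    ry = sps.rankdata(yv)
    rho = _rank_pearson(rx, ry)

    if n <= EXACT_PERMUTATION_MAX_N:
        target = abs(rho) - 1e-12
        hits = sum(abs(_rank_pearson(rx, np.asarray(perm))) >= target
                   for perm in itertools.permutations(ry))
        p = hits / math.factorial(n)
    else:
        t = rho * math.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(rho=rho, p_value=float(min(p, 1.0)),
                             strength=classify_strength(rho), n=int(n))


# ---------------------------------------------------------------------------
# Welch's t
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    df: float
    p_value: float


def welch_t(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Two-sample mean comparison without the equal-variance assumption.

    Uses Welch's statistic with Welch–Satterthwaite degrees of freedom and
    a two-sided p-value.  Undefined when both samples are constant (the
    variance estimate collapses).
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.size < 2 or bv.size < 2:
        raise InsufficientDataError("Welch's t needs n >= 2 in both samples")
    if np.var(av, ddof=1) == 0 and np.var(bv, ddof=1) == 0:
        raise UndefinedStatisticError(
            "t statistic undefined: both samples have zero variance")
    res = sps.ttest_ind(av, bv, equal_var=False)
    return WelchResult(t_statistic=float(res.statistic), df=float(res.df),
                       p_value=float(res.pvalue))


def site_vs_all_tests(records: pd.DataFrame,
                      metrics: Sequence[str] = ("eta_percent",)) -> pd.DataFrame:
    """Welch tests of each site's sessions against the whole cohort.

    Returns one row per (site, metric) with t, df and the two-sided
    p-value; sites with fewer than two non-missing values for a metric are
    skipped with a logged warning.
    """
    missing = [m for m in metrics if m not in records.columns]
    if missing:
        raise ConfigurationError(f"metric columns absent from records: {missing}")
    rows = []
    for site in sorted(records["site"].unique()):
        for metric in metrics:
            a = records.loc[records["site"] == site, metric].dropna().to_numpy()
            b = records[metric].dropna().to_numpy()
            if a.size < 2:
                logger.warning("site %s has < 2 values for %s; skipped", site, metric)
                continue
            try:
                res = welch_t(a, b)
            except UndefinedStatisticError:
                logger.warning("degenerate variance for %s/%s; skipped", site, metric)
                continue
            rows.append({"site": site, "metric": metric,
                         "t_statistic": res.t_statistic, "df": res.df,
                         "p_value": res.p_value,
                         "significant": res.p_value < SIGNIFICANCE_LEVEL})
    return pd.DataFrame(rows, columns=["site", "metric", "t_statistic", "df",
                                       "p_value", "significant"])


# ---------------------------------------------------------------------------
# fraction trend monitoring
# ---------------------------------------------------------------------------

def fraction_trend(records: pd.DataFrame, signal_threshold_z: float = 3.0,
                   eta_threshold_z: float = 3.0) -> list[int]:
    """Fractions of one plan where detector signal and attainment co-decline.

    A fraction is flagged when its detector signal falls below
    median - z_s * (scaled MAD) AND its attainment rate falls below
    median - z_e * (scaled MAD); both conditions are required, so an
    attainment dip without a detector dip (or vice versa) is not flagged.
    Median/MAD are used instead of mean/SD because treatment courses are
    short (often <= 10 fractions) and a couple of anomalous days would
    otherwise inflate the spread estimate.
    """
    for col in ("detector_signal", "eta_percent", "fraction"):
        if col not in records.columns:
            raise ConfigurationError(f"records lack required column {col!r}")
    df = records.dropna(subset=["detector_signal", "eta_percent"])
    if len(df) < 3:
        raise InsufficientDataError(
            f"trend monitoring needs >= 3 complete fractions, got {len(df)}")

    def lower_threshold(x: np.ndarray, z: float) -> float:
        med = float(np.median(x))
        mad = _MAD_SCALE * float(np.median(np.abs(x - med)))
        return med - z * mad

    sig = df["detector_signal"].to_numpy(dtype=float)
    eta = df["eta_percent"].to_numpy(dtype=float)
    flag = (sig < lower_threshold(sig, signal_threshold_z)) & \
           (eta < lower_threshold(eta, eta_threshold_z))
    return sorted(int(f) for f in df.loc[flag, "fraction"])


# ---------------------------------------------------------------------------
# optional figure export
# ---------------------------------------------------------------------------

def boxplot_by_site(records: pd.DataFrame, path: str) -> None:
    """Box-and-whisker plot of attainment rates by site, saved to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sites = sorted(records["site"].unique())
    data = [records.loc[records["site"] == s, "eta_percent"] for s in sites]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.boxplot(data, tick_labels=sites)
    ax.set_ylabel("LOT attainment rate (%)")
    ax.set_xlabel("treatment site")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
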