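"""Aggregation, outlier screening, correlation and Welch tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lotqa import (ConfigurationError, InsufficientDataError,
                   UndefinedStatisticError, classify_strength, fraction_trend,
                   iqr_outliers, site_vs_all_tests, spearman, summarize,
                   welch_t)


def sessions(values, site="prostate", plan_id="p1", **extra):
    rows = [{"plan_id": plan_id, "site": site, "fraction": i + 1,
             "eta_percent": v, **extra} for i, v in enumerate(values)]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# summarize
# ---------------------------------------------------------------------------

class TestSummarize:
    def test_constant_group(self):
        (summ,) = summarize(sessions([95.0, 95.0, 95.0]), group_by="all")
        assert (summ.n, summ.mean, summ.sd, summ.iqr) == (3, 95.0, 0.0, 0.0)
        assert summ.outliers == []

    def test_mean_and_sample_sd_against_two_pass_arithmetic(self):
        values = [90.0, 94.0, 95.0, 96.0, 99.0]
        (summ,) = summarize(sessions(values), group_by="all")
        mean = sum(values) / 5
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / 4)
        assert summ.mean == pytest.approx(mean)   # 94.8
        assert summ.sd == pytest.approx(sd)       # 3.2710...
        assert summ.sd == pytest.approx(3.27108, abs=1e-5)

    def test_groups_split_by_site(self):
        df = pd.concat([sessions([94, 95, 96], site="prostate"),
                        sessions([90, 92], site="pelvis", plan_id="p2")])
        summs = summarize(df, group_by="site")
        assert [(s.group_label, s.n) for s in summs] == [("pelvis", 2), ("prostate", 3)]

    def test_single_session_group_reports_zero_sd(self):
        (summ,) = summarize(sessions([97.0]), group_by="all")
        assert summ.sd == 0.0

    def test_permutation_invariance(self, rng):
        df = pd.concat([sessions(rng.uniform(90, 99, 6), site="prostate"),
                        sessions(rng.uniform(90, 99, 6), site="sbrt", plan_id="p2")])
        shuffled = df.sample(frac=1.0, random_state=1)
        a = summarize(df, group_by="site")
        b = summarize(shuffled, group_by="site")
        assert a == b

    def test_plan_mean_aggregation(self):
        df = pd.concat([sessions([90.0, 92.0]),  # plan mean 91
                        sessions([96.0, 98.0], plan_id="p2")])  # plan mean 97
        (summ,) = summarize(df, group_by="all", aggregation="plan")
        assert summ.n == 2
        assert summ.mean == pytest.approx(94.0)

    def test_outliers_surfaced_with_identity(self):
        df = sessions([70.0, 94.0, 95.0, 95.0, 96.0, 96.0, 97.0])
        (summ,) = summarize(df, group_by="all")
        assert summ.outliers == [("p1", 1, 70.0)]


# ---------------------------------------------------------------------------
# IQR outliers
# ---------------------------------------------------------------------------

class TestIQROutliers:
    def test_tight_set_has_no_outliers(self):
        res = iqr_outliers([1.0, 2.0, 3.0, 4.0])
        assert res.outlier_indices == []

    def test_low_side_outlier_flagged_by_hand_fences(self):
        # sorted values: Q1 = 94.5, Q3 = 96 (linear interpolation), IQR = 1.5,
        # lower fence 92.25 -> only 10 falls outside
        values = [10.0, 94.0, 95.0, 95.0, 96.0, 96.0, 97.0]
        res = iqr_outliers(values)
        assert res.iqr == pytest.approx(1.5)
        assert res.fences == (pytest.approx(92.25), pytest.approx(98.25))
        assert res.outlier_indices == [0]

    def test_degenerate_spread(self):
        res = iqr_outliers([95.0] * 6)
        assert res.iqr == 0.0
        assert res.outlier_indices == []

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            iqr_outliers([1.0, 2.0, 3.0])

    def test_inside_value_never_unflags_existing_outlier(self, rng):
        """Adding an in-fence value keeps flagged values flagged when the
        quartiles are unchanged."""
        values = [10.0, 94.0, 95.0, 95.0, 96.0, 96.0, 97.0]
        base = iqr_outliers(values)
        lo, hi = base.fences
        inserted = values + [95.0]  # at the median: quartiles unchanged
        res = iqr_outliers(inserted)
        assert 0 in res.outlier_indices


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def brute_force_spearman_rho(x, y):
    """Rank-Pearson via explicit summation formulas."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(x)
    sx, sy = sum(rx), sum(ry)
    sxx = sum(r * r for r in rx)
    syy = sum(r * r for r in ry)
    sxy = sum(a * b for a, b in zip(rx, ry))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


class TestSpearman:
    def test_monotone_is_perfect_and_very_strong(self):
        res = spearman([1, 2, 3, 4, 5], [10, 20, 25, 40, 80])
        assert res.rho == pytest.approx(1.0)
        assert res.strength == "very_strong"

    def test_rho_and_exact_p_match_exhaustive_enumeration(self, rng):
        """n=6: p from all 720 rank permutations, rho from summation formulas."""
        for _ in range(5):
            x = rng.uniform(0, 1, 6)
            y = rng.uniform(0, 1, 6)
            res = spearman(x, y)
            rho_bf = brute_force_spearman_rho(x, y)
            assert res.rho == pytest.approx(rho_bf, abs=1e-10)
            rx = sps.rankdata(x)
            ry = sps.rankdata(y)
            hits = 0
            for perm in itertools.permutations(ry):
                r = brute_force_spearman_rho(rx, perm)
                if abs(r) >= abs(rho_bf) - 1e-12:
                    hits += 1
            assert res.p_value == pytest.approx(hits / 720, abs=1e-10)

    def test_large_n_uses_t_approximation(self, rng):
        x = rng.uniform(0, 1, 40)
        y = x + rng.normal(0, 0.4, 40)
        res = spearman(x, y)
        t = res.rho * math.sqrt((40 - 2) / (1 - res.rho ** 2))
        assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t), 38), abs=1e-12)

    def test_constant_input_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])

    def test_ties_use_average_ranks(self):
        res = spearman([1, 2, 2, 3], [1, 2, 3, 4])
        assert res.rho == pytest.approx(brute_force_spearman_rho([1, 2, 2, 3],
                                                                 [1, 2, 3, 4]))


class TestStrengthClassification:
    @pytest.mark.parametrize("rho,label", [
        (0.1, "very_weak"), (0.19999, "very_weak"),
        (0.2, "weak"), (0.39999, "weak"),
        (0.4, "moderate"), (0.43, "moderate"), (0.430, "moderate"),
        (0.59999, "moderate"),
        (0.6, "strong"), (0.61, "strong"), (0.79999, "strong"),
        (0.8, "very_strong"), (1.0, "very_strong"),
        (-0.43, "moderate"), (-1.0, "very_strong"), (0.0, "very_weak"),
    ])
    def test_five_level_cutpoints(self, rho, label):
        assert classify_strength(rho) == label


# ---------------------------------------------------------------------------
# Welch
# ---------------------------------------------------------------------------

def welch_by_hand(a, b):
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, p


class TestWelch:
    def test_identical_samples(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_matches_closed_form(self):
        res = welch_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        t, df, p = welch_by_hand([1, 2, 3], [4, 5, 6])
        assert res.t_statistic == pytest.approx(t, abs=1e-10)   # -3.6742...
        assert res.df == pytest.approx(df, abs=1e-10)           # 4.0
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_random_inputs_match_closed_form(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, rng.integers(2, 9))
            b = rng.normal(0.5, 2, rng.integers(2, 9))
            res = welch_t(a, b)
            t, df, p = welch_by_hand(a, b)
            assert res.t_statistic == pytest.approx(t, abs=1e-10)
            assert res.df == pytest.approx(df, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_antisymmetry(self):
        ab = welch_t([1.0, 2.0, 4.0], [3.0, 5.0, 9.0])
        ba = welch_t([3.0, 5.0, 9.0], [1.0, 2.0, 4.0])
        assert ab.t_statistic == pytest.approx(-ba.t_statistic)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_double_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            welch_t([2.0, 2.0, 2.0], [2.0, 2.0])


class TestSiteVsAll:
    def make_cohort(self, rng):
        frames = []
        for site in ("prostate", "pelvis", "head"):
            frames.append(sessions(rng.normal(95, 1, 10), site=site,
                                   plan_id=f"{site}-1"))
        return pd.concat(frames, ignore_index=True)

    def test_shifted_site_is_significant(self, rng):
        df = self.make_cohort(rng)
        df.loc[df["site"] == "head", "eta_percent"] -= 10.0
        res = site_vs_all_tests(df, ["eta_percent"])
        head_p = res.loc[res["site"] == "head", "p_value"].iloc[0]
        assert head_p < 1e-6

    def test_one_row_per_site_metric(self, rng):
        res = site_vs_all_tests(self.make_cohort(rng), ["eta_percent"])
        assert len(res) == 3
        assert sorted(res["site"]) == ["head", "pelvis", "prostate"]

    def test_matches_direct_welch_call(self, rng):
        df = self.make_cohort(rng)
        res = site_vs_all_tests(df, ["eta_percent"])
        direct = welch_t(df.loc[df["site"] == "pelvis", "eta_percent"],
                         df["eta_percent"])
        row = res.loc[res["site"] == "pelvis"].iloc[0]
        assert row["t_statistic"] == pytest.approx(direct.t_statistic)
        assert row["p_value"] == pytest.approx(direct.p_value)

    def test_missing_metric_column_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            site_vs_all_tests(self.make_cohort(rng), ["gamma_delta4_missing"])


# ---------------------------------------------------------------------------
# fraction trend
# ---------------------------------------------------------------------------

class TestFractionTrend:
    def test_flat_series_not_flagged(self):
        df = sessions([95.0] * 8, detector_signal=1.0)
        assert fraction_trend(df) == []

    def test_eta_drop_alone_not_flagged(self):
        values = [95.0] * 8
        values[3] = 80.0
        df = sessions(values, detector_signal=1.0)
        assert fraction_trend(df) == []

    def test_joint_drop_flagged(self):
        eta = [95.0, 95.1, 80.0, 94.9, 81.0, 95.2, 95.0, 94.8]
        sig = [1.0, 1.001, 0.9, 0.999, 0.9, 1.002, 0.998, 1.0]
        df = sessions(eta)
        df["detector_signal"] = sig
        assert fraction_trend(df) == [3, 5]

    def test_requires_signal_column(self):
        df = sessions([95.0] * 5).drop(columns=[], errors="ignore")
        df = df.drop(columns=[c for c in df.columns if c == "detector_signal"],
                     errors="ignore")
        with pytest.raises(ConfigurationError):
            fraction_trend(df)

    def test_too_few_fractions(self):
        df = sessions([95.0, 94.0], detector_signal=1.0)
        with pytest.raises(InsufficientDataError):
            fraction_trend(df)
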