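"""Hygiene operators against hand-computed and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from gmlcs import SimConfig, generate_study
from gmlcs.data_hygiene import (
    adjust_for_icv,
    adjust_table_for_icv,
    apply_compliance_exclusion,
    classify_compliance,
    flag_multivariate_outliers,
    flag_univariate_outliers,
    mahalanobis_threshold,
    stack_standardize,
)
from gmlcs.studytable import StudyTable
from gmlcs.synthetic_data import TrainingLog


def _mini_table(values):
    """StudyTable from {(pid, var, occ): value}."""
    rows = [(p, "ACG", v, t, x) for (p, v, t), x in values.items()]
    meas = pd.DataFrame(rows, columns=["participant_id", "group", "variable", "occasion", "value"])
    pids = sorted({p for p, _, _ in values})
    part = pd.DataFrame(
        {
            "participant_id": pids,
            "group": "ACG",
            "age": 70.0,
            "sex": "F",
            "education_years": 13.0,
            "icv": 1500.0,
        }
    )
    return StudyTable(meas, part)


# ----------------------------------------------------------------------
# ICV adjustment
# ----------------------------------------------------------------------
class TestAdjustForICV:
    def test_hand_least_squares_oracle(self):
        """volumes (2,4,6) on ICV (10,20,30): slope 0.2, all adjusted to 4."""
        vals = pd.Series([2.0, 4.0, 6.0], index=["a", "b", "c"])
        icv = pd.Series([10.0, 20.0, 30.0], index=["a", "b", "c"])
        adj = adjust_for_icv(vals, icv)
        assert np.allclose(adj.to_numpy(), [4.0, 4.0, 4.0])

    def test_zero_slope_leaves_values_unchanged(self, rng):
        # duplicated ICV block against a two-level value pattern gives an
        # exactly zero sample covariance, hence b = 0 and adjusted == raw
        half = rng.normal(1500, 100, 20)
        icv = pd.Series(np.concatenate([half, half]))
        vals = pd.Series([1.0] * 20 + [2.0] * 20)
        adj = adjust_for_icv(vals, icv)
        assert np.allclose(adj, vals)

    def test_participant_at_mean_icv_unchanged(self):
        vals = pd.Series([2.0, 4.0, 6.0])
        icv = pd.Series([10.0, 20.0, 30.0])
        adj = adjust_for_icv(vals, icv)
        assert adj[1] == pytest.approx(vals[1])  # ICV = mean ICV

    def test_adjusted_values_uncorrelated_with_icv(self, rng):
        icv = pd.Series(rng.normal(1500, 120, 200))
        vals = pd.Series(0.5 + 0.002 * icv + rng.normal(0, 0.05, 200))
        adj = adjust_for_icv(vals, icv)
        slope = np.polyfit(icv, adj, 1)[0]
        assert abs(slope) < 1e-10 * abs(np.polyfit(icv, vals, 1)[0] or 1.0)

    def test_missing_values_stay_missing(self, rng):
        vals = pd.Series([1.0, np.nan, 3.0, 4.0])
        icv = pd.Series([10.0, 20.0, 30.0, 40.0])
        adj = adjust_for_icv(vals, icv)
        assert np.isnan(adj[1]) and adj.notna().sum() == 3

    def test_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            adjust_for_icv(pd.Series([1.0, 2.0, 3.0]), pd.Series([5.0, 5.0, 5.0]))
        with pytest.raises(ValueError, match=">=3"):
            adjust_for_icv(pd.Series([1.0, 2.0]), pd.Series([5.0, 6.0]))

    def test_table_level_adjustment_targets_vbm_only(self, rng):
        cfg = SimConfig(rois=("ACC_R",), dropout_prob=0.0, mcar_rate=0.0,
                        icv_slope_vbm=0.005, seed=3)
        table = generate_study(cfg)
        adjusted = adjust_table_for_icv(table)
        icv = table.participants.set_index("participant_id")["icv"]
        for var, should_change in (("ACC_R.VBM", True), ("ACC_R.MT", False)):
            m0 = table.measurements.query("variable == @var and occasion == 1")
            m1 = adjusted.measurements.query("variable == @var and occasion == 1")
            changed = not np.allclose(m0["value"].to_numpy(), m1["value"].to_numpy())
            assert changed == should_change
            if should_change:
                joined = m1.set_index("participant_id")["value"]
                slope = np.polyfit(icv[joined.index], joined, 1)[0]
                assert abs(slope) < 1e-12


# ----------------------------------------------------------------------
# longitudinal standardization
# ----------------------------------------------------------------------
class TestStackStandardize:
    def test_hand_computation_oracle(self):
        """T1 (1,2,3), T2 (2,3,4): pooled mean 2.5, pooled sample SD
        sqrt(1.1); transformed T1 mean is -0.5/sqrt(1.1)."""
        vals = {("a", "x", 1): 1.0, ("b", "x", 1): 2.0, ("c", "x", 1): 3.0,
                ("a", "x", 2): 2.0, ("b", "x", 2): 3.0, ("c", "x", 2): 4.0}
        out = stack_standardize(_mini_table(vals), "x")
        m = out.measurements
        pooled = m["value"]
        assert pooled.mean() == pytest.approx(0.0, abs=1e-12)
        assert pooled.std(ddof=1) == pytest.approx(1.0)
        t1_mean = m[m["occasion"] == 1]["value"].mean()
        assert t1_mean == pytest.approx(-0.5 / np.sqrt(1.1))

    def test_idempotent_on_standardized_input(self):
        vals = {("a", "x", 1): 1.0, ("b", "x", 1): 2.0, ("c", "x", 1): 3.0,
                ("a", "x", 2): 2.0, ("b", "x", 2): 3.0, ("c", "x", 2): 4.0}
        once = stack_standardize(_mini_table(vals), "x")
        twice = stack_standardize(once, "x")
        assert np.allclose(once.measurements["value"], twice.measurements["value"])

    def test_occasion_mean_difference_preserved_up_to_scale(self):
        vals = {("a", "x", 1): 1.0, ("b", "x", 1): 3.0,
                ("a", "x", 2): 4.0, ("b", "x", 2): 6.0}
        out = stack_standardize(_mini_table(vals), "x")
        m = out.measurements
        d = m[m["occasion"] == 2]["value"].mean() - m[m["occasion"] == 1]["value"].mean()
        s = pd.Series([1.0, 3.0, 4.0, 6.0]).std(ddof=1)
        assert d == pytest.approx(3.0 / s)
        assert d != 0

    def test_zero_sd_error_names_variable(self):
        vals = {("a", "flat", 1): 2.0, ("b", "flat", 1): 2.0}
        with pytest.raises(ValueError, match="flat"):
            stack_standardize(_mini_table(vals), "flat")


# ----------------------------------------------------------------------
# univariate screen
# ----------------------------------------------------------------------
class TestUnivariateScreen:
    def test_zero_spread_groups_flag_nothing(self):
        vals = {(p, "x", 1): 5.0 for p in "abcdef"}
        cleaned, report = flag_univariate_outliers(_mini_table(vals))
        assert report.univariate_flags == []
        assert len(cleaned.measurements) == 6

    def test_injected_outlier_caught_exactly(self, rng):
        """100 standard-normal draws plus one cell at mean + 6 SD: exactly
        that cell is flagged (verified against a direct z-score scan)."""
        draws = rng.standard_normal(100)
        vals = {(f"p{i}", "x", 1): float(v) for i, v in enumerate(draws)}
        vals[("bad", "x", 1)] = float(draws.mean() + 6 * draws.std(ddof=1))
        table = _mini_table(vals)
        cleaned, report = flag_univariate_outliers(table, threshold_sd=4.0)
        # brute-force scan oracle
        s = pd.Series(vals)
        z = (s - s.mean()) / s.std(ddof=1)
        expected = {k[0] for k, zz in z.items() if abs(zz) > 4}
        flagged = {p for p, _, _, _ in report.univariate_flags}
        assert flagged == expected == {"bad"}
        assert len(cleaned.measurements) == 100
        assert all(abs(z) > 4 for *_, z in report.univariate_flags)


# ----------------------------------------------------------------------
# multivariate screen
# ----------------------------------------------------------------------
class TestMultivariateScreen:
    def test_threshold_is_chi_square_quantile(self):
        """criterion 0.001 with 3 occasions: threshold ~16.266, checked by
        numerically inverting the chi-square CDF."""
        thr = mahalanobis_threshold(3, 0.001)
        inverted = optimize.brentq(lambda q: stats.chi2.cdf(q, 3) - 0.999, 1, 50)
        assert thr == pytest.approx(inverted, abs=1e-8)
        assert thr == pytest.approx(16.266, abs=5e-4)

    def test_identity_covariance_reduces_to_euclidean_distance(self, rng):
        """With identity sample covariance, distance^2 is the squared
        Euclidean distance from the complete-case mean."""
        n = 200
        x = rng.standard_normal((n, 3))
        # whiten so the sample covariance is exactly the identity
        x = (x - x.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(x.T, ddof=1))).T
        assert np.allclose(np.cov(x.T, ddof=1), np.eye(3), atol=1e-10)
        vals = {(f"p{i}", "x", t + 1): float(x[i, t]) for i in range(n) for t in range(3)}
        table = _mini_table(vals)
        _, report = flag_multivariate_outliers(table, "x", criterion=0.5)
        d2 = {p: d for p, _, d, _ in report.multivariate_flags}
        euclid = ((x - x.mean(0)) ** 2).sum(axis=1)
        for i in range(n):
            if euclid[i] > mahalanobis_threshold(3, 0.5):
                assert d2[f"p{i}"] == pytest.approx(euclid[i], rel=1e-9)

    def test_flagged_case_loses_all_occasions(self, rng):
        n = 60
        x = rng.multivariate_normal([0, 0, 0], np.eye(3), n)
        x[0] = [8.0, -8.0, 8.0]
        vals = {(f"p{i:02d}", "x", t + 1): float(x[i, t]) for i in range(n) for t in range(3)}
        cleaned, report = flag_multivariate_outliers(_mini_table(vals), "x")
        assert [p for p, *_ in report.multivariate_flags] == ["p00"]
        left = cleaned.measurements["participant_id"].unique()
        assert "p00" not in left
        assert report.cells_discarded == 3

    def test_singular_covariance_errors(self):
        vals = {}
        for i in range(10):
            vals[(f"p{i}", "x", 1)] = float(i)
            vals[(f"p{i}", "x", 2)] = float(i)  # perfectly collinear
            vals[(f"p{i}", "x", 3)] = float(-i)
        with pytest.raises(ValueError, match="singular"):
            flag_multivariate_outliers(_mini_table(vals), "x")


# ----------------------------------------------------------------------
# compliance
# ----------------------------------------------------------------------
class TestCompliance:
    def test_26_weeks_at_90_minutes_is_compliant(self):
        log = TrainingLog("p", list(range(1, 27)), [90.0] * 26, [70.0] * 26)
        rec = classify_compliance(log, require_nondecreasing_watts=True)
        assert rec.compliant and rec.total_minutes == 2340 >= 1890

    def test_empty_log_fails_on_minutes(self):
        rec = classify_compliance(TrainingLog("p", [], [], []))
        assert not rec.compliant and rec.reasons == ["minutes"]

    def test_three_week_pause_flagged_despite_enough_minutes(self):
        """Active weeks 1-10 and 14-26, zero weeks 11-13, total 2000+ min:
        non-compliant solely for the pause (run-length oracle)."""
        weeks = list(range(1, 27))
        minutes = [90.0 if (w <= 10 or w >= 14) else 0.0 for w in weeks]
        scale = 2000.0 / sum(minutes)
        minutes = [m * scale for m in minutes]
        log = TrainingLog("p", weeks, minutes, [70.0] * 26)
        rec = classify_compliance(log)
        # oracle: longest zero run computed independently
        runs, run = [], 0
        for m in minutes:
            run = run + 1 if m == 0 else 0
            runs.append(run)
        assert rec.longest_pause_weeks == max(runs) == 3
        assert rec.reasons == ["pause"]

    def test_gap_in_week_numbering_counts_as_pause(self):
        log = TrainingLog("p", [1, 2, 7, 8], [500.0] * 4, [70.0] * 4)
        rec = classify_compliance(log)
        assert rec.longest_pause_weeks == 4
        assert "pause" in rec.reasons

    def test_decreasing_watts_only_when_required(self):
        log = TrainingLog("p", list(range(1, 27)), [100.0] * 26,
                          [100.0 - 2 * w for w in range(26)])
        assert classify_compliance(log).compliant
        rec = classify_compliance(log, require_nondecreasing_watts=True)
        assert rec.reasons == ["watts"] and rec.wattage_trend < 0

    def test_exclusion_modes(self, study_table):
        pid = study_table.participants["participant_id"].iloc[0]
        rec = classify_compliance(TrainingLog(pid, [], [], []))
        kept = apply_compliance_exclusion(study_table, {pid: rec}, "t1-retained")
        mine = kept.measurements[kept.measurements["participant_id"] == pid]
        assert set(mine["occasion"]) <= {1} and len(mine) > 0
        gone = apply_compliance_exclusion(study_table, {pid: rec}, "fully-excluded")
        assert pid not in set(gone.measurements["participant_id"])
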