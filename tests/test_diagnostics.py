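"""Thresholds, 2×2 tables, interval estimates, logistic fits, RMS-CV."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sfscore as sf
from sfscore.diagnostics import (
    SeparationError,
    StatisticsError,
    evaluate,
    positive_mask,
    reclassified_table,
)


def _df(porosity, density, sfs, fracture, bmd=None):
    n = len(porosity)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "cortical_porosity": porosity,
            "trabecular_density": density,
            "fn_bmd_tscore": bmd if bmd is not None else [0.0] * n,
            "sfs": sfs,
            "fracture": fracture,
        }
    )


class TestPercentileThreshold:
    def test_constant_sample(self):
        for p in (5, 50, 90):
            assert sf.percentile_threshold([7.0] * 10, p) == 7.0

    def test_integer_grid(self):
        assert sf.percentile_threshold(range(101), 90) == pytest.approx(90.0)

    def test_against_sort_and_interpolate_oracle(self, rng):
        vals = rng.standard_normal(137)
        for p in (5.0, 36.7, 50.0, 90.0):
            srt = np.sort(vals)
            h = p / 100.0 * (len(vals) - 1)
            lo, frac = int(math.floor(h)), h - math.floor(h)
            oracle = srt[lo] + frac * (srt[min(lo + 1, len(vals) - 1)] - srt[lo])
            assert sf.percentile_threshold(vals, p) == pytest.approx(oracle, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(StatisticsError):
            sf.percentile_threshold([1.0], 90)
        with pytest.raises(StatisticsError):
            sf.percentile_threshold([1.0, 2.0], 100.0)


class TestBuildTable:
    thresholds = sf.Thresholds(porosity_cut=45.0, density_cut=70.0, bmd_cut=-2.5, sfs_cut=70.0)

    def test_perfect_separation_counts(self):
        df = _df([0, 0, 0, 0], [100] * 4, [80, 75, 60, 50], [True, True, False, False])
        t = sf.build_table(df, "sfs", self.thresholds)
        assert (t.tp, t.fn, t.fp, t.tn) == (2, 0, 0, 2)

    def test_threshold_at_minus_infinity_makes_all_positive(self):
        df = _df([10, 20, 30], [100] * 3, [0] * 3, [True, False, False])
        thr = sf.Thresholds(porosity_cut=-math.inf, density_cut=0, bmd_cut=0, sfs_cut=0)
        with pytest.raises(StatisticsError):
            sf.build_table(df, "porosity", thr)  # cut must be finite
        thr = sf.Thresholds(porosity_cut=-1e300, density_cut=0, bmd_cut=0, sfs_cut=0)
        t = sf.build_table(df, "porosity", thr)
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 2, 0, 0)

    def test_boundary_equality_counts_positive(self):
        df = _df([45.0, 44.9], [70.0, 70.1], [70.0, 69.9], [True, False])
        for trait in ("porosity", "density", "sfs"):
            assert positive_mask(df, trait, self.thresholds).tolist() == [True, False]

    def test_random_cohort_matches_brute_force_recount(self, rng):
        n = 500
        df = _df(
            rng.uniform(20, 60, n),
            rng.uniform(20, 150, n),
            rng.uniform(-20, 120, n),
            rng.random(n) < 0.4,
            bmd=rng.normal(-1, 1, n),
        )
        for trait, col, at_risk in [
            ("porosity", "cortical_porosity", lambda v, c: v >= c),
            ("density", "trabecular_density", lambda v, c: v <= c),
            ("bmd", "fn_bmd_tscore", lambda v, c: v <= c),
            ("sfs", "sfs", lambda v, c: v >= c),
        ]:
            t = sf.build_table(df, trait, self.thresholds)
            cut = self.thresholds.cut(trait)
            tp = sum(
                at_risk(v, cut) and f for v, f in zip(df[col], df["fracture"])
            )
            fp = sum(
                at_risk(v, cut) and not f for v, f in zip(df[col], df["fracture"])
            )
            assert (t.tp, t.fp) == (tp, fp)
            assert t.tp + t.fn + t.fp + t.tn == n

    def test_missing_trait_value_names_subject(self):
        df = _df([45.0, 44.0], [70.0, 70.0], [70.0, np.nan], [True, False])
        with pytest.raises(sf.ValidationError, match="s1"):
            sf.build_table(df, "sfs", self.thresholds)


class TestReconstructTable:
    @pytest.mark.parametrize(
        "sens, spec, n1, n0, expected",
        [
            (0.1010, 0.9810, 99, 105, (10, 89, 2, 103)),
            (0.3540, 0.8950, 99, 105, (35, 64, 11, 94)),
            (0.0404, 0.9900, 99, 105, (4, 95, 1, 104)),
            (0.2930, 0.9050, 99, 105, (29, 70, 10, 95)),
            (1.0, 1.0, 7, 9, (7, 0, 0, 9)),
        ],
    )
    def test_reconstruction(self, sens, spec, n1, n0, expected):
        t = sf.reconstruct_table(sens, spec, n1, n0)
        assert (t.tp, t.fn, t.fp, t.tn) == expected

    def test_half_rounds_away_from_zero(self):
        t = sf.reconstruct_table(0.5, 0.5, 5, 5)  # 2.5 -> 3
        assert (t.tp, t.tn) == (3, 3)


class TestOddsRatio:
    def test_published_bmd_row(self):
        res = sf.odds_ratio(sf.ContingencyTable(10, 89, 2, 103))
        assert round(res.estimate, 2) == 5.79
        assert res.ci_low == pytest.approx(1.24, abs=0.015)
        assert res.ci_high == pytest.approx(27.10, abs=0.015)
        assert res.p_value == pytest.approx(0.026, abs=0.0005)

    def test_published_sfs_row(self):
        res = sf.odds_ratio(sf.ContingencyTable(35, 64, 11, 94))
        assert round(res.estimate, 2) == 4.67
        assert res.ci_low == pytest.approx(2.21, abs=0.015)
        assert res.ci_high == pytest.approx(9.88, abs=0.015)
        assert res.p_value < 0.0001

    def test_uniform_table_symmetric_about_one(self):
        res = sf.odds_ratio(sf.ContingencyTable(1, 1, 1, 1))
        assert res.estimate == 1.0
        assert res.ci_low * res.ci_high == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_cell_requires_correction(self):
        table = sf.ContingencyTable(0, 10, 5, 5)
        with pytest.raises(StatisticsError, match="zero cell"):
            sf.odds_ratio(table)
        res = sf.odds_ratio(table, zero_cell_correction=True)
        assert res.estimate == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_label_swap_inverts_or(self, rng):
        for _ in range(20):
            cells = rng.integers(1, 50, size=4)
            t = sf.ContingencyTable(*map(int, cells))
            res, swapped = sf.odds_ratio(t), sf.odds_ratio(t.swapped())
            assert swapped.estimate == pytest.approx(1.0 / res.estimate)
            assert swapped.ci_low == pytest.approx(1.0 / res.ci_high)
            assert swapped.ci_high == pytest.approx(1.0 / res.ci_low)


class TestSensSpec:
    def test_published_bmd_row_with_exact_cis(self):
        sens, spec = sf.sens_spec(sf.ContingencyTable(10, 89, 2, 103))
        assert sens.estimate * 100 == pytest.approx(10.10, abs=0.005)
        assert (round(sens.ci_low * 100, 2), round(sens.ci_high * 100, 2)) == (4.95, 17.79)
        assert spec.estimate * 100 == pytest.approx(98.10, abs=0.005)
        assert (round(spec.ci_low * 100, 1), round(spec.ci_high * 100, 1)) == (93.3, 99.8)

    def test_against_statsmodels_exact_oracle(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(10, 99), (103, 105), (0, 12), (12, 12), (35, 99)]:
            ci = sf.clopper_pearson(k, n)
            lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
            assert ci.ci_low == pytest.approx(0.0 if k == 0 else lo, abs=1e-10)
            assert ci.ci_high == pytest.approx(1.0 if k == n else hi, abs=1e-10)
            assert ci.ci_low <= ci.estimate <= ci.ci_high

    def test_degenerate_bounds_exact(self):
        assert sf.clopper_pearson(0, 50).ci_low == 0.0
        assert sf.clopper_pearson(50, 50).ci_high == 1.0

    def test_exact_coverage_at_reference_size(self):
        """CP interval covers p = 0.10 with >= 95% probability at n = 99."""
        n, p = 99, 0.10
        coverage = sum(
            stats.binom.pmf(k, n, p)
            for k in range(n + 1)
            if sf.clopper_pearson(k, n).ci_low <= p <= sf.clopper_pearson(k, n).ci_high
        )
        assert coverage >= 0.95


class TestLogisticFit:
    def test_single_binary_predictor_matches_cross_product_or(self, rng):
        for _ in range(10):
            tp, fn, fp, tn = map(int, rng.integers(3, 40, size=4))
            x = np.array([1.0] * (tp + fp) + [0.0] * (fn + tn))
            y = np.array([True] * tp + [False] * fp + [True] * fn + [False] * tn)
            fit = sf.logistic_fit(y, x, names=["exposed"])
            expected = sf.odds_ratio(sf.ContingencyTable(tp, fn, fp, tn))
            assert fit.converged
            assert fit.odds_ratios["exposed"].estimate == pytest.approx(
                expected.estimate, abs=1e-6 * expected.estimate
            )
            assert fit.odds_ratios["exposed"].ci_low == pytest.approx(
                expected.ci_low, rel=1e-4
            )

    def test_identical_split_gives_or_one(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        y = np.array([True, False, True, False])
        fit = sf.logistic_fit(y, x)
        assert fit.odds_ratios["x0"].estimate == pytest.approx(1.0, abs=1e-8)

    def test_perfect_separation_raises(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = x > 2.5
        with pytest.raises(SeparationError):
            sf.logistic_fit(y, x)

    def test_constant_column_rejected(self):
        with pytest.raises(StatisticsError, match="constant"):
            sf.logistic_fit([True, False], np.array([1.0, 1.0]))

    def test_all_one_outcome_rejected(self):
        with pytest.raises(StatisticsError, match="event"):
            sf.logistic_fit([True, True], np.array([0.0, 1.0]))

    def test_against_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        n = 400
        x1 = rng.standard_normal(n)
        x2 = rng.random(n) < 0.5
        eta = -0.5 + 0.8 * x1 + 0.6 * x2
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        X = pd.DataFrame({"x1": x1, "x2": x2.astype(float)})
        fit = sf.logistic_fit(y, X)
        ref = sm.Logit(y, sm.add_constant(X.to_numpy())).fit(disp=0)
        assert fit.coef == pytest.approx(ref.params, abs=1e-6)
        assert fit.se == pytest.approx(ref.bse, rel=1e-4)


class TestRmsCv:
    def test_identical_replicates_give_zero(self):
        assert sf.rms_cv([[5.0, 5.0, 5.0], [2.0, 2.0]]) == 0.0

    def test_three_and_four_percent_pair(self):
        # subject cvs exactly 3% and 4%: sqrt((9+16)/2) = 3.5355%
        reps = [[97.0, 100.0, 103.0], [96.0, 100.0, 104.0]]
        assert sf.rms_cv(reps) == pytest.approx(math.sqrt(12.5), abs=1e-10)

    def test_single_subject_ten_percent(self):
        assert sf.rms_cv([[90.0, 100.0, 110.0]]) == pytest.approx(10.0, abs=1e-10)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(StatisticsError, match="mean"):
            sf.rms_cv([[1.0, -1.0]])


class TestEvaluateReport:
    def test_reclassification_and_joint_adjustment(self, rng):
        n = 300
        df = _df(
            rng.uniform(20, 60, n),
            rng.uniform(20, 150, n),
            rng.uniform(-20, 120, n),
            rng.random(n) < 0.4,
            bmd=rng.normal(-1, 1, n),
        )
        thr = sf.Thresholds(porosity_cut=45, density_cut=70, bmd_cut=-2.5, sfs_cut=70)
        report = evaluate(df, thr, zero_cell_correction=True)
        assert set(report["traits"]) == {"porosity", "density", "bmd", "sfs"}
        sfs_entry = report["traits"]["sfs"]
        assert sfs_entry["threshold"] == 70
        counts = sfs_entry["table"]
        assert sum(counts.values()) == n
        adj = sfs_entry["after_bmd"]
        assert adj["method"] == "reclassification"
        # reclassified positives = sfs-positive and bmd-negative
        t = reclassified_table(df, "sfs", "bmd", thr)
        assert adj["table"] == {"tp": t.tp, "fn": t.fn, "fp": t.fp, "tn": t.tn}
        manual = (
            positive_mask(df, "sfs", thr)
            & ~positive_mask(df, "bmd", thr)
            & df["fracture"].to_numpy()
        ).sum()
        assert t.tp == manual
        assert "joint_logistic" in adj
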