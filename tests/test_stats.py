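"""Statistical battery: t/proportion tests, Bonferroni, odds ratios, regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from faocohort.stats import (ComparisonResult, ContingencyTable2x2,
                             RegressionSpec, bonferroni_adjust, crude_or,
                             fit_linear, fit_logistic_or, pearson_corr,
                             proportion_test, two_sample_t)


def welch_oracle(x, y):
    """Hand-written Welch t statistic, df and two-sided p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df, 2 * sps.t.sf(abs(t), df)


def exact_prop_oracle(k1, n1, k2, n2, alpha=0.05):
    """Exact enumeration: reject iff the null probability (at the pooled
    MLE) of a |z| at least as large as observed is < alpha."""
    def zstat(a, b):
        p = (a + b) / (n1 + n2)
        if p in (0.0, 1.0):
            return 0.0
        se = np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
        return (a / n1 - b / n2) / se
    z_obs = abs(zstat(k1, k2))
    p0 = (k1 + k2) / (n1 + n2)
    pk1 = sps.binom.pmf(np.arange(n1 + 1), n1, p0)
    pk2 = sps.binom.pmf(np.arange(n2 + 1), n2, p0)
    pval = sum(pk1[a] * pk2[b]
               for a in range(n1 + 1) for b in range(n2 + 1)
               if abs(zstat(a, b)) >= z_obs - 1e-12)
    return pval < alpha


class TestTwoSampleT:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = two_sample_t(x, list(x))
        assert res.estimate == pytest.approx(0.0)
        assert res.p_raw == pytest.approx(1.0)

    def test_matches_hand_welch_computation(self):
        x = [4.2, 5.1, 3.8, 4.9, 5.5]
        y = [3.1, 2.8, 3.9, 3.3, 2.5]
        res = two_sample_t(x, y)
        t, df, p = welch_oracle(x, y)
        assert res.p_raw == pytest.approx(p, abs=1e-6)
        assert res.estimate == pytest.approx(np.mean(x) - np.mean(y), abs=1e-12)
        tcrit = sps.t.ppf(0.975, df)
        se = (np.mean(x) - np.mean(y)) / t
        assert res.ci_low == pytest.approx(res.estimate - tcrit * se, abs=1e-9)

    def test_p_decreases_with_shift(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        ps = [two_sample_t(x, y + d).p_raw for d in (0.5, 1.0, 2.0)]
        assert ps[0] > ps[1] > ps[2]

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


class TestProportionTest:
    def test_equal_rates_give_p_one(self):
        res = proportion_test(10, 100, 20, 200)
        assert res.estimate == pytest.approx(0.0)
        assert res.p_raw == pytest.approx(1.0)

    def test_printed_count_contrast(self):
        """Primary-cesarean contrast between two large groups."""
        res = proportion_test(535, 2082, 883, 4226)
        assert res.estimate == pytest.approx(0.0481, abs=5e-4)
        assert res.p_raw < 0.001
        assert res.estimate > 0

    def test_agrees_with_exact_enumeration_on_small_n(self, rng):
        agree = 0
        cases = 0
        for _ in range(200):
            n1, n2 = rng.integers(8, 31, size=2)
            k1 = rng.integers(0, n1 + 1)
            k2 = rng.integers(0, n2 + 1)
            if k1 + k2 in (0, n1 + n2):
                continue
            cases += 1
            z_reject = proportion_test(int(k1), int(n1), int(k2), int(n2)).p_raw < 0.05
            agree += z_reject == exact_prop_oracle(int(k1), int(n1), int(k2), int(n2))
        assert agree / cases >= 0.95

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            proportion_test(0, 0, 1, 10)

    def test_type_one_error_calibration(self, rng):
        """Null rejection rate at alpha=0.05: p1=p2=0.2, n=200/arm, 2000 reps."""
        reps = 2000
        k1 = rng.binomial(200, 0.2, reps)
        k2 = rng.binomial(200, 0.2, reps)
        rej = sum(proportion_test(int(a), 200, int(b), 200).p_raw < 0.05
                  for a, b in zip(k1, k2))
        assert abs(rej / reps - 0.05) <= 0.012


class TestBonferroni:
    def test_examples_and_cap(self):
        assert bonferroni_adjust([0.01, 0.4], 6) == [pytest.approx(0.06), 1.0]

    def test_family_of_one_is_identity(self):
        ps = [0.01, 0.2, 0.9]
        assert bonferroni_adjust(ps, 1) == ps

    def test_monotone_never_decreases(self, rng):
        ps = sorted(rng.uniform(0, 1, 50))
        adj = bonferroni_adjust(ps, 6)
        assert all(a >= p for a, p in zip(adj, ps))
        assert adj == sorted(adj)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.2], 2)


class TestCrudeOr:
    def test_symmetric_table_is_unity(self):
        res = crude_or(ContingencyTable2x2(10, 10, 10, 10))
        assert res.estimate == pytest.approx(1.0)

    def test_cross_product_from_printed_counts(self):
        # 26/215 events vs 169/4226: (26*4057)/(189*169)
        res = crude_or(ContingencyTable2x2(26, 189, 169, 4057))
        assert res.estimate == pytest.approx(26 * 4057 / (189 * 169), rel=1e-12)
        assert res.estimate == pytest.approx(3.30, abs=5e-3)

    def test_zero_cell_haldane_corrected(self):
        res = crude_or(ContingencyTable2x2(0, 20, 5, 15))
        assert np.isfinite(res.estimate)
        assert "haldane_correction" in res.flags

    def test_woolf_interval_contains_estimate(self):
        res = crude_or(ContingencyTable2x2(30, 70, 20, 80))
        assert res.ci_low < res.estimate < res.ci_high

    def test_coverage_of_planted_or(self, rng):
        """Woolf 95% CI coverage near nominal over 1000 cohorts of n=2000."""
        true_or = 2.0
        p0 = 0.15
        odds1 = true_or * p0 / (1 - p0)
        p1 = odds1 / (1 + odds1)
        hits = 0
        for _ in range(1000):
            n_exp = 600
            a = rng.binomial(n_exp, p1)
            c = rng.binomial(2000 - n_exp, p0)
            res = crude_or(ContingencyTable2x2(a, n_exp - a, c, 1400 - c))
            hits += res.ci_low <= true_or <= res.ci_high
        assert 0.93 <= hits / 1000 <= 0.97


class TestLogistic:
    def test_single_binary_exposure_equals_crude_or(self, rng):
        n = 400
        exposed = rng.uniform(size=n) < 0.4
        p = np.where(exposed, 0.35, 0.15)
        event = rng.uniform(size=n) < p
        df = pd.DataFrame({"y": event.astype(float),
                           "x": exposed.astype(float)})
        res = fit_logistic_or(df, RegressionSpec("y", "x"))[0]
        oracle = crude_or(ContingencyTable2x2.from_arrays(exposed, event))
        assert res.estimate == pytest.approx(oracle.estimate, rel=1e-6)

    def test_recovers_planted_group_ors(self, rng):
        """Planted per-group ORs are covered by fitted 95% CIs in a clear
        majority of independent replicates (single draws sit in the 5% tail
        too often for a hard assertion)."""
        n = 20000
        planted = np.array([1.0, 3.0, 1.5, 2.8])
        hits = np.zeros(3, int)
        reps = 5
        for _ in range(reps):
            group = rng.choice(4, n, p=[0.6, 0.1, 0.2, 0.1])
            lp = np.log(0.05 / 0.95) + np.log(planted)[group]
            y = rng.uniform(size=n) < 1 / (1 + np.exp(-lp))
            df = pd.DataFrame({"y": y.astype(float),
                               "g": pd.Series(group).map({0: "G1", 1: "G2",
                                                          2: "G3", 3: "G4"})})
            results = fit_logistic_or(df, RegressionSpec("y", "g",
                                                         reference="G1"))
            for j, (res, target) in enumerate(zip(results, planted[1:])):
                hits[j] += res.ci_low <= target <= res.ci_high
        assert np.all(hits >= 3), hits

    def test_recovers_categorized_age_band_or_with_confounder(self, rng):
        """Planted OR 1.55 for an age band, confounded covariate adjusted away;
        coverage in a clear majority of independent replicates."""
        n = 20000
        hits = 0
        reps = 5
        for _ in range(reps):
            band = rng.choice(3, n, p=[0.5, 0.35, 0.15])   # <30, 30-35, 35-40
            bmi = rng.normal(21, 2.5, n) + 0.8 * band
            lp = (np.log(0.08 / 0.92) + np.log([1.0, 1.2, 1.55])[band]
                  + 0.10 * (bmi - 21))
            y = rng.uniform(size=n) < 1 / (1 + np.exp(-lp))
            df = pd.DataFrame({"y": y.astype(float), "bmi": bmi,
                               "band": pd.Series(band).map(
                                   {0: "lt30", 1: "b30_35", 2: "b35_40"})})
            results = fit_logistic_or(
                df, RegressionSpec("y", "band", ("bmi",), reference="lt30"))
            res = {r.label: r for r in results}["b35_40"]
            hits += res.ci_low <= 1.55 <= res.ci_high
        assert hits >= 3, hits

    def test_separation_flagged_not_estimated(self):
        df = pd.DataFrame({"y": [0.0] * 30 + [1.0] * 30,
                           "x": [0.0] * 30 + [1.0] * 30})
        res = fit_logistic_or(df, RegressionSpec("y", "x"))[0]
        assert res.estimate is None
        assert "separation" in res.flags

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"y": [0.0, 1.0] * 5, "x": [0.0, 1.0] * 5})
        with pytest.raises(ValueError, match="too few"):
            fit_logistic_or(df, RegressionSpec("y", "x"))


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        assert pearson_corr(x, x).estimate == pytest.approx(1.0)

    def test_perfect_negative_affine(self):
        x = np.arange(10.0)
        assert pearson_corr(x, -2 * x + 3).estimate == pytest.approx(-1.0)

    def test_null_simulation_small_r(self, rng):
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        assert abs(pearson_corr(x, y).estimate) < 0.08

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLinear:
    def test_exact_recovery_without_noise(self, rng):
        n = 200
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = 2.0 + 1.5 * x1 - 0.7 * x2
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        res = {r.label: r for r in
               fit_linear(df, RegressionSpec("y", "x1", ("x2",)))}
        assert res["x1"].estimate == pytest.approx(1.5, abs=1e-8)
        assert res["x2"].estimate == pytest.approx(-0.7, abs=1e-8)

    def test_planted_coefficients_small_bias(self, rng):
        n = 20000
        age = rng.normal(33, 3.8, n)
        bmi = rng.normal(21, 2.6, n)
        y = 0.95 + 0.0010 * age + 0.0015 * bmi + rng.normal(0, 0.036, n)
        df = pd.DataFrame({"y": y, "age": age, "bmi": bmi})
        res = {r.label: r for r in
               fit_linear(df, RegressionSpec("y", "age", ("bmi",)))}
        assert abs(res["age"].estimate - 0.0010) < 0.1 * 0.0010 + 2e-5
        assert abs(res["bmi"].estimate - 0.0015) < 0.1 * 0.0015 + 2e-5

    def test_irrelevant_covariate_keeps_recovery(self, rng):
        n = 5000
        x = rng.normal(size=n)
        junk = rng.normal(size=n)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.5, n)
        res = {r.label: r for r in
               fit_linear(pd.DataFrame({"y": y, "x": x, "junk": junk}),
                          RegressionSpec("y", "x", ("junk",)))}
        assert res["x"].ci_low <= 0.5 <= res["x"].ci_high

    def test_collinear_design_flagged(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"y": x + rng.normal(size=100), "x": x, "x2": 2 * x})
        res = fit_linear(df, RegressionSpec("y", "x", ("x2",)))
        assert all("rank_deficient" in r.flags for r in res)


class TestCoverageCalibration:
    """95% CI coverage of planted truth for the mean-difference and
    proportion-difference procedures."""

    def test_t_interval_coverage(self, rng):
        hits = 0
        for _ in range(1000):
            x = rng.normal(0.3, 1.0, 2000)
            y = rng.normal(0.0, 1.2, 2000)
            res = two_sample_t(x, y)
            hits += res.ci_low <= 0.3 <= res.ci_high
        assert 0.93 <= hits / 1000 <= 0.97

    def test_proportion_interval_coverage(self, rng):
        hits = 0
        for _ in range(1000):
            k1 = rng.binomial(1000, 0.25)
            k2 = rng.binomial(1000, 0.20)
            res = proportion_test(int(k1), 1000, int(k2), 1000)
            hits += res.ci_low <= 0.05 <= res.ci_high
        assert 0.93 <= hits / 1000 <= 0.97
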