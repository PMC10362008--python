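"""Pearson correlations and overlapping dependent-correlation tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lgibp.correlations import (DEFAULT_FAMILY_SIZES, OutcomeTable,
                                UndefinedCorrelationError, bonferroni_adjust,
                                build_comparison_table,
                                dependent_overlapping_test, pearson_pairwise,
                                zou_confidence_interval)


class TestPearsonPairwise:
    def test_identity_gives_one(self):
        a = np.arange(10.0)
        r, n, p = pearson_pairwise(a, a)
        assert r == pytest.approx(1.0) and n == 10

    def test_constructed_orthogonality_gives_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        b = rng.normal(size=50)
        a = a - a.mean()
        b = b - b.mean()
        b = b - (a @ b) / (a @ a) * a  # exact residualization
        r, _, _ = pearson_pairwise(a, b)
        assert abs(r) < 1e-12

    def test_joint_missing_handling(self):
        a = np.array([1, 2, 3, 4, np.nan])
        b = np.array([2, 4, 6, np.nan, 10.0])
        r, n, _ = pearson_pairwise(a, b)
        assert n == 3 and r == pytest.approx(1.0)

    def test_too_few_pairs(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_pairwise(np.array([1.0, 2, np.nan]),
                             np.array([1.0, np.nan, 2]))

    def test_sampling_mean_near_population_rho(self):
        rng = np.random.default_rng(1)
        rho, n, reps = 0.3, 200, 3000
        L = np.linalg.cholesky([[1, rho], [rho, 1.0]])
        xs = rng.standard_normal((reps, n, 2)) @ L.T
        rs = []
        for x in xs:
            r, _, _ = pearson_pairwise(x[:, 0], x[:, 1])
            rs.append(r)
        bias = -(1 - rho ** 2) * rho / (2 * n)
        se = np.std(rs) / math.sqrt(reps)
        assert abs(np.mean(rs) - (rho + bias)) < 3 * se


class TestDependentTest:
    def test_null_on_the_nose(self):
        stat, p = dependent_overlapping_test(0.4, 0.4, 0.2, 50)
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_frozen_worked_example_steiger(self):
        # independently derived from the published Fisher-z statistic
        stat, p = dependent_overlapping_test(0.5, 0.3, 0.2, 100)
        assert stat == pytest.approx(1.780324, abs=1e-5)
        assert p == pytest.approx(0.075023, abs=1e-5)

    def test_frozen_worked_example_williams(self):
        stat, p = dependent_overlapping_test(0.5, 0.3, 0.2, 100,
                                             method="williams")
        assert stat == pytest.approx(1.797982, abs=1e-5)
        assert p == pytest.approx(0.075291, abs=1e-5)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 9999),
           method=st.sampled_from(["steiger", "williams"]))
    def test_antisymmetry(self, seed, method):
        rng = np.random.default_rng(seed)
        # draw a valid correlation triple from a random covariance
        x = rng.normal(size=(12, 3))
        c = np.corrcoef(x.T)
        r_jy, r_ky, r_jk = c[0, 2], c[1, 2], c[0, 1]
        s1, p1 = dependent_overlapping_test(r_jy, r_ky, r_jk, 60,
                                            method=method)
        s2, p2 = dependent_overlapping_test(r_ky, r_jy, r_jk, 60,
                                            method=method)
        assert s1 == pytest.approx(-s2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            dependent_overlapping_test(1.0, 0.3, 0.2, 30)

    def test_inconsistent_triple_rejected(self):
        # strong same-sign correlations with y but strongly negative
        # feature overlap cannot form a valid correlation matrix
        with pytest.raises(ValueError, match="positive semidefinite"):
            dependent_overlapping_test(0.9, 0.85, -0.9, 30)

    def test_zou_interval_covers_difference(self):
        lo, hi = zou_confidence_interval(0.5, 0.3, 0.2, 100)
        assert lo < 0.2 < hi

    def test_zou_p_consistent_with_interval(self):
        diff, p = dependent_overlapping_test(0.6, 0.1, 0.2, 150,
                                             method="zou")
        lo, hi = zou_confidence_interval(0.6, 0.1, 0.2, 150, alpha=p)
        assert min(abs(lo), abs(hi)) < 1e-6

    def test_calibration_under_null(self):
        """Trivariate-normal null: rejection near nominal level."""
        rng = np.random.default_rng(5)
        rho_y, rho_jk, n, reps = 0.2, 0.3, 200, 1500
        C = np.array([[1, rho_jk, rho_y], [rho_jk, 1, rho_y],
                      [rho_y, rho_y, 1.0]])
        L = np.linalg.cholesky(C)
        X = rng.standard_normal((reps, n, 3)) @ L.T
        rej = 0
        for x in X:
            c = np.corrcoef(x.T)
            _, p = dependent_overlapping_test(c[0, 2], c[1, 2], c[0, 1], n)
            rej += p < 0.05
        assert 0.03 < rej / reps < 0.07


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expect", [
        (0.01, 4, 0.04), (0.6, 2, 1.0), (0.2, 1, 0.2), (0.5, 3, 1.0)])
    def test_values(self, p, m, expect):
        assert bonferroni_adjust(p, m) == pytest.approx(expect)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(p1=st.floats(0, 1), p2=st.floats(0, 1), m=st.integers(1, 10))
    def test_monotone_and_capped(self, p1, p2, m):
        lo, hi = sorted((p1, p2))
        assert bonferroni_adjust(lo, m) <= bonferroni_adjust(hi, m) <= 1.0
        assert bonferroni_adjust(lo, m) <= bonferroni_adjust(lo, m + 1)


def _outcomes(values: dict, families: dict):
    df = pd.DataFrame(values)
    ids = tuple(f"p{i}" for i in range(len(df)))
    df.index = pd.Index(ids, name="participant_id")
    return OutcomeTable(ids, df, families)


class TestComparisonTable:
    def test_identical_features_give_zero_statistics(self):
        rng = np.random.default_rng(0)
        v = rng.random(60)
        vals = np.column_stack([v, v])
        y = rng.normal(size=60)
        out = _outcomes({"y": y}, {"y": "impulsive_behavior"})
        _, comp = build_comparison_table(vals, out)
        assert np.allclose(comp["statistic"], 0.0)

    def test_all_missing_outcome_excluded_with_warning(self):
        rng = np.random.default_rng(1)
        vals = rng.random((30, 2))
        out = _outcomes({"y": np.full(30, np.nan),
                         "ok": rng.normal(size=30)},
                        {"y": "substance_use", "ok": "substance_use"})
        with pytest.warns(UserWarning, match="no observed values"):
            corr, comp = build_comparison_table(vals, out)
        assert list(corr["outcome"]) == ["ok"]

    def test_family_sizes_drive_adjustment(self):
        rng = np.random.default_rng(2)
        n = 200
        z = rng.standard_normal((n, 2))
        y = 0.4 * z[:, 0] + rng.standard_normal(n)
        out = _outcomes({"imp": y, "sub": y.copy()},
                        {"imp": "impulsive_behavior",
                         "sub": "substance_use"})
        _, comp = build_comparison_table(z, out)
        imp = comp[comp.outcome == "imp"].iloc[0]
        sub = comp[comp.outcome == "sub"].iloc[0]
        assert imp["bonferroni_m"] == 2 and sub["bonferroni_m"] == 4
        assert sub["p_adjusted"] == pytest.approx(
            min(1.0, 2 * imp["p_adjusted"]), abs=1e-12)

    def test_invariant_to_participant_order(self):
        rng = np.random.default_rng(3)
        n = 80
        vals = rng.random((n, 2))
        y = rng.normal(size=n)
        out = _outcomes({"y": y}, {"y": "impulsive_behavior"})
        _, comp1 = build_comparison_table(vals, out)
        perm = rng.permutation(n)
        ids = tuple(f"p{i}" for i in perm)
        df = pd.DataFrame({"y": y[perm]},
                          index=pd.Index(ids, name="participant_id"))
        out2 = OutcomeTable(ids, df, {"y": "impulsive_behavior"})
        _, comp2 = build_comparison_table(vals[perm], out2)
        assert comp1["statistic"].iloc[0] == pytest.approx(
            comp2["statistic"].iloc[0])

    def test_planted_contrast_power(self):
        """Feature with rho = 0.3 vs feature with rho = 0 at n = 600:
        the comparison is flagged at Bonferroni-adjusted alpha in most
        replicates."""
        rng = np.random.default_rng(4)
        hits = 0
        reps = 60
        for _ in range(reps):
            n = 600
            z1 = (rng.random(n) < 0.3).astype(float)
            z2 = (rng.random(n) < 0.3).astype(float)
            sd1 = math.sqrt(0.3 * 0.7)
            y = 0.3 / sd1 * z1 + rng.normal(0, math.sqrt(1 - 0.09), n)
            out = _outcomes({"y": y}, {"y": "impulsive_behavior"})
            _, comp = build_comparison_table(np.column_stack([z1, z2]), out)
            hits += bool(comp["significant_adjusted"].iloc[0])
        assert hits / reps >= 0.8
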