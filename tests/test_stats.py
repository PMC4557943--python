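"""Statistical conventions: chi-square, Mann-Whitney, t, correlation, regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from scotowatch.stats import (
    ContingencyTable2x2,
    chi2_2x2,
    chi2_gof,
    mann_whitney_u,
    median_summary,
    ols_logrt,
    pearson_r,
    two_sample_t,
    untimely_summary,
)


class TestChi2_2x2:
    def test_untimely_occlusion_table(self):
        # 29/39 untimely occluded vs 79/223 timely occluded
        stat, p = chi2_2x2(ContingencyTable2x2(29, 10, 79, 144))
        assert stat == pytest.approx(20.8, abs=0.05)
        assert p < 0.001

    def test_cross_study_driver_table(self):
        # 3 of 11 vs 6 of 7 current drivers
        stat, _ = chi2_2x2([[3, 8], [6, 1]])
        assert stat == pytest.approx(5.84, abs=0.005)

    def test_equal_proportions_zero(self):
        stat, _ = chi2_2x2([[10, 10], [10, 10]])
        assert stat == 0.0

    def test_symmetry_invariants(self, rng):
        for _ in range(20):
            t = rng.integers(1, 50, size=(2, 2))
            base = chi2_2x2(t)[0]
            assert chi2_2x2(t.T)[0] == pytest.approx(base)
            assert chi2_2x2(t[::-1])[0] == pytest.approx(base)
            assert chi2_2x2(t[:, ::-1])[0] == pytest.approx(base)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            chi2_2x2([[0, 0], [5, 5]])


class TestChi2Gof:
    def test_exact_fit_zero(self):
        assert chi2_gof([10, 20, 30], [1, 2, 3])[0] == pytest.approx(0.0)

    def test_availability_counts(self):
        # expectation proportional to per-eccentricity appearance totals
        stat, p = chi2_gof([66, 67, 62, 65], [178, 179, 175, 173])
        assert stat == pytest.approx(0.139, abs=0.001)
        assert p > 0.98

    def test_two_cell_value(self):
        assert chi2_gof([10, 0], [1, 1])[0] == pytest.approx(10.0)

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            chi2_gof([5, 5], [1, 0])


class TestMannWhitney:
    def test_driver_status_u(self):
        # 6 of 7 CFL vs 7 of 7 NV current drivers
        cfl = [1, 1, 1, 1, 1, 1, 0]
        nv = [1] * 7
        assert mann_whitney_u(cfl, nv) == 21.0

    def test_full_separation(self):
        assert mann_whitney_u([1, 2, 3], [10, 11, 12]) == 0.0

    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=8),
        st.lists(st.integers(0, 5), min_size=1, max_size=8),
    )
    def test_matches_brute_force_pairs(self, x, y):
        u1 = sum(1.0 if xi > yi else 0.5 if xi == yi else 0.0 for xi in x for yi in y)
        u2 = len(x) * len(y) - u1
        assert mann_whitney_u(x, y) == pytest.approx(min(u1, u2))

    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=10),
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=10),
    )
    def test_u1_plus_u2_identity(self, x, y):
        u1 = sum(1.0 if xi > yi else 0.5 if xi == yi else 0.0 for xi in x for yi in y)
        u = mann_whitney_u(x, y)
        assert u <= len(x) * len(y) / 2 + 1e-9
        assert u == pytest.approx(min(u1, len(x) * len(y) - u1))


class TestTwoSampleT:
    def test_identical_groups_zero(self):
        t, df = two_sample_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and df == 4

    def test_pooled_hand_value(self):
        # sd 0.7071 in both groups, SE 0.7071 -> t = -10/0.7071
        t, df = two_sample_t([0, 1], [10, 11], "pooled")
        assert t == pytest.approx(-14.142, abs=0.001)
        assert df == 2

    def test_welch_reduces_to_pooled_under_equal_variance(self):
        t_p, df_p = two_sample_t([0, 1, 2], [10, 11, 12], "pooled")
        t_w, df_w = two_sample_t([0, 1, 2], [10, 11, 12], "welch")
        assert t_w == pytest.approx(t_p)
        assert df_w == pytest.approx(df_p)

    def test_welch_df_never_exceeds_pooled(self, rng):
        for _ in range(20):
            x = rng.normal(0, rng.uniform(0.5, 3), rng.integers(3, 12))
            y = rng.normal(1, rng.uniform(0.5, 3), rng.integers(3, 12))
            _, df_w = two_sample_t(x, y, "welch")
            assert df_w <= x.size + y.size - 2 + 1e-9

    def test_zero_variance_everywhere_errors(self):
        with pytest.raises(ValueError):
            two_sample_t([1, 1], [2, 2])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert pearson_r([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_affine_invariance(self, rng):
        x, y = rng.normal(size=(2, 50))
        base = pearson_r(x, y)
        assert pearson_r(3 * x + 2, y) == pytest.approx(base)
        assert abs(base) <= 1.0

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestOlsLogRt:
    def test_noiseless_linear_exact(self, rng):
        occ = rng.uniform(0, 2, 60)
        subj = np.repeat(["a", "b", "c"], 20)
        eff = {"a": 0.0, "b": 0.2, "c": -0.1}
        y = 0.5 + 0.3 * occ + np.array([eff[s] for s in subj])
        fit = ols_logrt(y, occ, subj)
        assert fit["occ_slope"] == pytest.approx(0.3, abs=1e-9)
        assert fit["adj_r2"] == pytest.approx(1.0)
        assert fit["subject_effects"]["b"] == pytest.approx(0.2, abs=1e-9)

    def test_adjusted_r2_below_r2_with_noise(self, rng):
        occ = rng.uniform(0, 2, 80)
        y = 0.5 + 0.3 * occ + rng.normal(0, 0.3, 80)
        fit = ols_logrt(y, occ, ["s"] * 80)
        assert fit["adj_r2"] <= fit["r2"]

    def test_degenerate_design_errors(self):
        with pytest.raises(ValueError, match="collinear|aliased"):
            ols_logrt([1.0, 1.1, 0.9, 1.2], np.ones(4), ["s"] * 4)


class TestUntimelySummary:
    def _table(self, n_unt_occ, n_unt_clear, n_tim_occ, n_tim_clear):
        rows = []
        for n, unt, occ in [
            (n_unt_occ, True, True),
            (n_unt_clear, True, False),
            (n_tim_occ, False, True),
            (n_tim_clear, False, False),
        ]:
            for _ in range(n):
                rows.append(
                    {
                        "detected": True,
                        "timely": not unt,
                        "gaze_usable": True,
                        "occlusion_time": 0.4 if occ else 0.0,
                        "ecc_class": "small",
                        "drive_type": "city",
                        "participant_id": "p",
                    }
                )
        return pd.DataFrame(rows)

    def test_study_contingency_reproduced(self):
        out = untimely_summary(self._table(29, 10, 79, 144))
        tab = out["occlusion_by_timeliness"]
        assert (tab.a, tab.b, tab.c, tab.d) == (29, 10, 79, 144)
        assert out["chi2"] == pytest.approx(20.8, abs=0.05)

    def test_all_timely_skips_chi2(self):
        out = untimely_summary(self._table(0, 0, 40, 40))
        assert out["overall"] == 0.0
        assert out["chi2"] is None


class TestMedianSummary:
    def _table(self, values, pid="p"):
        return pd.DataFrame(
            {
                "participant_id": pid,
                "detected": True,
                "reaction_time": values,
            }
        )

    def test_simple_median(self):
        out = median_summary(self._table([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert out[0].median == 3.0
        assert out[0].ci_low <= 3.0 <= out[0].ci_high

    def test_single_value_degenerate(self):
        out = median_summary(self._table([2.5]))
        assert out[0].median == out[0].ci_low == out[0].ci_high == 2.5

    def test_bootstrap_ci_coverage(self):
        # n = 200 lognormal draws; the nominal-95% percentile CI for the
        # median should cover the truth in at least 93% of replicates
        rng = np.random.default_rng(7)
        true_median = np.exp(0.8)
        n_rep = 1000
        hits = 0
        for rep in range(n_rep):
            vals = rng.lognormal(0.8, 0.5, 200)
            out = median_summary(self._table(vals), seed=rep)[0]
            hits += out.ci_low <= true_median <= out.ci_high
        assert hits >= 0.93 * n_rep
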