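"""Rank-sum tests, Holm correction, regression and the report tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsmm.stats import (
    build_tables,
    holm_bonferroni,
    linear_regression,
    mann_whitney,
)

from conftest import brute_force_mann_whitney_p


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.u_statistic == 0.0
        assert r.method == "exact"
        # 1/20 per tail over the C(6,3) = 20 assignments
        assert r.p_value == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_with_ties(self):
        r = mann_whitney([5, 5], [5, 5])
        assert r.p_value == 1.0
        assert r.method == "normal"

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n, m = rng.integers(2, 6, size=2)
            a = rng.normal(size=n)
            b = rng.normal(size=m) + rng.normal()
            ours = mann_whitney(a, b)
            assert ours.method == "exact"
            assert ours.p_value == pytest.approx(
                brute_force_mann_whitney_p(a, b), abs=1e-12
            )

    def test_large_samples_use_normal_approximation(self, rng):
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        r = mann_whitney(a, b)
        assert r.method == "normal"
        assert 0.0 < r.p_value <= 1.0

    def test_normal_approximation_close_to_exact_at_cutoff(self, rng):
        # same data through both paths (forced by a tie that does not
        # change the ranks' midpoint structure materially)
        a = rng.normal(size=10)
        b = rng.normal(size=10) + 0.8
        exact = mann_whitney(a, b)
        with_tie = np.concatenate([a, [a[0]]])
        approx = mann_whitney(with_tie, b)
        assert approx.method == "normal"
        assert abs(exact.p_value - approx.p_value) < 0.08

    def test_empty_or_singleton_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            mann_whitney([1.0], [2.0, 3.0])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        a = r.normal(size=r.integers(2, 9))
        b = r.normal(size=r.integers(2, 9))
        p0 = mann_whitney(a, b).p_value
        f = lambda x: np.exp(3.0 * x) - 5.0  # strictly increasing
        assert mann_whitney(f(a), f(b)).p_value == pytest.approx(p0, abs=1e-12)


class TestHolm:
    def test_step_down_by_hand(self):
        adj = holm_bonferroni([0.02, 0.04, 0.01, 0.30])
        np.testing.assert_allclose(adj, [0.06, 0.08, 0.04, 0.30])

    def test_single_p_identity(self):
        assert holm_bonferroni([0.03])[0] == 0.03

    def test_uncapped_exceeds_one_for_tied_large_ps(self):
        # two equal p-values both receive the m=2 multiplier via the
        # monotonicity step
        adj = holm_bonferroni([0.794, 0.794])
        np.testing.assert_allclose(adj, [1.588, 1.588])

    def test_cap_flag(self):
        adj = holm_bonferroni([0.794, 0.794], cap=True)
        np.testing.assert_allclose(adj, [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            holm_bonferroni([0.5, 1.5])

    def test_matches_statsmodels_when_capped(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 11))
            ours = holm_bonferroni(p, cap=True)
            _, sm, _, _ = multipletests(p, method="holm")
            np.testing.assert_allclose(ours, sm, atol=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_bracketed_by_raw_and_bonferroni(self, seed):
        r = np.random.default_rng(seed)
        p = r.uniform(0, 1, r.integers(1, 11))
        adj = holm_bonferroni(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= len(p) * p + 1e-15)


class TestLinearRegression:
    def test_exact_line(self):
        fit = linear_regression([0, 1, 2], [1, 3, 5])
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equation_oracle(self, rng):
        from scipy.stats import t as tdist

        for _ in range(50):
            n = int(rng.integers(4, 30))
            x = rng.normal(size=n)
            y = 1.4 * x + rng.normal(size=n)
            fit = linear_regression(x, y)
            X = np.column_stack([x, np.ones(n)])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta
            sse = resid @ resid
            sst = np.sum((y - y.mean()) ** 2)
            se = np.sqrt(sse / (n - 2) / np.sum((x - x.mean()) ** 2))
            p = 2 * tdist.sf(abs(beta[0] / se), n - 2)
            assert fit.slope == pytest.approx(beta[0], abs=1e-10)
            assert fit.intercept == pytest.approx(beta[1], abs=1e-10)
            assert fit.r_squared == pytest.approx(1 - sse / sst, abs=1e-10)
            assert fit.p_value == pytest.approx(p, abs=1e-10)

    def test_null_r2_mean_is_one_over_n_minus_1(self, rng):
        n = 14
        r2 = [
            linear_regression(rng.normal(size=n), rng.normal(size=n)).r_squared
            for _ in range(1000)
        ]
        assert np.mean(r2) == pytest.approx(1.0 / (n - 1), abs=0.012)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            linear_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_affine_rescaling_of_x(self, rng):
        x = rng.normal(size=12)
        y = 2.0 * x + rng.normal(size=12)
        f1 = linear_regression(x, y)
        f2 = linear_regression(10.0 * x + 3.0, y)
        assert f2.slope == pytest.approx(f1.slope / 10.0, rel=1e-10)
        assert f2.r_squared == pytest.approx(f1.r_squared, rel=1e-10)
        assert f2.p_value == pytest.approx(f1.p_value, rel=1e-9)


class TestBuildTables:
    def test_zero_noise_cohort_has_perfect_regressions(self):
        from tsmm.synthetic.cohort import generate_cohort

        from test_synthetic import zero_noise_config

        cfg = zero_noise_config(
            n_young=6, n_older=6, height_sd_m=0.08, mass_sd_kg=10.0,
            volume_slope={"young": 7.0, "older": 5.95},
        )
        df, _ = generate_cohort(cfg)
        tables = build_tables(df)
        t3 = tables["table3"]
        hm_rows = t3[t3.response == "height_mass_kgm"]
        assert (hm_rows.r_squared > 1.0 - 1e-9).all()

    def test_identical_groups_give_p_one(self):
        import pandas as pd

        base = {
            "vol_ps_cm3": [400.0, 410, 395, 405],
            "vol_as_cm3": [80.0, 82, 78, 81],
            "vol_mg_cm3": [300.0, 305, 295, 302],
            "vol_lg_cm3": [170.0, 172, 168, 171],
            "height_m": [1.78, 1.8, 1.75, 1.77],
            "mass_kg": [75.0, 80, 70, 72],
        }
        df = pd.concat(
            [
                pd.DataFrame({**base, "group": "young"}),
                pd.DataFrame({**base, "group": "older"}),
            ]
        )
        tables = build_tables(df)
        assert (tables["table2"].p_raw == 1.0).all()

    def test_family_structure_and_adjustment(self):
        from tsmm.synthetic.cohort import CohortConfig, generate_cohort

        df, _ = generate_cohort(CohortConfig(seed=5))
        tables = build_tables(df)
        t2 = tables["table2"]
        muscle_rows = t2[~t2.measure.str.contains("total")]
        assert muscle_rows.p_adjusted.notna().all()
        assert (muscle_rows.p_adjusted >= muscle_rows.p_raw - 1e-12).all()
        total_rows = t2[t2.measure.str.contains("total")]
        assert total_rows.p_adjusted.isna().all()
        assert set(t2.family) == {
            "muscle_volume_cm3",
            "normalized_volume_cm3_per_kgm",
            "relative_volume_pct",
            "tendon_csa_per_volume_cm",
        }

    def test_missing_measure_skipped_with_warning(self, caplog):
        from tsmm.synthetic.cohort import CohortConfig, generate_cohort

        df, _ = generate_cohort(CohortConfig(seed=5))
        df = df.drop(columns=["moment_arm_mm"])
        with caplog.at_level("WARNING", logger="tsmm.stats"):
            tables = build_tables(df)
        assert "moment_arm_mm" in caplog.text
        assert "moment_arm_mm" not in set(tables["table1"].measure)
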