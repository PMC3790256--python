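"""Voxelwise GLM, DOF accounting, nested F-tests and BIC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pnmkit import bic, bic_compare, effective_dof, fit_nuisance_glm, nested_f_test
from pnmkit.glm import fdr_threshold
from pnmkit.design import DesignMatrix, NoiseModelSpec
from pnmkit.errors import DimensionError, DOFError, NestingError, RankError


def design_from_matrix(mat, labels=None):
    labels = labels or [f"reg_{j}" for j in range(mat.shape[1])]
    return DesignMatrix(
        matrices=[mat - mat.mean(axis=0)], labels=labels,
        spec=NoiseModelSpec.default(),
    )


class TestFit:
    def test_exact_linear_combination_has_zero_rss(self, rng):
        n = 60
        X = rng.standard_normal((n, 3))
        dm = design_from_matrix(X)
        coefs = np.array([2.0, -1.0, 0.5])
        series = 10.0 + (dm.matrices[0] @ coefs)
        data = np.tile(series, (2, 2, 1, 1))
        res = fit_nuisance_glm(data, dm)
        assert np.allclose(res.rss, 0.0, atol=1e-16)
        assert np.allclose(res.residuals, 0.0, atol=1e-9)

    def test_orthogonal_column_gets_zero_coefficient(self, rng):
        n = 100
        t = np.arange(n)
        x1 = np.sin(2 * np.pi * 5 * t / n)
        x2 = np.cos(2 * np.pi * 7 * t / n)  # orthogonal to x1 and to the data
        data = (5.0 + 2.0 * x1).reshape(1, 1, 1, n)
        res_both = fit_nuisance_glm(data, design_from_matrix(np.column_stack([x1, x2])))
        res_one = fit_nuisance_glm(data, design_from_matrix(x1[:, None]))
        assert abs(res_both.coefficients[0, 0, 0, 2]) < 1e-10
        assert res_both.rss[0, 0, 0] == pytest.approx(res_one.rss[0, 0, 0], abs=1e-10)

    def test_residuals_orthogonal_to_design_and_zero_mean(self, rng):
        n = 80
        X = rng.standard_normal((n, 4))
        dm = design_from_matrix(X)
        data = rng.standard_normal((3, 3, 1, n)) + 50.0
        res = fit_nuisance_glm(data, dm)
        r = res.residuals[1, 2, 0]
        assert abs(r.mean()) < 1e-10  # intercept present
        assert np.allclose(dm.matrices[0].T @ r, 0.0, atol=1e-8)

    def test_adding_regressors_never_increases_rss(self, rng):
        n = 60
        X = rng.standard_normal((n, 6))
        data = rng.standard_normal((4, 4, 1, n))
        rss_small = fit_nuisance_glm(data, design_from_matrix(X[:, :3])).rss
        rss_big = fit_nuisance_glm(data, design_from_matrix(X)).rss
        assert np.all(rss_big <= rss_small + 1e-10)

    def test_mask_excludes_voxels_as_nan(self, rng):
        n = 40
        data = rng.standard_normal((2, 2, 1, n))
        mask = np.zeros((2, 2, 1), dtype=bool)
        mask[0, 0, 0] = True
        res = fit_nuisance_glm(data, design_from_matrix(rng.standard_normal((n, 2))),
                               mask=mask)
        assert np.isfinite(res.rss[0, 0, 0])
        assert np.isnan(res.rss[1, 1, 0])

    def test_rank_deficient_design_names_columns(self, rng):
        n = 50
        x = rng.standard_normal(n)
        X = np.column_stack([x, 2 * x])
        data = rng.standard_normal((1, 1, 1, n))
        with pytest.raises(RankError, match="reg_"):
            fit_nuisance_glm(data, design_from_matrix(X))

    def test_too_many_regressors_is_dof_error(self, rng):
        n = 10
        X = rng.standard_normal((n, 9))
        data = rng.standard_normal((1, 1, 1, n))
        with pytest.raises(DOFError):
            fit_nuisance_glm(data, design_from_matrix(X))


class TestDOF:
    def test_printed_example(self):
        assert effective_dof(100, 35) == 64

    def test_no_regressors(self):
        assert effective_dof(10, 0) == 9

    def test_boundary_raises(self):
        with pytest.raises(DOFError):
            effective_dof(10, 9)


class TestFTest:
    def test_equal_rss_gives_f_zero_p_one(self):
        rss = np.array([5.0, 7.0])
        cmp_ = nested_f_test(rss, rss, 1, 3, 100)
        assert np.allclose(cmp_.f_stat, 0.0)
        assert np.allclose(cmp_.p_value, 1.0)

    def test_closed_form_example(self):
        cmp_ = nested_f_test(np.array([120.0]), np.array([100.0]), 1, 3, 100)
        assert cmp_.f_stat[0] == pytest.approx((20.0 / 2) / (100.0 / 96))  # 9.6
        assert (cmp_.f_dof_num, cmp_.f_dof_den) == (2, 96)

    def test_nesting_violations_raise(self):
        with pytest.raises(NestingError):
            nested_f_test(np.array([1.0]), np.array([2.0]), 1, 3, 100)
        with pytest.raises(NestingError):
            nested_f_test(np.array([2.0]), np.array([1.0]), 3, 3, 100)

    def test_type_i_error_calibrated_on_white_noise(self, rng):
        # 4000 null voxels, intercept-only vs +4 irrelevant regressors
        n, q, nvox = 100, 4, 4000
        X = rng.standard_normal((n, q))
        Y = rng.standard_normal((n, nvox))
        ones = np.ones((n, 1))
        b0 = np.linalg.lstsq(ones, Y, rcond=None)[0]
        rss0 = np.sum((Y - ones @ b0) ** 2, axis=0)
        Xf = np.column_stack([ones, X])
        b1 = np.linalg.lstsq(Xf, Y, rcond=None)[0]
        rss1 = np.sum((Y - Xf @ b1) ** 2, axis=0)
        cmp_ = nested_f_test(rss0, rss1, 1, 1 + q, n)
        rate = np.mean(cmp_.p_value < 0.05)
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / nvox) + 0.002


class TestBIC:
    def test_rss_equal_n_leaves_penalty_only(self):
        assert bic(np.array([100.0]), 3, 100)[0] == pytest.approx(3 * np.log(100))

    def test_printed_example(self):
        assert bic(np.array([100.0]), 2, 100)[0] == pytest.approx(9.2103, abs=1e-4)

    def test_monotone_in_rss(self):
        rss = np.linspace(10, 1, 20)
        vals = bic(rss, 5, 50)
        assert np.all(np.diff(vals) < 0)

    def test_zero_rss_is_minus_inf(self):
        assert bic(np.array([0.0]), 2, 50)[0] == -np.inf

    def test_equal_k_reduces_to_smaller_rss(self):
        assert bic_compare(90.0, 5, 100.0, 5, 50) == 1
        assert bic_compare(100.0, 5, 90.0, 5, 50) == 2

    def test_printed_inequality_example(self):
        # ln(100/90) ≈ 0.105 < 8·ln(100)/100 ≈ 0.368 → model 1 superior
        assert bic_compare(100.0, 2, 90.0, 10, 100) == 1

    @settings(deadline=None, max_examples=200)
    @given(
        rss1=st.floats(0.1, 1e4),
        rss2=st.floats(0.1, 1e4),
        k1=st.integers(1, 40),
        k2=st.integers(1, 40),
        n=st.integers(50, 500),
    )
    def test_inequality_agrees_with_pairwise_bic_ordering(self, rss1, rss2, k1, k2, n):
        pref = bic_compare(rss1, k1, rss2, k2, n)
        b1 = bic(np.array([rss1]), k1, n)[0]
        b2 = bic(np.array([rss2]), k2, n)[0]
        if b1 != b2:
            assert pref == (1 if b1 < b2 else 2)

    def test_tie_prefers_smaller_model(self):
        # identical rss and k: either way, the larger model must not win
        assert bic_compare(50.0, 3, 50.0, 3, 100) == 1


class TestFDR:
    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 500) ** 2
        ours = fdr_threshold(p, alpha=0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        assert np.array_equal(ours, ref)

    def test_nan_voxels_never_rejected(self):
        p = np.array([1e-6, np.nan, 0.9])
        rej = fdr_threshold(p, alpha=0.05)
        assert rej[0] and not rej[1] and not rej[2]


class TestShapes:
    def test_mismatched_rss_shapes_raise(self):
        with pytest.raises(DimensionError):
            nested_f_test(np.zeros(3), np.zeros(4), 1, 2, 50)
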