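import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methclock as mc
from methclock.errors import ValidationError
from methclock._cox import cox_fit, cox_loglik, schoenfeld_residuals

from conftest import CELLS, toy_matrix


def ols_oracle(X, y):
    """Textbook normal-equations OLS: coefficients, SEs, two-sided t p-values."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * XtX_inv))
    p = 2 * stats.t.sf(np.abs(beta / se), df)
    return beta, se, p, resid @ resid, df


def mvalues_standardized(meth):
    m = meth.to_mvalues().values
    return (m - m.mean(0)) / m.std(0, ddof=1)


class TestLinearAgeEwas:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        n = 200
        age = rng.uniform(20, 90, n)
        beta_vals = np.clip(mc.m_to_beta(0.5 + 0.01 * age + rng.normal(0, 0.2, n)), 1e-3, 1 - 1e-3)
        meth = toy_matrix(beta_vals[:, None])
        pheno = pd.DataFrame({"age": age}, index=meth.sample_ids)
        table = mc.linear_age_ewas(meth, pheno, covariates=None)
        z = mvalues_standardized(meth)[:, 0]
        X = np.column_stack([np.ones(n), z])
        b, se, p, _, _ = ols_oracle(X, age - age.mean())
        assert table["beta_linear"].iloc[0] == pytest.approx(b[1], abs=1e-8)
        assert table["se_linear"].iloc[0] == pytest.approx(se[1], abs=1e-8)
        assert table["p_linear"].iloc[0] == pytest.approx(p[1], rel=1e-8)

    def test_fwl_equals_full_design_with_covariates(self, small_cohort):
        meth, pheno, _ = small_cohort
        spec = mc.CovariateSpec(cell_proportions=CELLS)
        table = mc.linear_age_ewas(meth, pheno, spec)
        # full-design oracle on a handful of CpGs
        design = spec.build_design(pheno)
        C = np.column_stack([np.ones(len(pheno)), design.to_numpy(float)])
        Z = mvalues_standardized(meth)
        y = pheno["age"].to_numpy() - pheno["age"].mean()
        for j in [0, 17, 250]:
            X = np.column_stack([C, Z[:, j]])
            b, se, p, _, _ = ols_oracle(X, y)
            assert table["beta_linear"].iloc[j] == pytest.approx(b[-1], abs=1e-8)
            assert table["se_linear"].iloc[j] == pytest.approx(se[-1], abs=1e-8)

    def test_collinear_cpg_flagged_missing(self):
        rng = np.random.default_rng(1)
        n = 60
        age = rng.uniform(20, 80, n)
        pack = rng.gamma(2, 5, n)
        # CpG 1 is an affine image of the pack_years covariate on the M
        # scale (kept within the beta clipping bounds)
        m = np.column_stack([rng.normal(size=n), pack / 10.0])
        meth = mc.MethylationMatrix(
            pd.DataFrame(mc.m_to_beta(m), index=[f"s{i}" for i in range(n)],
                         columns=["cgA", "cgB"]))
        pheno = pd.DataFrame({
            "age": age, "sex": rng.integers(0, 2, n), "pack_years": pack,
            "smoking_status": "never", "batch": "b0"}, index=meth.sample_ids)
        spec = mc.CovariateSpec(batch=False, smoking_status=False)
        table = mc.linear_age_ewas(meth, pheno, spec)
        assert np.isfinite(table.loc["cgA", "p_linear"])
        assert np.isnan(table.loc["cgB", "p_linear"])

    def test_constant_cpg_flagged(self):
        meth = toy_matrix(np.full((30, 1), 0.5))
        pheno = pd.DataFrame({"age": np.linspace(20, 80, 30)}, index=meth.sample_ids)
        table = mc.linear_age_ewas(meth, pheno, covariates=None)
        assert np.isnan(table["beta_linear"].iloc[0])

    def test_too_few_samples_is_global_error(self):
        meth = toy_matrix([[0.2], [0.4]])
        pheno = pd.DataFrame({"age": [30.0, 40.0]}, index=meth.sample_ids)
        with pytest.raises(ValidationError):
            mc.linear_age_ewas(meth, pheno, covariates=None)

    def test_permutation_invariance(self, small_cohort):
        meth, pheno, _ = small_cohort
        table = mc.linear_age_ewas(meth, pheno, covariates=None)
        perm = list(meth.data.columns[::-1])
        meth_perm = mc.MethylationMatrix(meth.data[perm])
        table_perm = mc.linear_age_ewas(meth_perm, pheno, covariates=None)
        pd.testing.assert_frame_equal(table.sort_index(), table_perm.sort_index())

    def test_t_squared_equals_nested_f_against_covariate_only(self, small_cohort):
        meth, pheno, _ = small_cohort
        spec = mc.CovariateSpec(cell_proportions=CELLS)
        table = mc.linear_age_ewas(meth, pheno, spec)
        design = spec.build_design(pheno)
        C = np.column_stack([np.ones(len(pheno)), design.to_numpy(float)])
        y = pheno["age"].to_numpy() - pheno["age"].mean()
        resid0 = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
        rss0 = resid0 @ resid0
        t2 = (table["beta_linear"] / table["se_linear"]) ** 2
        f = (rss0 - table["rss"]) / (table["rss"] / table["df"])
        np.testing.assert_allclose(t2, f, atol=1e-8, rtol=1e-8)


class TestQuadraticAgeEwas:
    def test_curved_monotone_signal_detected(self):
        # a monotone-but-curved trajectory M = b*u + c*u^2 (vertex outside
        # the age range): the squared M-value term must reach genome-wide
        # significance at n=2000.  A perfectly age-symmetric CpG carries no
        # information about age under this outcome orientation (age is not
        # a function of a symmetric M-value), so curvature is what the
        # quadratic term detects.
        rng = np.random.default_rng(2)
        n = 2000
        age = rng.uniform(20, 90, n)
        u = age - age.mean()
        m = 0.02 * u + 4e-4 * u ** 2 + rng.normal(0, 0.1, n)
        meth = mc.MethylationMatrix(
            pd.DataFrame({"cgQ": np.clip(mc.m_to_beta(m), 1e-3, 1 - 1e-3)},
                         index=[f"s{i}" for i in range(n)]))
        pheno = pd.DataFrame({"age": age}, index=meth.sample_ids)
        table = mc.quadratic_age_ewas(meth, pheno, covariates=None)
        assert table["p_quadratic"].iloc[0] < 3.6e-8

    def test_pure_linear_cpgs_give_uniform_quadratic_p(self):
        cfg = mc.SimulationConfig(
            n_samples=500, n_cpgs=1000, seed=31, fraction_linear_cpgs=1.0,
            fraction_quadratic_cpgs=0.0, fraction_logage_cpgs=0.0,
            fraction_smoking_cpgs=0.0, effect_size_sd=0.02, noise_sd=0.1,
            n_batches=1, batch_sd=0.0)
        meth, pheno, _ = mc.simulate_cohort(cfg)
        table = mc.quadratic_age_ewas(meth, pheno, covariates=None)
        rate = (table["p_quadratic"] < 0.05).mean()
        assert 0.02 <= rate <= 0.09

    def test_constant_cpg_flagged(self):
        meth = toy_matrix(np.full((30, 1), 0.4))
        pheno = pd.DataFrame({"age": np.linspace(20, 80, 30)}, index=meth.sample_ids)
        table = mc.quadratic_age_ewas(meth, pheno, covariates=None)
        assert np.isnan(table["p_quadratic"].iloc[0])

    def test_matches_full_design_oracle(self, small_cohort):
        meth, pheno, _ = small_cohort
        table = mc.quadratic_age_ewas(meth, pheno, covariates=None)
        m = meth.to_mvalues().values
        z1 = (m - m.mean(0)) / m.std(0, ddof=1)
        m2 = m ** 2
        z2 = (m2 - m2.mean(0)) / m2.std(0, ddof=1)
        y = pheno["age"].to_numpy() - pheno["age"].mean()
        for j in [3, 99]:
            X = np.column_stack([np.ones(len(y)), z1[:, j], z2[:, j]])
            b, se, p, rss, df = ols_oracle(X, y)
            assert table["beta_quadratic"].iloc[j] == pytest.approx(b[2], abs=1e-8)
            assert table["se_quadratic"].iloc[j] == pytest.approx(se[2], abs=1e-8)
            assert table["rss"].iloc[j] == pytest.approx(rss, rel=1e-10)


class TestNestedFTest:
    def _tables(self, y, z, n):
        meth = mc.MethylationMatrix(
            pd.DataFrame({"cg": mc.m_to_beta(z)}, index=[f"s{i}" for i in range(n)]))
        pheno = pd.DataFrame({"age": y}, index=meth.sample_ids)
        lin = mc.linear_age_ewas(meth, pheno, covariates=None)
        quad = mc.quadratic_age_ewas(meth, pheno, covariates=None)
        return lin, quad

    def test_hand_computed_rss_formula(self):
        rng = np.random.default_rng(5)
        n = 20
        z = rng.normal(size=n)
        y = 30 + 3 * z + 0.5 * z ** 2 + rng.normal(size=n)
        lin, quad = self._tables(y, z, n)
        out = mc.nested_f_test(lin, quad)
        f_hand = (lin["rss"].iloc[0] - quad["rss"].iloc[0]) / (
            quad["rss"].iloc[0] / quad["df"].iloc[0])
        assert out["f_stat"].iloc[0] == pytest.approx(f_hand, abs=1e-10)
        assert out["p_f"].iloc[0] == pytest.approx(
            stats.f.sf(f_hand, 1, quad["df"].iloc[0]), rel=1e-10)

    def test_zero_quadratic_contribution_gives_f_zero(self):
        # outcome built so the squared term adds exactly nothing: noise is
        # projected off both the linear and squared standardized columns
        rng = np.random.default_rng(6)
        n = 50
        z = rng.normal(size=n)
        m2 = z ** 2
        z1 = (z - z.mean()) / z.std(ddof=1)
        z2 = (m2 - m2.mean()) / m2.std(ddof=1)
        e = rng.normal(size=n)
        A = np.column_stack([np.ones(n), z1, z2])
        e = e - A @ np.linalg.lstsq(A, e, rcond=None)[0]
        y = 40 + 2 * z1 + e
        lin, quad = self._tables(y, z, n)
        out = mc.nested_f_test(lin, quad)
        assert out["f_stat"].iloc[0] == pytest.approx(0.0, abs=1e-8)
        assert out["p_f"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_scale_invariance_of_f(self):
        rng = np.random.default_rng(7)
        n = 40
        z = rng.normal(size=n)
        y = 30 + z + 0.3 * z ** 2 + rng.normal(size=n)
        lin1, quad1 = self._tables(y, z, n)
        lin2, quad2 = self._tables(7.3 * y, z, n)
        f1 = mc.nested_f_test(lin1, quad1)["f_stat"].iloc[0]
        f2 = mc.nested_f_test(lin2, quad2)["f_stat"].iloc[0]
        assert f1 == pytest.approx(f2, rel=1e-8)

    def test_mismatched_samples_rejected(self):
        rng = np.random.default_rng(8)
        lin, _ = self._tables(rng.uniform(20, 80, 30), rng.normal(size=30), 30)
        _, quad = self._tables(rng.uniform(20, 80, 40), rng.normal(size=40), 40)
        with pytest.raises(ValidationError):
            mc.nested_f_test(lin, quad)


class TestCoxMortalityEwas:
    def test_toy_loghr_matches_grid_search_oracle(self):
        rng = np.random.default_rng(9)
        n = 20
        x = rng.normal(size=n)
        cov = rng.integers(0, 2, n).astype(float)
        lp = 0.8 * x
        t = rng.exponential(np.exp(-lp)) + 0.01
        e = np.ones(n, dtype=int)
        fit = cox_fit(np.column_stack([x, cov]), t, e)
        # brute-force grid maximization of the profile over the first coef
        grid = np.arange(fit.coef[0] - 0.5, fit.coef[0] + 0.5, 1e-4)
        best, best_ll = None, -np.inf
        for b in grid:
            ll = cox_loglik(np.column_stack([x, cov]), t, e, np.array([b, fit.coef[1]]))
            if ll > best_ll:
                best, best_ll = b, ll
        assert fit.coef[0] == pytest.approx(best, abs=1e-3)

    def test_constant_cpg_degenerate(self):
        meth = toy_matrix(np.full((40, 1), 0.5))
        rng = np.random.default_rng(10)
        pheno = pd.DataFrame({
            "age": rng.uniform(40, 80, 40), "tte": rng.exponential(5, 40) + 0.1,
            "event": rng.integers(0, 2, 40)}, index=meth.sample_ids)
        table = mc.cox_mortality_ewas(meth, pheno, covariates=None)
        assert table["degenerate"].iloc[0]
        assert table["hr"].iloc[0] == 1.0 and table["p_cox"].iloc[0] == 1.0

    def test_zero_events_is_global_error(self):
        meth = toy_matrix(np.random.default_rng(0).uniform(0.2, 0.8, (10, 2)))
        pheno = pd.DataFrame({
            "age": np.linspace(30, 70, 10), "tte": np.ones(10),
            "event": np.zeros(10, dtype=int)}, index=meth.sample_ids)
        with pytest.raises(ValidationError, match="event"):
            mc.cox_mortality_ewas(meth, pheno, covariates=None)

    def test_matches_lifelines_on_untied_data(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(11)
        n = 150
        meth = toy_matrix(rng.uniform(0.2, 0.8, (n, 3)))
        lp = 1.5 * mvalues_standardized(meth)[:, 0]
        t0 = rng.exponential(np.exp(-lp))
        pheno = pd.DataFrame({
            "age": rng.uniform(30, 80, n), "tte": np.minimum(t0, 3.0) + 1e-3,
            "event": (t0 <= 3.0).astype(int)}, index=meth.sample_ids)
        table = mc.cox_mortality_ewas(meth, pheno, covariates=None)
        z = mvalues_standardized(meth)
        for j, cpg in enumerate(meth.cpg_ids):
            df = pd.DataFrame({"x": z[:, j], "t": pheno["tte"], "e": pheno["event"]})
            cph = lifelines.CoxPHFitter().fit(df, "t", "e")
            assert np.log(table.loc[cpg, "hr"]) == pytest.approx(
                cph.params_["x"], abs=1e-4)

    def test_schoenfeld_residuals_sum_to_zero_at_optimum(self):
        rng = np.random.default_rng(12)
        n = 120
        X = rng.normal(size=(n, 2))
        t0 = rng.exponential(np.exp(-X[:, 0] * 0.5))
        t = np.minimum(t0, 2.0) + 1e-3
        e = (t0 <= 2.0).astype(int)
        fit = cox_fit(X, t, e)
        res, _ = schoenfeld_residuals(X, t, e, fit.coef)
        np.testing.assert_allclose(res.sum(axis=0), 0.0, atol=1e-6)


class TestDnamPcs:
    def test_rank_one_matrix_single_pc_explains_everything(self):
        rng = np.random.default_rng(13)
        u = rng.normal(size=20)
        v = rng.uniform(0.5, 1.5, size=10)
        m = np.outer(u, v)
        meth = mc.MethylationMatrix(
            pd.DataFrame(m, index=[f"s{i}" for i in range(20)],
                         columns=[f"cg{j}" for j in range(10)]), scale="mvalue")
        scores = mc.compute_dnam_pcs(meth, 2)
        var = scores.var(axis=0, ddof=1)
        assert var["PC2"] / var["PC1"] < 1e-20

    def test_matches_dense_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(14)
        m = rng.normal(size=(20, 50))
        meth = mc.MethylationMatrix(
            pd.DataFrame(m, index=[f"s{i}" for i in range(20)],
                         columns=[f"cg{j}" for j in range(50)]), scale="mvalue")
        scores = mc.compute_dnam_pcs(meth, 2)
        z = (m - m.mean(0)) / m.std(0, ddof=1)
        U, S, _ = np.linalg.svd(z - z.mean(0), full_matrices=False)
        oracle = U[:, :2] * S[:2]
        for k in range(2):
            diff = min(np.abs(scores.iloc[:, k] - oracle[:, k]).max(),
                       np.abs(scores.iloc[:, k] + oracle[:, k]).max())
            assert diff < 1e-8

    def test_orthogonal_columns(self, small_cohort):
        meth, _, _ = small_cohort
        scores = mc.compute_dnam_pcs(meth, 4)
        centered = scores - scores.mean()
        gram = centered.T.to_numpy() @ centered.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6

    def test_k_too_large_is_error(self):
        meth = toy_matrix(np.random.default_rng(0).uniform(0.2, 0.8, (10, 30)))
        with pytest.raises(ValidationError):
            mc.compute_dnam_pcs(meth, 10)


class TestApplySignificance:
    def _table(self, ps):
        return pd.DataFrame({"p_linear": ps},
                            index=pd.Index([f"cg{i}" for i in range(len(ps))], name="cpg"))

    def test_no_hits(self):
        assert len(mc.apply_significance(self._table([0.5, 0.5]))) == 0

    def test_filter_and_sort(self):
        out = mc.apply_significance(self._table([1e-10, 1e-7, 1e-9]))
        assert list(out.index) == ["cg0", "cg2"]

    def test_threshold_one_keeps_all(self):
        assert len(mc.apply_significance(self._table([0.2, 0.9]), threshold=1.0)) == 2
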