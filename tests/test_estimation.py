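"""Model fitting, reference models, likelihood-ratio tests, fit indices."""

import numpy as np
import pytest
from scipy import optimize

import pgstransmit as pt
from pgstransmit.model import (FitResult, PGSTransmissionModel, _em_mvnormal,
                               _fiml_ll_unstructured, fit_indices, lr_test)


class TestTransmissionFit:
    def test_full_model_has_ten_free_parameters(self, fitted):
        assert fitted.n_free == 10

    def test_no_nurture_model_has_eight(self, complete_data):
        res = pt.fit_no_nurture(complete_data)
        assert res.n_free == 8
        assert res.params.g_m == 0.0 and res.params.g_f == 0.0

    def test_ml_dominance_over_generating_parameters(self, fitted,
                                                     study_params):
        assert fitted.llf >= fitted.model.loglike(study_params) - 1e-6

    def test_estimates_recover_truth_on_large_sample(self, study_params):
        data = pt.simulate_families(
            pt.SimulationConfig(n_mz=3000, n_dz=3000, seed=99))
        res = pt.fit_transmission(data)
        assert res.converged
        est, truth = res.params.to_array(), study_params.to_array()
        # loose per-parameter bands appropriate for n = 6,000 families
        tol = np.array([0.05, 0.05, 0.05, 0.03, 0.05, 0.04, 0.04, 0.04,
                        0.03, 0.03])
        assert (np.abs(est - truth) < 3 * tol).all()

    def test_invariant_to_family_order_and_twin_labels(self, missing_data):
        values, is_mz = missing_data.arrays()
        base = PGSTransmissionModel((values, is_mz)).fit()
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(values))
        shuffled = PGSTransmissionModel((values[perm], is_mz[perm])).fit()
        assert shuffled.llf == pytest.approx(base.llf, abs=1e-6)
        swapped_vals = values[:, [0, 1, 3, 2, 5, 4]]
        swapped = PGSTransmissionModel((swapped_vals, is_mz)).fit()
        assert swapped.llf == pytest.approx(base.llf, abs=1e-6)
        assert swapped.params.g_tw == pytest.approx(base.params.g_tw, abs=1e-5)

    def test_single_group_data_needs_explicit_opt_in(self):
        data = pt.simulate_families(pt.SimulationConfig(n_mz=0, n_dz=50, seed=1))
        with pytest.raises(ValueError, match="zygosity"):
            PGSTransmissionModel(data)
        res = PGSTransmissionModel(data, require_both_groups=False).fit()
        assert np.isfinite(res.llf)


class TestSaturatedAndBaseline:
    def test_complete_single_group_saturated_is_ml_moments(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(40, 6)) @ np.diag([1, 1, 1, 1, 2, 2])
        is_mz = np.zeros(40, bool)      # DZ only: no dedup interference
        sat = pt.fit_saturated((values, is_mz))
        grp = sat.params["DZ"]
        assert grp["mean"] == pytest.approx(values.mean(axis=0))
        centred = values - values.mean(axis=0)
        assert grp["cov"] == pytest.approx(centred.T @ centred / 40, abs=1e-8)
        assert sat.n_free == 27

    def test_generic_two_group_complete_data_has_54_free_parameters(self):
        # generic data: MZ twin PGS not duplicated, so all 6 variables are
        # observed in both groups
        rng = np.random.default_rng(3)
        values = rng.normal(size=(60, 6))
        is_mz = np.arange(60) < 30
        sat = pt.fit_saturated((values, is_mz))
        assert sat.n_free == 54

    def test_saturated_dominates_transmission_dominates_baseline(
            self, complete_data, fitted):
        sat = fitted.model.fit_saturated()
        base = fitted.model.fit_baseline()
        assert sat.loglik >= fitted.llf >= base.loglik
        assert base.n_free == 2 * (5 + 6)   # MZ twin-PGS column collapsed

    def test_baseline_on_generic_two_group_data_has_24_free_parameters(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(50, 6))
        is_mz = np.arange(50) < 25
        base = pt.fit_baseline((values, is_mz))
        assert base.n_free == 24
        # per-variable Gaussian fits reproduce the loglik by hand
        ll = 0.0
        for g in (values[:25], values[25:]):
            for j in range(6):
                col = g[:, j]
                v = col.var()
                ll += -0.5 * len(col) * (np.log(2 * np.pi * v) + 1)
        assert base.loglik == pytest.approx(ll, abs=1e-8)

    def test_em_reaches_the_fiml_optimum_of_a_direct_optimizer(self):
        rng = np.random.default_rng(5)
        n, k = 50, 3
        X = rng.multivariate_normal(np.zeros(k), np.eye(k) + 0.4, size=n)
        X[rng.random((n, k)) < 0.3] = np.nan
        X = X[np.isfinite(X).any(axis=1)]
        obs = np.isfinite(X)
        mu, cov, ll, ok = _em_mvnormal(X, tol=1e-12, maxiter=20000)
        assert ok

        def neg(theta):
            m = theta[:k]
            L = np.zeros((k, k))
            L[np.tril_indices(k)] = theta[k:]
            return -_fiml_ll_unstructured(X, obs, m, L @ L.T + 1e-10 * np.eye(k))

        th0 = np.concatenate([np.zeros(k), np.eye(k)[np.tril_indices(k)]])
        res = optimize.minimize(neg, th0, method="Nelder-Mead",
                                options={"maxiter": 50000, "xatol": 1e-10,
                                         "fatol": 1e-12})
        assert ll >= -res.fun - 1e-6
        assert ll == pytest.approx(-res.fun, abs=1e-3)


class TestLRT:
    def _fit(self, ll, n_free, model="full", h="same"):
        return FitResult(model=model, loglik=ll, n_free=n_free, n_families=100,
                         converged=True, data_hash=h)

    def test_identical_fits_give_zero_statistic_and_p_one(self):
        t = lr_test(self._fit(-500.0, 10), self._fit(-500.0, 8))
        assert t.statistic == 0.0 and t.p_value == 1.0

    def test_chi_square_tail_matches_reference_quantile(self):
        t = lr_test(self._fit(-500.0, 10), self._fit(-500.0 - 5.991 / 2, 8))
        assert t.df == 2
        assert t.p_value == pytest.approx(0.05, abs=5e-4)

    def test_float_noise_below_clamp_is_zeroed(self):
        t = lr_test(self._fit(-500.0005, 10), self._fit(-500.0, 8))
        assert t.statistic == 0.0 and t.p_value == 1.0

    def test_non_nested_inputs_rejected(self):
        with pytest.raises(ValueError, match="fewer free"):
            lr_test(self._fit(-500.0, 8), self._fit(-490.0, 10))
        with pytest.raises(ValueError, match="different data"):
            lr_test(self._fit(-500.0, 10, h="a"), self._fit(-501.0, 8, h="b"))

    def test_nurture_test_has_two_degrees_of_freedom(self, fitted):
        t = fitted.lr_test_nurture()
        assert t.df == 2
        assert 0.0 <= t.p_value <= 1.0


class TestFitIndices:
    def _fit(self, ll, n_free, model="x"):
        return FitResult(model=model, loglik=ll, n_free=n_free, n_families=415,
                         converged=True)

    def test_perfect_fit_gives_cfi_one_rmsea_zero(self):
        sat = self._fit(-1000.0, 54, "saturated")
        target = self._fit(-1000.0, 10)
        base = self._fit(-1400.0, 24, "baseline")
        idx = fit_indices(target, sat, base)
        assert idx.cfi == 1.0 and idx.rmsea == 0.0

    def test_formula_arithmetic_on_frozen_example(self):
        # chisq_t = 50 on df 44, chisq_b = 500 on df 30, n = 415
        sat = self._fit(-1000.0, 54, "saturated")
        target = self._fit(-1025.0, 10)
        base = self._fit(-1250.0, 24, "baseline")
        idx = fit_indices(target, sat, base)
        assert idx.chisq == pytest.approx(50.0)
        assert idx.df == 44
        assert idx.cfi == pytest.approx(1.0 - 6.0 / 470.0, abs=1e-9)
        expect_tli = ((500 / 30) - (50 / 44)) / ((500 / 30) - 1)
        assert idx.tli == pytest.approx(expect_tli, abs=1e-9)
        assert idx.rmsea == pytest.approx(np.sqrt(6.0 / (44 * 415)), abs=1e-9)

    def test_chisq_below_df_clamps_rmsea_to_zero(self):
        sat = self._fit(-1000.0, 54, "saturated")
        target = self._fit(-1010.0, 10)     # chisq 20 < df 44
        base = self._fit(-1400.0, 24, "baseline")
        assert fit_indices(target, sat, base).rmsea == 0.0

    def test_nonpositive_df_reported_undefined(self):
        sat = self._fit(-1000.0, 10, "saturated")
        target = self._fit(-1001.0, 10)
        base = self._fit(-1400.0, 8, "baseline")
        idx = fit_indices(target, sat, base)
        assert not idx.defined and np.isnan(idx.cfi)

    def test_model_generated_data_fit_well(self, fitted):
        idx = fitted.fit_indices()
        assert idx.cfi > 0.95
        assert idx.rmsea < 0.05


def test_nested_no_nurture_gap_is_chi2_scale_under_null():
    params = pt.STUDY_PARAMS.with_(g_m=0.0, g_f=0.0)
    data = pt.simulate_families(
        pt.SimulationConfig(n_mz=500, n_dz=700, params=params, seed=17))
    full = pt.fit_transmission(data)
    red = pt.fit_no_nurture(data)
    gap = 2 * (full.llf - red.llf)
    assert -1e-6 <= gap < 15.0      # chi2(2) has mean 2, far tail ~15


def test_diagnostic_plots_render(fitted):
    import matplotlib
    matplotlib.use("Agg")
    ax = fitted.plot_moments()
    assert ax.get_xlabel().startswith("model-implied")
    boot = fitted.bootstrap(n_reps=12, seed=1)
    ax2 = boot.plot("g_tw_std")
    assert ax2.get_ylabel() == "replicates"
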