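"""Mixed-effects Fourier regression, cycle test, effect size and bands."""

import numpy as np
import pandas as pd
import pytest

from cyclechrome import synthetic_data as sd
from cyclechrome.cyclic_stats import (
    ComparabilityError,
    FourierFit,
    effect_size,
    fit_fourier_mixed,
    fitted_curve_ci,
    fourier_basis,
    lr_cycle_test,
)


def make_fit(coef, cov=None, intercept=0.0, orders=2):
    coef = np.asarray(coef, dtype=float)
    if cov is None:
        cov = np.zeros((len(coef), len(coef)))
    return FourierFit(
        intercept=intercept, coef=coef, cov=np.asarray(cov, dtype=float),
        var_participant=0.0, var_cycle=0.0, var_resid=1.0, loglik=0.0,
        orders=orders, n_obs=100,
    )


class TestFourierBasis:
    def test_cardinal_days(self):
        assert np.allclose(fourier_basis(1.0), [0, 1, 0, 1], atol=1e-12)
        assert np.allclose(fourier_basis(8.0), [1, 0, 0, -1], atol=1e-12)
        assert np.allclose(fourier_basis(15.0), [0, -1, 0, 1], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fourier_basis(0.5)
        with pytest.raises(ValueError):
            fourier_basis(28.6)

    def test_day_28_sits_one_day_short_of_full_phase(self):
        step = 2.0 * np.pi / 28.0  # one day of phase
        want = [-np.sin(step), np.cos(step), -np.sin(2 * step), np.cos(2 * step)]
        assert np.allclose(fourier_basis(28.0), want, atol=1e-12)


class TestEffectSize:
    def test_pure_sine(self):
        amp = 0.7
        assert effect_size(make_fit([amp, 0, 0, 0])) == pytest.approx(
            amp / np.sqrt(2.0)
        )

    def test_unit_coefficients(self):
        assert effect_size(make_fit([1, 1, 1, 1])) == pytest.approx(np.sqrt(2.0))

    def test_matches_dense_grid_sd_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            coef = rng.normal(0, 1, 4)
            fit = make_fit(coef, intercept=rng.normal())
            theta = np.linspace(0.0, 2.0 * np.pi, 10_000, endpoint=False)
            basis = np.stack([np.sin(theta), np.cos(theta),
                              np.sin(2 * theta), np.cos(2 * theta)], axis=-1)
            curve = fit.intercept + basis @ coef
            # population SD over one full period
            assert effect_size(fit) == pytest.approx(np.std(curve), abs=1e-6)

    def test_invariant_under_phase_rotation(self):
        # rotating each harmonic pair leaves the curve SD unchanged
        coef = np.array([0.8, -0.3, 0.2, 0.5])
        phi = 1.1
        r1 = np.array([[np.cos(phi), np.sin(phi)], [-np.sin(phi), np.cos(phi)]])
        r2 = np.array([[np.cos(2 * phi), np.sin(2 * phi)],
                       [-np.sin(2 * phi), np.cos(2 * phi)]])
        rotated = np.concatenate([r1 @ coef[:2], r2 @ coef[2:]])
        assert effect_size(make_fit(rotated)) == pytest.approx(
            effect_size(make_fit(coef)), abs=1e-12
        )


class TestFittedCurveCi:
    def test_zero_covariance_collapses_bands(self):
        fit = make_fit([0.5, 0.2, 0.1, 0.0], intercept=2.0)
        curve = fitted_curve_ci(fit, np.arange(1.0, 29.0))
        assert np.allclose(curve["lower95"], curve["mean"])
        assert np.allclose(curve["upper95"], curve["mean"])

    def test_isotropic_covariance_quadratic_form(self):
        sigma2 = 0.04
        fit = make_fit([1, 0, 0, 0], cov=sigma2 * np.eye(4))
        grid = np.array([1.0, 5.0, 14.0, 22.0])
        curve = fitted_curve_ci(fit, grid)
        half = curve["upper95"] - curve["mean"]
        want = 1.96 * np.sqrt(sigma2) * np.linalg.norm(fourier_basis(grid),
                                                       axis=1)
        assert np.allclose(half, want, atol=1e-12)

    def test_band_periodicity(self):
        # bands at day 1 and just short of day 29 agree in the limit; the
        # valid domain ends at 28, so compare via the basis periodicity
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, (4, 4))
        fit = make_fit(rng.normal(0, 1, 4), cov=a @ a.T)
        c1 = fitted_curve_ci(fit, [1.0]).iloc[0]
        b_wrap = fourier_basis(1.0)  # == basis at day 29 - eps in the limit
        mean_wrap = fit.intercept + b_wrap @ fit.coef
        var_wrap = b_wrap @ fit.cov @ b_wrap
        assert c1["mean"] == pytest.approx(mean_wrap, abs=1e-12)
        assert c1["upper95"] - c1["mean"] == pytest.approx(
            1.96 * np.sqrt(var_wrap), abs=1e-12
        )

    def test_non_psd_covariance_rejected(self):
        fit = make_fit([1, 0, 0, 0], cov=-np.eye(4))
        with pytest.raises(ValueError):
            fitted_curve_ci(fit, [1.0, 2.0])


@pytest.fixture(scope="module")
def strong_signal_study():
    design = sd.StudyDesign(
        seed=77, redness_intercept=2.0, redness_coef=(1.0, 0.5, 0.0, 0.0),
        redness_participant_sd=0.3, redness_cycle_sd=0.0, redness_resid_sd=0.2,
    )
    obs, truth = sd.gen_study(design)
    return obs, truth


class TestFitFourierMixed:
    def test_recovers_strong_coefficients(self, strong_signal_study):
        obs, truth = strong_signal_study
        fit = fit_fourier_mixed(obs, "redness")
        se = np.sqrt(np.diag(fit.cov))
        truth_coef = np.array(truth["redness"]["coef"])
        assert np.all(np.abs(fit.coef - truth_coef) < 4.0 * se)
        assert fit.method == "ML"
        assert fit.var_participant > 0

    def test_null_signal_coefficients_near_zero(self):
        design = sd.StudyDesign(
            seed=123, redness_coef=(0, 0, 0, 0), redness_intercept=2.0,
            redness_participant_sd=0.3, redness_cycle_sd=0.0,
            redness_resid_sd=0.2,
        )
        obs, _ = sd.gen_study(design)
        fit = fit_fourier_mixed(obs, "redness")
        se = np.sqrt(np.diag(fit.cov))
        assert np.all(np.abs(fit.coef) < 3.5 * se)

    def test_single_cycle_per_participant_reports_zero_cycle_var(
            self, strong_signal_study):
        obs, _ = strong_signal_study
        fit = fit_fourier_mixed(obs, "redness")
        assert fit.var_cycle == 0.0
        assert fit.has_cycle_component is False

    def test_multi_cycle_design_estimates_cycle_variance(self):
        design = sd.StudyDesign(
            seed=5, cycles_per_participant=2, n_participants=12,
            redness_intercept=2.0, redness_coef=(0.3, 0.2, 0.0, 0.0),
            redness_participant_sd=0.25, redness_cycle_sd=0.25,
            redness_resid_sd=0.1,
        )
        obs, _ = sd.gen_study(design)
        fit = fit_fourier_mixed(obs, "redness")
        assert fit.has_cycle_component is True
        assert fit.var_cycle > 0.01

    def test_missing_columns_rejected(self):
        df = pd.DataFrame({"participant_id": ["a", "b"], "x": [1.0, 2.0]})
        with pytest.raises(ValueError, match="missing columns"):
            fit_fourier_mixed(df, "x")

    def test_single_participant_rejected_by_default(self, strong_signal_study):
        obs, _ = strong_signal_study
        solo = obs[obs["participant_id"] == "P01"]
        with pytest.raises(ValueError, match="participants"):
            fit_fourier_mixed(solo, "redness")


class TestLrCycleTest:
    def test_identical_models_give_zero(self):
        full = make_fit([0, 0, 0, 0])
        reduced = make_fit([])
        full.loglik = reduced.loglik = -12.5
        chi2, df, p = lr_cycle_test(full, reduced)
        assert chi2 == 0.0 and df == 4 and p == 1.0

    def test_clamped_at_zero(self):
        full, reduced = make_fit([0, 0, 0, 0]), make_fit([])
        full.loglik, reduced.loglik = -13.0, -12.5
        chi2, _, p = lr_cycle_test(full, reduced)
        assert chi2 == 0.0 and p == 1.0

    def test_strong_signal_highly_significant(self, strong_signal_study):
        obs, _ = strong_signal_study
        full = fit_fourier_mixed(obs, "redness")
        reduced = fit_fourier_mixed(obs, "redness",
                                    include_fourier_terms=False)
        chi2, df, p = lr_cycle_test(full, reduced)
        assert df == 4 and p < 1e-6

    def test_affine_outcome_rescaling_invariance(self, strong_signal_study):
        obs, _ = strong_signal_study
        full = fit_fourier_mixed(obs, "redness")
        reduced = fit_fourier_mixed(obs, "redness",
                                    include_fourier_terms=False)
        chi2, *_ = lr_cycle_test(full, reduced)
        scaled = obs.assign(redness=3.0 * obs["redness"] + 7.0)
        full2 = fit_fourier_mixed(scaled, "redness")
        reduced2 = fit_fourier_mixed(scaled, "redness",
                                     include_fourier_terms=False)
        chi2b, *_ = lr_cycle_test(full2, reduced2)
        assert chi2b == pytest.approx(chi2, abs=1e-4)

    def test_risk_covariate_keeps_df_four(self, strong_signal_study):
        from cyclechrome.cycle_time import conception_risk
        from cyclechrome.synthetic_data import placeholder_risk_table

        obs, _ = strong_signal_study
        table = placeholder_risk_table()
        obs = obs.assign(
            risk=[conception_risk(d, table) for d in obs["adjusted_day"]]
        )
        full = fit_fourier_mixed(obs, "redness", covariates=["risk"])
        reduced = fit_fourier_mixed(obs, "redness", covariates=["risk"],
                                    include_fourier_terms=False)
        chi2, df, p = lr_cycle_test(full, reduced)
        assert df == 4
        assert "risk" in full.covariate_coef

    def test_mismatched_rows_rejected(self, strong_signal_study):
        obs, _ = strong_signal_study
        full = fit_fourier_mixed(obs, "redness")
        reduced = fit_fourier_mixed(obs.iloc[:-5], "redness",
                                    include_fourier_terms=False)
        with pytest.raises(ComparabilityError):
            lr_cycle_test(full, reduced)
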