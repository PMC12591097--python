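"""ICL calibration, synthetic-data generation and cross-dose validation."""

import numpy as np
import pytest

from depotsim import (
    FitTarget,
    fit_icl,
    fixtures,
    generate_synthetic_profile,
    pk_metrics,
    simulate,
    validate_doses,
)
from depotsim.calibration import _residuals, apply_params

from conftest import make_fast_suspension


@pytest.fixture(scope="module")
def solution_scenario():
    return fixtures.build_scenario("ar_im_solution_5mg")


class TestSyntheticProfiles:
    times = np.linspace(1.0, 160.0, 50)

    def test_zero_cv_returns_model_values(self, solution_scenario):
        target = generate_synthetic_profile(solution_scenario, self.times, 0.0, 7)
        result = simulate(solution_scenario)
        np.testing.assert_allclose(
            target.conc, np.interp(self.times, result.t, result.cp), rtol=1e-12
        )

    def test_seed_determinism(self, solution_scenario):
        t1 = generate_synthetic_profile(solution_scenario, self.times, 0.2, 42)
        t2 = generate_synthetic_profile(solution_scenario, self.times, 0.2, 42)
        t3 = generate_synthetic_profile(solution_scenario, self.times, 0.2, 43)
        assert (t1.conc == t2.conc).all()
        assert (t1.conc != t3.conc).any()

    def test_noise_multipliers_are_mean_one(self, solution_scenario):
        """10,000 log-normal factors with cv 0.1 average to 1 within 2%."""
        many = np.linspace(1.0, 160.0, 10_000)
        clean = generate_synthetic_profile(solution_scenario, many, 0.0, 1)
        noisy = generate_synthetic_profile(solution_scenario, many, 0.1, 1)
        mult = noisy.conc / clean.conc
        assert mult.mean() == pytest.approx(1.0, abs=0.02)
        assert mult.std() / mult.mean() == pytest.approx(0.1, rel=0.1)


class TestFitICL:
    def test_noiseless_self_consistency(self, fast_suspension):
        """Fitting noise-free synthetic metrics recovers the generator.

        The conductance depends on (kappa/a, b) only, so those are the
        identifiable quantities; the objective must vanish at the optimum.
        """
        truth_ratio = fast_suspension.icl.kappa / fast_suspension.icl.a
        truth_b = fast_suspension.icl.b
        target = FitTarget(kind="metrics", metrics=pk_metrics(simulate(fast_suspension)))
        fit = fit_icl(fast_suspension, target)
        assert fit.objective < 1e-12
        assert fit.params["b"] == pytest.approx(truth_b, rel=0.01)
        assert fit.params["kappa"] / fit.params["a"] == pytest.approx(
            truth_ratio, rel=0.01
        )

    def test_refit_from_optimum_is_fixed_point(self, fast_suspension):
        target = FitTarget(kind="metrics", metrics=pk_metrics(simulate(fast_suspension)))
        fit = fit_icl(fast_suspension, target)
        refit = fit_icl(apply_params(fast_suspension, fit.params), target)
        assert fit.objective - refit.objective < 1e-10

    def test_objective_invariant_to_point_order(self, fast_suspension):
        times = np.array([100.0, 400.0, 900.0, 1500.0])
        target = generate_synthetic_profile(fast_suspension, times, 0.1, 3)
        perm = np.array([2, 0, 3, 1])
        shuffled = FitTarget(
            kind="profile", times=target.times[perm], conc=target.conc[perm]
        )
        x = np.array([np.log10(2.09e-6), np.log10(0.012), 0.0])
        r1 = _residuals(fast_suspension, target, ("a", "b", "kappa"), x)
        r2 = _residuals(fast_suspension, shuffled, ("a", "b", "kappa"), x)
        assert np.dot(r1, r1) == pytest.approx(np.dot(r2, r2), rel=1e-12)

    def test_underdetermined_target_rejected(self, fast_suspension):
        target = FitTarget(kind="profile", times=[100.0], conc=[5.0])
        with pytest.raises(ValueError):
            fit_icl(fast_suspension, target, free=("a", "b", "kappa"))

    def test_unknown_free_parameter_rejected(self, fast_suspension):
        target = FitTarget(kind="profile", times=[1.0, 2.0], conc=[1.0, 2.0])
        with pytest.raises(ValueError):
            fit_icl(fast_suspension, target, free=("a", "nope"))

    def test_fit_to_observed_400_metrics(self, icl_fit, observed, suspension_scenarios):
        """The calibrated model reproduces the 400 mg-eq target closely."""
        result = simulate(
            apply_params(suspension_scenarios["arl_im_400"], icl_fit.params)
        )
        sim = pk_metrics(result, t_last=observed["arl_im_400"].t_last)
        assert sim.cmax / observed["arl_im_400"].cmax == pytest.approx(1.0, abs=0.10)
        assert sim.auc0t / observed["arl_im_400"].auc0t == pytest.approx(1.0, abs=0.10)
        assert icl_fit.converged


class TestValidateDoses:
    def test_identity_when_observed_equals_simulated(self, fast_suspension):
        m = pk_metrics(simulate(fast_suspension))
        params = {
            "a": fast_suspension.icl.a,
            "b": fast_suspension.icl.b,
            "kappa": fast_suspension.icl.kappa,
        }
        table = validate_doses(params, {"self": fast_suspension}, {"self": m})
        row = table.iloc[0]
        assert row.fe_cmax == pytest.approx(1.0, rel=1e-6)
        assert row.fe_auc == pytest.approx(1.0, rel=1e-6)
        assert bool(row.cmax_pass) and bool(row.auc_pass)

    def test_empty_inputs_give_empty_table(self):
        table = validate_doses({"a": 1e-6, "b": 0.01, "kappa": 1.0}, {}, {})
        assert len(table) == 0

    def test_missing_observed_raises(self, fast_suspension):
        with pytest.raises(KeyError):
            validate_doses(
                {"a": 1e-6, "b": 0.01, "kappa": 1.0},
                {"x": fast_suspension},
                {},
            )
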