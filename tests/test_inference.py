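import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from amylv.forward import ReducedOrderInflation
from amylv.inference import (
    CaseData,
    MaterialParameterEstimator,
    ObjectiveSpec,
    PressureModel,
    XI_RANGE,
    closure_as,
    closure_bs_bfs,
    objective,
    residual_bootstrap,
    scale_pressure,
)
from amylv.markers import score_distribution
from amylv.synthetic import NoiseModel, closure_consistent_truth, generate_diastolic_series


class TestPressureScaling:
    @pytest.mark.parametrize(
        "v_ratio, expected",
        [
            (1.5379, 10.91),
            (2.7021, 19.17),
            (1.9746, 14.01),
            (3.2463, 23.03),
            (3.5, 24.83),
            (2.678, 19.00),  # the cohort-mean ratio maps to the mean pressure
        ],
    )
    def test_reference_cohort_baseline_pressures(self, v_ratio, expected):
        assert scale_pressure(v_ratio) == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize(
        "v_ratio, expected",
        [(1.8881, 13.39), (3.8163, 27.07), (1.6576, 11.76), (3.196, 22.67),
         (5.0283, 35.67)],
    )
    def test_reference_cohort_followup_pressures(self, v_ratio, expected):
        assert scale_pressure(v_ratio) == pytest.approx(expected, abs=0.01)

    def test_linearity(self):
        assert scale_pressure(2.0) * 1.7 == pytest.approx(scale_pressure(3.4))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            scale_pressure(-1.0)
        with pytest.raises(ValueError):
            PressureModel(p_edm=0.0)


class TestObjective:
    def test_perfect_model_scores_zero(self):
        v = np.array([50.0, 60.0, 70.0])
        e = np.zeros((3, 20, 3)) + 0.05
        assert objective(v, e, v, e) == (0.0, 0.0, 0.0)

    def test_single_frame_arithmetic(self):
        f_v, f_e, f_ve = objective(
            np.array([100.0]), np.zeros((3, 20, 1)),
            np.array([110.0]), np.zeros((3, 20, 1)),
            ObjectiveSpec(w_v=1.0, w_E=1.0, n_time=1),
        )
        assert f_v == pytest.approx(0.01)
        assert f_e == 0.0
        assert f_ve == pytest.approx(0.01)

    def test_matches_bruteforce_triple_loop(self):
        rng = np.random.default_rng(12)
        dv, mv = 50 + 10 * rng.random(4), 50 + 10 * rng.random(4)
        de, me = rng.random((3, 20, 4)) * 0.1, rng.random((3, 20, 4)) * 0.1
        w_v, w_e = 1.3, 0.7
        f_v, f_e, f_ve = objective(dv, de, mv, me, ObjectiveSpec(w_v, w_e, n_time=4))
        brute_v = w_v * sum(((mv[i] - dv[i]) / dv[i]) ** 2 for i in range(4))
        brute_e = 0.0
        for k in range(3):
            for r in range(20):
                for i in range(4):
                    brute_e += (me[k, r, i] - de[k, r, i]) ** 2
        brute_e *= w_e / 60.0
        assert f_v == pytest.approx(brute_v, rel=1e-12)
        assert f_e == pytest.approx(brute_e, rel=1e-12)
        assert f_ve == pytest.approx(brute_v + brute_e, rel=1e-12)

    def test_zero_measured_volume_rejected(self):
        with pytest.raises(ValueError, match="zero measured volume"):
            objective(
                np.array([0.0]), np.zeros((3, 20, 1)),
                np.array([1.0]), np.zeros((3, 20, 1)),
            )


class TestClosures:
    def test_constructed_fixed_point(self):
        # a_f chosen so a_s = 1 solves the regression with a_fs = 1
        assert closure_as(4.65 / 1.72, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_quadratic_root_against_numeric_solver(self):
        for a_f, a_fs in [(2.0, 0.5), (0.3, 1.2), (10.0, 0.05)]:
            a_s = closure_as(a_f, a_fs)
            num = brentq(
                lambda x: x**2 + 3.65 * a_fs * x - 1.72 * a_f * a_fs, 1e-12, 1e3
            )
            assert a_s == pytest.approx(num, rel=1e-10)

    def test_direct_substitution_example(self):
        b_s, b_fs = closure_bs_bfs(2.0, 2.0)
        assert b_s == pytest.approx(1.0)
        assert b_fs == pytest.approx(2.0 / 1.5)

    def test_singular_xi_rejected(self):
        with pytest.raises(ValueError, match="xi"):
            closure_bs_bfs(2.0, 1.61 / 0.43)  # outside the admissible range

    @given(
        a_f=st.floats(0.05, 50.0),
        a_fs=st.floats(0.05, 50.0),
        b_f=st.floats(0.5, 30.0),
        xi=st.floats(*XI_RANGE),
    )
    @settings(max_examples=200, deadline=None)
    def test_closure_outputs_satisfy_the_regressions(self, a_f, a_fs, b_f, xi):
        a_s = closure_as(a_f, a_fs)
        assert a_s / a_fs == pytest.approx(1.72 * a_f / a_s - 3.65, abs=1e-10)
        b_s, b_fs = closure_bs_bfs(b_f, xi)
        assert b_s / b_fs == pytest.approx(-0.43 * b_f / b_s + 1.61, abs=1e-10)

    def test_invalid_closure_inputs(self):
        with pytest.raises(ValueError):
            closure_as(-1.0, 1.0)
        with pytest.raises(ValueError):
            closure_bs_bfs(0.0, 2.0)


@pytest.fixture(scope="module")
def fitted_zero_noise(tiny_mesh):
    """Zero-noise synthetic case fitted by the two-step estimator."""
    model = ReducedOrderInflation()
    rec = generate_diastolic_series(
        tiny_mesh, closure_consistent_truth(), n_time=4,
        noise=NoiseModel(0.0, 0.0, 0), model=model,
    )
    est = MaterialParameterEstimator(
        forward_model=model, n_starts=1, max_nfev=40, xi_tol=5e-3, random_state=0
    )
    est.fit(rec.as_case_data())
    return rec, est


class TestTwoStepFit:
    def test_zero_noise_objective_collapses(self, fitted_zero_noise):
        _, est = fitted_zero_noise
        assert est.result_.f_ve < 1e-4
        assert est.result_.f_ve == pytest.approx(
            est.result_.f_v + est.result_.f_e, rel=1e-12
        )

    def test_local_optimality_of_the_estimate(self, fitted_zero_noise):
        rec, est = fitted_zero_noise
        case = rec.as_case_data()
        model = est.forward_model
        base = est.result_.f_ve

        def f_ve_at(params):
            pressures = np.linspace(0, case.p_ed, case.n_time)
            res = model.solve(case.mesh, params, pressures, strict=False)
            from amylv import geometry

            field = geometry.regional_strains(res.frames, case.mesh)
            return objective(case.volumes, case.ecc, res.curve.volumes,
                             field.E_cc)[2]

        arr = est.params_.as_array()
        for idx in (0, 2, 6):  # a, a_f, a_fs
            for fac in (0.8, 1.2):
                pert = arr.copy()
                pert[idx] *= fac
                from amylv.mechanics import MaterialParameters

                assert f_ve_at(MaterialParameters.from_array(pert)) >= base - 1e-9

    def test_deterministic_under_fixed_seed(self, tiny_mesh):
        model = ReducedOrderInflation()
        rec = generate_diastolic_series(
            tiny_mesh, closure_consistent_truth(), n_time=3,
            noise=NoiseModel(0.02, 0.01, 7), model=model,
        )
        kw = dict(n_starts=2, max_nfev=15, xi_tol=1e-2, random_state=3)
        a = MaterialParameterEstimator(forward_model=model, **kw).fit(rec.as_case_data())
        b = MaterialParameterEstimator(forward_model=model, **kw).fit(rec.as_case_data())
        np.testing.assert_array_equal(a.params_.as_array(), b.params_.as_array())
        assert a.xi_ == b.xi_

    def test_step2_beats_both_interval_endpoints(self, fitted_zero_noise):
        rec, est = fitted_zero_noise
        case = rec.as_case_data()
        model = est.forward_model
        from amylv.mechanics import HEALTHY_SECOND_GROUP, MaterialParameters

        def f_e_at(xi):
            a, b, a_f, b_f, a_fs = np.exp(est.theta_)
            p = MaterialParameters(
                a, b, a_f, b_f, closure_as(a_f, a_fs),
                *closure_bs_bfs(b_f, xi)[:1], a_fs, closure_bs_bfs(b_f, xi)[1],
            )
            res = model.solve(case.mesh, p, np.linspace(0, case.p_ed, case.n_time),
                              strict=False)
            from amylv import geometry

            field = geometry.regional_strains(res.frames, case.mesh)
            return objective(case.volumes, case.ecc, res.curve.volumes,
                             field.E_cc)[1]

        assert est.result_.f_e <= f_e_at(XI_RANGE[0]) + 1e-12
        assert est.result_.f_e <= f_e_at(XI_RANGE[1]) + 1e-12

    def test_accepted_cost_sequence_is_monotone(self, fitted_zero_noise):
        _, est = fitted_zero_noise
        costs = est.result_.accepted_costs
        assert np.all(np.diff(costs) <= 0)

    def test_fitted_parameters_give_valid_stress_stretch_curve(self, fitted_zero_noise):
        from amylv.mechanics import uniaxial_fiber_response

        _, est = fitted_zero_noise
        curve = uniaxial_fiber_response(est.params_, 1.15, 10)
        assert curve.stresses[0] == 0.0
        assert np.all(np.diff(curve.stresses) > 0)


class TestResidualBootstrap:
    def test_zero_residuals_collapse_to_the_point_estimate(self, fitted_zero_noise):
        import dataclasses

        rec, est = fitted_zero_noise
        # a fit whose observations equal its own predictions: residuals are
        # identically zero, so every surrogate dataset is the original one
        case = CaseData(
            mesh=rec.template, p_ed=rec.p_ed,
            volumes=est.result_.pred_volumes, ecc=est.result_.pred_ecc,
        )
        est0 = MaterialParameterEstimator(
            forward_model=est.forward_model, n_starts=1, max_nfev=40,
            xi_tol=1e-2, random_state=0,
        )
        est0.fit(case, theta0=est.theta_)
        est0.result_ = dataclasses.replace(
            est0.result_,
            residuals_volume=np.zeros_like(est0.result_.residuals_volume),
            residuals_strain=np.zeros_like(est0.result_.residuals_strain),
            pred_volumes=case.volumes,
            pred_ecc=case.ecc,
        )
        boot = residual_bootstrap(
            est0, case, n_boot=5, seed=2, refit_max_nfev=5, refit_restarts=0
        )
        # every replicate sees the identical (noise-free) surrogate: draws
        # collapse onto the point estimate (up to solver tolerance)
        for draw in boot.draws:
            np.testing.assert_allclose(draw, est0.params_.as_array(), rtol=1e-6)

    def test_same_seed_gives_identical_draws(self, fitted_zero_noise, tiny_mesh):
        model = ReducedOrderInflation()
        rec = generate_diastolic_series(
            tiny_mesh, closure_consistent_truth(), n_time=3,
            noise=NoiseModel(0.02, 0.01, 5), model=model,
        )
        est = MaterialParameterEstimator(
            forward_model=model, n_starts=1, max_nfev=15, xi_tol=1e-2,
            random_state=0,
        ).fit(rec.as_case_data())
        a = residual_bootstrap(est, rec.as_case_data(), n_boot=3, seed=11,
                               refit_max_nfev=3, refit_restarts=0)
        b = residual_bootstrap(est, rec.as_case_data(), n_boot=3, seed=11,
                               refit_max_nfev=3, refit_restarts=0)
        np.testing.assert_array_equal(a.draws, b.draws)
        assert a.n_dropped == b.n_dropped == 0


class TestScoreDistribution:
    def test_matches_bruteforce_enumeration_on_a_two_marker_toy(self):
        """Only two markers vary across draws; the score distribution must
        equal the enumeration over the four call combinations weighted by
        their draw frequencies."""
        rng = np.random.default_rng(0)
        n = 400
        m1 = rng.random(n) < 0.7  # better with probability 0.7
        m2 = rng.random(n) < 0.4
        fixed = np.tile([True, False, True, False, True], (n, 1))
        calls = np.column_stack([m1, m2, fixed])
        dist = score_distribution(calls)
        # brute force over the 4 combinations of the two varying markers
        expected = {}
        for v1 in (True, False):
            for v2 in (True, False):
                w = np.mean((m1 == v1) & (m2 == v2))
                s = (v1 + v2 + 3) / 7.0
                expected[s] = expected.get(s, 0.0) + w
        for s, p in expected.items():
            if p > 0:
                assert dist[s] == pytest.approx(p, abs=1e-12)
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_degenerate_draws_give_a_point_mass(self):
        calls = np.tile([True, True, False, False, True, False, True], (10, 1))
        dist = score_distribution(calls)
        assert dist == {4 / 7: 1.0}
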