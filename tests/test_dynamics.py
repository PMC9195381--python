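import numpy as np
import pytest

from grsr.dynamics import (
    DEFAULT_INIT,
    ModelParams,
    ModelState,
    NoLysogensError,
    ParameterError,
    SCENARIOS,
    grsr_sweep,
    induction_rate,
    infection_lambda,
    logistic_growth,
    model_specialization,
    poisson_multiplicity,
    replace_lysogen_size,
    rhs,
    scenario_params,
    simulate,
    temperature_fitness,
)


class TestElementaryRates:
    def test_logistic_at_capacity_and_zero(self):
        assert logistic_growth(1e7, 2.0, 1e7) == 0.0
        assert logistic_growth(0.0, 2.0, 1e7) == 2.0
        assert logistic_growth(5e6, 2.0, 1e7) == pytest.approx(1.0)

    def test_logistic_invalid_capacity(self):
        with pytest.raises(ParameterError):
            logistic_growth(1.0, 2.0, 0.0)

    def test_temperature_fitness_peak_and_width(self):
        assert temperature_fitness(30.0, 30.0, 10.0) == 1.0
        assert temperature_fitness(40.0, 30.0, 10.0) == pytest.approx(
            np.exp(-0.5))

    @pytest.mark.parametrize("x", [0.5, 3.0, 17.2])
    def test_temperature_fitness_symmetry(self, x):
        assert temperature_fitness(30 + x, 30, 8.0) == pytest.approx(
            temperature_fitness(30 - x, 30, 8.0))

    def test_temperature_fitness_invalid_sigma(self):
        with pytest.raises(ParameterError):
            temperature_fitness(30.0, 30.0, 0.0)

    def test_induction_half_at_heat_threshold(self):
        p = ModelParams(T_h=37.0, T_c=-100.0, xi0=2.0)
        assert induction_rate(37.0, p) == pytest.approx(1.0)

    def test_induction_saturates(self):
        p = ModelParams(xi0=2.0)
        assert induction_rate(200.0, p) == pytest.approx(2.0)

    def test_induction_closed_between_switches(self):
        p = ModelParams(T_h=37.0, T_c=4.0, k=5.0)
        assert induction_rate(20.0, p) < 1e-10

    def test_induction_off_mode(self):
        p = ModelParams(switch_mode="off")
        assert induction_rate(37.0, p) == 0.0

    @pytest.mark.parametrize("mode,expect_hot,expect_cold", [
        ("heat_only", True, False),
        ("cold_only", False, True),
    ])
    def test_single_switch_modes(self, mode, expect_hot, expect_cold):
        p = ModelParams(switch_mode=mode, xi0=1.0, k=2.0)
        hot = induction_rate(60.0, p) > 0.5
        cold = induction_rate(-20.0, p) > 0.5
        assert hot == expect_hot and cold == expect_cold

    def test_infection_lambda_substitutions(self):
        assert infection_lambda(0.0, 100.0, 100.0, 1.0) == pytest.approx(1.0)
        assert infection_lambda(50.0, 0.0, 100.0, 1.0) == 0.0
        assert infection_lambda(200.0, 50.0, 100.0, 1.0) == pytest.approx(1.5)
        assert infection_lambda(10.0, 10.0, 0.0, 1.0) == 0.0

    @pytest.mark.parametrize("lam", [0.0, 0.3, 1.0, 4.7, 40.0])
    @pytest.mark.parametrize("imax", [1, 5, 10])
    def test_poisson_multiplicity_sums_to_one(self, lam, imax):
        pr = poisson_multiplicity(lam, imax)
        assert pr.size == imax + 1
        assert pr.sum() == pytest.approx(1.0, abs=1e-15)
        assert (pr >= 0).all()

    def test_poisson_multiplicity_values(self):
        assert poisson_multiplicity(0.0, 5)[0] == 1.0
        assert poisson_multiplicity(1.0, 5)[1] == pytest.approx(np.exp(-1))

    def test_poisson_multiplicity_negative_lambda(self):
        with pytest.raises(ParameterError):
            poisson_multiplicity(-0.1, 5)


class TestParamsValidation:
    @pytest.mark.parametrize("kwargs", [
        {"C": 0.0}, {"alpha": 1.5}, {"beta": -1.0}, {"sigma_plus": 0.0},
        {"I_max": 0}, {"delta": -1e-9}, {"switch_mode": "sometimes"},
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ParameterError):
            ModelParams(**kwargs)

    def test_scenarios_available(self):
        assert set(SCENARIOS) == {"thermophile", "mesophile", "psychrophile"}
        p = scenario_params(ModelParams(), "psychrophile", "off")
        assert p.T_env == 4.0 and p.switch_mode == "off"
        with pytest.raises(ParameterError, match="unknown scenario"):
            scenario_params(ModelParams(), "lunarphile")


class TestRhs:
    def test_decoupled_limit_is_pure_logistic(self):
        p = ModelParams(delta=0.0, tau=0.0)
        state = ModelState(2e5, 3e5, np.zeros(10), 0.0)
        dy = rhs(state, 0.0, p)
        n = state.n
        theta = temperature_fitness(p.T_env, p.T_plus, p.sigma_plus)
        assert dy[0] == pytest.approx(
            logistic_growth(n, p.V_plus, p.C) * theta * state.b_plus)
        assert dy[1] == pytest.approx(
            logistic_growth(n, p.V_minus, p.C) * theta * state.b_minus)
        assert dy[2:-1] == pytest.approx(np.zeros(10))
        assert dy[-1] == 0.0

    def test_cell_derivative_sum_matches_n_finite_difference(self):
        # dN/dt (defined as the sum of the cell-compartment derivatives)
        # must agree with the finite difference of N along a simulation
        p = ModelParams(tau=0.0)
        traj = simulate(p, t_end=2.0, dt_out=0.001)
        i = 600
        state = ModelState(traj.b_plus[i], traj.b_minus[i],
                           traj.b_lysogen[i], traj.p[i])
        dy = rhs(state, traj.times[i], p)
        n = traj.n
        fd_n = (n[i + 1] - n[i - 1]) / 0.002
        assert np.sum(dy[:12]) == pytest.approx(fd_n, rel=1e-4)

    def test_finite_difference_consistency(self):
        p = ModelParams(tau=0.0)
        traj = simulate(p, t_end=2.0, dt_out=0.001)
        i = 1000  # interior point
        state = ModelState(traj.b_plus[i], traj.b_minus[i],
                           traj.b_lysogen[i], traj.p[i])
        dy = rhs(state, traj.times[i], p)
        fd_bplus = (traj.b_plus[i + 1] - traj.b_plus[i - 1]) / 0.002
        fd_p = (traj.p[i + 1] - traj.p[i - 1]) / 0.002
        assert dy[0] == pytest.approx(fd_bplus, rel=1e-4)
        assert dy[-1] == pytest.approx(fd_p, rel=1e-3, abs=1e-3 * p.C)


class TestSimulate:
    def test_logistic_closed_form_when_decoupled(self):
        p = ModelParams(delta=0.0, tau=0.0)
        b0 = 1e4
        init = ModelState(0.0, b0, np.zeros(10), 0.0)
        traj = simulate(p, init, t_end=10.0, dt_out=0.1)
        v_eff = p.V_minus * temperature_fitness(p.T_env, p.T_minus, p.sigma_minus)
        analytic = p.C / (1 + (p.C / b0 - 1) * np.exp(-v_eff * traj.times))
        assert np.max(np.abs(traj.b_minus - analytic) / analytic) < 1e-6

    def test_all_zero_initial_state_stays_zero(self):
        init = ModelState(0.0, 0.0, np.zeros(10), 0.0)
        traj = simulate(ModelParams(), init, t_end=5.0, dt_out=0.5)
        assert traj.b_plus.max() == 0.0
        assert traj.p.max() == 0.0
        assert traj.b_lysogen.max() == 0.0

    def test_pure_adsorption_virus_nonincreasing(self):
        # alpha = 1 and no induction: virus is only ever adsorbed
        p = ModelParams(alpha=1.0, xi0=0.0, tau=0.0)
        traj = simulate(p, t_end=10.0, dt_out=0.1)
        assert (np.diff(traj.p) <= 1e-9 * traj.p[:-1] + 1e-12).all()

    def test_conservation_residual_small(self):
        traj = simulate(ModelParams(), t_end=20.0, dt_out=0.1)
        assert traj.conservation_residual.max() < 1e-6

    def test_nonnegative_outputs(self):
        traj = simulate(ModelParams(), t_end=20.0, dt_out=0.1)
        for series in (traj.b_plus, traj.b_minus, traj.p):
            assert (series >= 0).all()
        assert (traj.b_lysogen >= 0).all()

    def test_delay_changes_dynamics(self):
        base = dict(t_end=10.0, dt_out=0.1)
        fast = simulate(ModelParams(tau=0.0), **base)
        delayed = simulate(ModelParams(tau=1.0), **base)
        assert not np.allclose(fast.p, delayed.p, rtol=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            simulate(ModelParams(), t_end=0.0)
        with pytest.raises(ParameterError, match="nonnegative"):
            simulate(ModelParams(),
                     ModelState(-1.0, 0.0, np.zeros(10), 0.0), t_end=1.0)
        with pytest.raises(ParameterError, match="lysogen bins"):
            simulate(ModelParams(I_max=5),
                     ModelState(1.0, 1.0, np.zeros(10), 0.0), t_end=1.0)


class TestModelSpecialization:
    def test_single_species_lysogens(self):
        lys = np.zeros(10)
        lys[0] = 5e4
        assert model_specialization(ModelState(0, 0, lys, 0)) == 1.0

    def test_two_equal_bins(self):
        lys = np.zeros(10)
        lys[0] = lys[1] = 1e3
        assert model_specialization(ModelState(0, 0, lys, 0)) == pytest.approx(
            2.0 / 3.0)

    def test_bounds_on_random_states(self, rng):
        for _ in range(200):
            lys = rng.random(10) * rng.choice([0, 1], size=10, p=[0.3, 0.7])
            if lys.sum() == 0:
                continue
            d = model_specialization(ModelState(0, 0, lys, 0))
            assert 1.0 / 10 <= d <= 1.0

    def test_no_lysogens_raises(self):
        with pytest.raises(NoLysogensError):
            model_specialization(ModelState(1e5, 1e4, np.zeros(10), 1e3))


class TestGrsrSweep:
    def test_no_virus_control_reports_no_lysogens(self):
        p = ModelParams(xi0=0.0)
        init = ModelState(1e5, 1e3, np.zeros(10), 0.0)  # P0 = 0
        pts = grsr_sweep(p, [0.5, 1.0, 2.0], "control", init=init, t_end=5.0)
        assert all(pt.status == "no_lysogens" for pt in pts)
        assert all(np.isnan(pt.d) for pt in pts)

    def test_unsorted_rates_rejected(self):
        with pytest.raises(ParameterError, match="sorted"):
            grsr_sweep(ModelParams(), [2.0, 1.0], "x")

    def test_default_init_shape_tracks_imax(self):
        init = replace_lysogen_size(DEFAULT_INIT, 4)
        assert init.b_lysogen.size == 4
        pts = grsr_sweep(ModelParams(I_max=4), [1.0, 2.0, 4.0], "x",
                         init=init, t_end=5.0)
        assert {pt.status for pt in pts} == {"ok"}
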