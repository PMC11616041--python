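"""Unit and property tests for the kinetic model module."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retikin.exceptions import (
    DegenerateModelError,
    ModelStructureError,
    ValidationError,
)
from retikin.model import (
    ADJUSTABLE_RATES,
    FIXED_RATES,
    RATE_KEYS,
    ModelParameters,
    assemble_parameters,
    compute_kinetic_summaries,
    default_time_grid,
    load_parameters,
    plasma_return_probability,
    save_parameters,
    simulate_tracer,
    solve_steady_state,
)

from .oracles import markov_expected_plasma_visits


# ---------------------------------------------------------------------------
# parameters and constraint
# ---------------------------------------------------------------------------


class TestParameters:
    def test_reference_constraint_l85(self, ref_params):
        # L(8,5) = L(0,6) L(6,5) / (L(5,6) + L(0,6))
        expected = 0.00070779 * 5.23994 / (0.0184312 + 0.00070779)
        assert ref_params.l[(8, 5)] == pytest.approx(expected, rel=1e-12)
        # and it matches the conventional rounded report to 4 significant digits
        assert ref_params.l[(8, 5)] == pytest.approx(0.19378, rel=5e-4)

    def test_absorption_efficiency(self, ref_params):
        assert ref_params.absorption_efficiency == pytest.approx(0.7502, abs=5e-5)

    def test_zero_storage_loss_forces_zero_plasma_loss(self, ref_params):
        p = ref_params.replace(**{"L(0,6)": 0.0})
        assert p.l[(8, 5)] == 0.0

    def test_constraint_degenerate_cases(self, ref_params):
        # L(5,6) = L(0,6) = 0: no flux leaves compartment 6, and no loss
        # means the partition rule forces L(8,5) = 0 as well
        assert ModelParameters.constrained_l85(
            {(5, 6): 0.0, (0, 6): 0.0, (6, 5): 1.0}
        ) == 0.0
        # a full parameter set with L(5,6)=0 but L(0,6)>0 is fine
        p = ref_params.replace(**{"L(5,6)": 0.0})
        assert p.l[(8, 5)] == pytest.approx(p.l[(6, 5)])

    def test_negative_coefficient_rejected(self, ref_params):
        with pytest.raises(ValidationError):
            ref_params.replace(**{"L(6,5)": -1.0})

    def test_missing_coefficient_rejected(self):
        with pytest.raises(ValidationError):
            assemble_parameters({"DT(3)": 0.1})

    def test_roundtrip_save_load(self, ref_params, tmp_path):
        path = tmp_path / "p.json"
        save_parameters(ref_params, path)
        p2 = load_parameters(path)
        for k in RATE_KEYS:
            assert p2.l[k] == pytest.approx(ref_params.l[k], rel=1e-12)
        assert p2.dt3 == ref_params.dt3
        assert p2.dt8 == ref_params.dt8

    def test_fixed_rates_defaults(self, ref_params):
        for k, v in FIXED_RATES.items():
            assert ref_params.l[k] == v
        assert set(ADJUSTABLE_RATES) <= set(RATE_KEYS)


# ---------------------------------------------------------------------------
# tracer simulation
# ---------------------------------------------------------------------------


class TestSimulateTracer:
    def test_initial_condition(self, ref_params):
        sol = simulate_tracer(ref_params, [0.0, 0.001])
        assert sol.fd[1][0] == pytest.approx(1.0)
        assert sol.fdp[0] == 0.0
        assert sol.total()[0] == pytest.approx(1.0, abs=1e-12)

    def test_plasma_peak_near_half_day(self, ref_params):
        grid = default_time_grid(2.0)
        sol = simulate_tracer(ref_params, grid)
        t_peak = grid[np.argmax(sol.fdp)]
        assert 0.3 <= t_peak <= 0.8

    def test_linearity_in_dose(self, ref_params, sample_times):
        full = simulate_tracer(ref_params, sample_times, dose_fraction=1.0)
        half = simulate_tracer(ref_params, sample_times, dose_fraction=0.5)
        for c in full.fd:
            np.testing.assert_allclose(full.fd[c] * 0.5, half.fd[c], rtol=1e-10,
                                       atol=1e-15)

    def test_mass_conservation_reference(self, ref_params):
        grid = default_time_grid(91.0)
        sol = simulate_tracer(ref_params, grid)
        np.testing.assert_allclose(sol.total(), 1.0, atol=1e-6)

    def test_ode_matches_analytic(self, ref_params, sample_times):
        a = simulate_tracer(ref_params, sample_times, method="analytic")
        o = simulate_tracer(ref_params, sample_times, method="ode")
        np.testing.assert_allclose(a.fdp, o.fdp, atol=2e-8)
        np.testing.assert_allclose(a.total(), o.total(), atol=1e-7)

    def test_terminal_slope_is_system_fcr(self, ref_params, ref_ss):
        # for t > 60 d the local log-slope of fd5 approaches
        # -DR/(M5+M6+M7) within 5%
        t = np.array([70.0, 91.0])
        fdp = simulate_tracer(ref_params, t).fdp
        slope = (np.log(fdp[1]) - np.log(fdp[0])) / (t[1] - t[0])
        fcr = ref_ss.dr / (ref_ss.m[5] + ref_ss.m[6] + ref_ss.m[7])
        assert slope == pytest.approx(-fcr, rel=0.05)

    def test_input_validation(self, ref_params):
        with pytest.raises(ValidationError):
            simulate_tracer(ref_params, [])
        with pytest.raises(ValidationError):
            simulate_tracer(ref_params, [2.0, 1.0])
        with pytest.raises(ValidationError):
            simulate_tracer(ref_params, [-1.0, 1.0])
        with pytest.raises(ValidationError):
            simulate_tracer(ref_params, [1.0], dose_fraction=0.0)
        with pytest.raises(ValidationError):
            simulate_tracer(ref_params, [1.0], method="magic")

    def test_to_frame_shape(self, ref_params, sample_times):
        df = simulate_tracer(ref_params, sample_times).to_frame()
        # 8 components + 3 loss paths, one row per time each
        assert len(df) == 11 * sample_times.size
        assert set(df.columns) == {"time_d", "component", "fraction_of_dose"}


def _random_params(l54, l65, l56, l75, l57, l06, dt3):
    return assemble_parameters({
        "L(5,4)": l54, "L(6,5)": l65, "L(5,6)": l56, "L(7,5)": l75,
        "L(5,7)": l57, "L(0,6)": l06, "DT(3)": dt3,
    })


_rate = st.floats(min_value=1e-4, max_value=50.0, allow_nan=False)


class TestSimulationProperties:
    @settings(max_examples=25, deadline=None)
    @given(_rate, _rate, _rate, _rate, _rate, _rate,
           st.floats(min_value=0.01, max_value=1.0))
    def test_mass_conservation(self, l54, l65, l56, l75, l57, l06, dt3):
        p = _random_params(l54, l65, l56, l75, l57, l06, dt3)
        sol = simulate_tracer(p, np.array([0.1, 0.5, 1.0, 5.0, 20.0, 91.0]))
        np.testing.assert_allclose(sol.total(), 1.0, atol=1e-6)
        for c in sol.fd:
            assert np.all(sol.fd[c] >= 0)

    @settings(max_examples=25, deadline=None)
    @given(_rate, _rate, _rate, _rate, _rate, _rate,
           st.floats(min_value=0.01, max_value=1.0))
    def test_steady_state_flux_balance(self, l54, l65, l56, l75, l57, l06, dt3):
        p = _random_params(l54, l65, l56, l75, l57, l06, dt3)
        ss = solve_steady_state(p, m5=3.0)
        l = p.l
        m = ss.m
        # per-compartment |inflow - outflow| / inflow < 1e-9
        flows = {
            1: (ss.u1, (l[(2, 1)] + l[(0, 1)]) * m[1]),
            2: (l[(2, 1)] * m[1], (l[(3, 2)] + l[(5, 2)]) * m[2]),
            4: (l[(3, 2)] * m[2], l[(5, 4)] * m[4]),
            5: (l[(5, 4)] * m[4] + l[(5, 2)] * m[2]
                + l[(5, 6)] * m[6] + l[(5, 7)] * m[7],
                (l[(6, 5)] + l[(7, 5)] + l[(8, 5)]) * m[5]),
            6: (l[(6, 5)] * m[5], (l[(5, 6)] + l[(0, 6)]) * m[6]),
            7: (l[(7, 5)] * m[5], l[(5, 7)] * m[7]),
        }
        for c, (inflow, outflow) in flows.items():
            assert abs(inflow - outflow) / inflow < 1e-9, f"compartment {c}"


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------


class TestSteadyState:
    def test_reference_state(self, ref_ss):
        assert ref_ss.m[6] == pytest.approx(920.46, rel=1e-3)
        assert ref_ss.m[7] == pytest.approx(52.66, rel=1e-3)
        assert ref_ss.tbs == pytest.approx(973.0, rel=1e-3)
        assert ref_ss.r[(8, 5)] == pytest.approx(0.6515, rel=1e-3)
        assert ref_ss.r[(0, 6)] == pytest.approx(ref_ss.r[(8, 5)], rel=1e-9)
        assert ref_ss.dr == pytest.approx(1.303, rel=1e-3)
        assert ref_ss.u1 == pytest.approx(1.73687, rel=1e-3)

    def test_m7_symmetry(self, ref_params, ref_m5):
        # with L(7,5) = L(5,7), compartment 7 holds exactly M(5)
        p = ref_params.replace(**{"L(7,5)": 0.3, "L(5,7)": 0.3})
        ss = solve_steady_state(p, ref_m5)
        assert ss.m[7] == pytest.approx(ref_m5, rel=1e-12)

    def test_delay_masses(self, ref_params, ref_m5, ref_ss):
        assert ref_ss.m[3] == pytest.approx(ref_ss.r[(4, 3)] * ref_params.dt3, rel=1e-12)
        assert ref_ss.m[8] == pytest.approx(ref_ss.r[(8, 5)] * ref_params.dt8, rel=1e-12)

    def test_invalid_m5(self, ref_params):
        with pytest.raises(ValidationError):
            solve_steady_state(ref_params, 0.0)

    def test_no_exit_is_degenerate(self, ref_params):
        p = ref_params.replace(**{"L(5,7)": 0.0})
        with pytest.raises(DegenerateModelError):
            solve_steady_state(p, 3.362)

    def test_to_dict_keys(self, ref_ss):
        d = ref_ss.to_dict()
        for key in ("M(5)", "M(6)", "TBS", "DR", "U(1)", "R(8,5)", "R(0,6)"):
            assert key in d


# ---------------------------------------------------------------------------
# kinetic summaries
# ---------------------------------------------------------------------------


class TestKineticSummaries:
    def test_reference_values(self, ref_params, ref_ss):
        ks = compute_kinetic_summaries(ref_params, ref_ss)
        assert ks.transit_time_plasma_h == pytest.approx(24.0 / 10.17299, rel=1e-4)
        assert ks.plasma_visits == pytest.approx(26.25, rel=2e-3)
        assert ks.residence_time_plasma_d == pytest.approx(2.58, rel=2e-3)
        assert ks.fcr_percent_per_day == pytest.approx(0.1334, rel=2e-3)
        assert ks.store_half_life_d == pytest.approx(50.0 / 0.1334, rel=2e-3)
        assert ks.years_of_stores == pytest.approx(ref_ss.tbs / ref_ss.dr / 365.0,
                                                   rel=1e-12)
        assert ks.transit_time_plasma_h / 24.0 <= ks.residence_time_plasma_d
        assert all(v > 0 for v in ks.to_dict().values())

    def test_visits_match_markov_oracle(self, ref_params):
        oracle = markov_expected_plasma_visits(ref_params)
        p_return = plasma_return_probability(ref_params)
        assert 1.0 / (1.0 - p_return) == pytest.approx(oracle, rel=1e-10)

    def test_residence_matches_curve_integral(self, ref_params, ref_ss):
        # residence time = integral of fd5 over [0, inf) divided by the
        # fraction of dose ever reaching plasma (tail extrapolated with the
        # terminal exponential), within 1%
        ks = compute_kinetic_summaries(ref_params, ref_ss)
        grid = np.concatenate([default_time_grid(91.0),
                               np.linspace(92, 400, 400)])
        fdp = simulate_tracer(ref_params, grid).fdp
        area = np.trapezoid(fdp, grid)
        # terminal exponential tail beyond the grid
        slope = (np.log(fdp[-1]) - np.log(fdp[-10])) / (grid[-1] - grid[-10])
        area += fdp[-1] / (-slope)
        residence = area / ref_params.absorption_efficiency
        assert residence == pytest.approx(ks.residence_time_plasma_d, rel=0.01)

    def test_half_life_rules(self, ref_params, ref_ss):
        fifty = compute_kinetic_summaries(ref_params, ref_ss)
        ln2 = compute_kinetic_summaries(ref_params, ref_ss, half_life_rule="ln2")
        assert ln2.store_half_life_d == pytest.approx(
            fifty.store_half_life_d * 2.0 * np.log(2.0), rel=1e-12
        )
        with pytest.raises(ValidationError):
            compute_kinetic_summaries(ref_params, ref_ss, half_life_rule="nope")

    def test_no_irreversible_exit_errors(self, ref_params, ref_m5):
        ss = solve_steady_state(ref_params, ref_m5)
        p = ref_params.replace(constraint_mode=False, **{"L(0,6)": 0.0, "L(8,5)": 0.0})
        with pytest.raises(ModelStructureError):
            compute_kinetic_summaries(p, ss)
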