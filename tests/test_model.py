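"""Physics of the PAO cycle model: rate laws, balances, integration."""

import numpy as np
import pytest

from ebpr_gsa import model as M
from ebpr_gsa._kernel import _aux, _rhs
from ebpr_gsa.sampling import saltelli_design, transform

CARBON_ROWS = [1, 2, 4, 5, 6, 7, 8, 10]     # VFA, biomass, PHA, glycogen, CO2
PHOSPHORUS_ROWS = [3, 9]                    # PO4, poly-P


def params_from_row(matrix, i):
    return M.ModelParameters(matrix.values[i].copy())


class TestArrhenius:
    def test_reference_temperature_identity(self):
        assert M.arrhenius_correct(3.7, 1.08, 20.0) == pytest.approx(3.7)

    def test_unit_coefficient(self):
        assert M.arrhenius_correct(3.7, 1.0, 13.0) == pytest.approx(3.7)

    def test_ten_degree_correction(self):
        assert M.arrhenius_correct(1.0, 1.05, 30.0) == pytest.approx(1.6289, abs=1e-4)

    def test_positive_coefficient_required(self):
        with pytest.raises(ValueError):
            M.arrhenius_correct(1.0, 0.0, 25.0)


class TestPhYields:
    @pytest.mark.parametrize("source", ["HAc", "HPr"])
    def test_p_release_depends_on_ph(self, source):
        low = M.ph_yields(6.0, source)["p_release"]
        high = M.ph_yields(7.0, source)["p_release"]
        assert low != high

    def test_acetate_glycogen_stoichiometry_is_ph_independent(self):
        assert M.ph_yields(6.0, "HAc")["y_gly"] == M.ph_yields(7.5, "HAc")["y_gly"]

    def test_propionate_glycogen_stoichiometry_varies_with_ph(self):
        assert M.ph_yields(6.0, "HPr")["y_gly"] != M.ph_yields(7.5, "HPr")["y_gly"]

    @pytest.mark.parametrize("source", ["HAc", "HPr"])
    def test_yields_are_continuous_in_ph(self, source):
        for ph in np.linspace(6.0, 7.5 - 1e-6, 7):
            a = M.ph_yields(ph, source)
            b = M.ph_yields(ph + 1e-6, source)
            for key in ("alpha", "y_gly", "y_pha", "p_release"):
                assert abs(a[key] - b[key]) < 1e-4

    @pytest.mark.parametrize("source", ["HAc", "HPr"])
    def test_yield_carbon_balance(self, source):
        y = M.ph_yields(7.2, source)
        assert 1.0 + y["y_gly"] == pytest.approx(y["y_pha"] + y["co2"])

    def test_ph_outside_validated_domain_raises(self):
        with pytest.raises(ValueError):
            M.ph_yields(5.5, "HAc")
        with pytest.raises(ValueError):
            M.ph_yields(8.0, "HPr")


class TestRateLaws:
    def test_zero_biomass_zeroes_all_rates(self, midpoint_params, random_states):
        state = random_states[0].copy()
        state[4] = 0.0
        assert not M.anaerobic_rates(state, midpoint_params).any()

    def test_no_substrate_no_uptake_but_maintenance_continues(self, midpoint_params):
        state = np.array([0, 0, 0, 2.0, 4.0, 0.5, 0.2, 0.1, 1.5, 1.2, 0.0], float)
        rates = M.anaerobic_rates(state, midpoint_params)
        assert rates[0] == 0 and rates[1] == 0
        assert rates[2] > 0

    def test_uptake_proportional_to_biomass(self, midpoint_params):
        state = np.array([0, 1.0, 0.5, 2.0, 4.0, 0.5, 0.2, 0.1, 1.5, 1.2, 0.0], float)
        doubled = state.copy()
        doubled[4:10] *= 2.0             # same per-biomass composition
        r1 = M.anaerobic_rates(state, midpoint_params)
        r2 = M.anaerobic_rates(doubled, midpoint_params)
        np.testing.assert_allclose(r2[:3], 2.0 * r1[:3], rtol=1e-12)

    def test_negative_state_rejected(self, midpoint_params):
        state = np.array([0, -0.1, 0.5, 2.0, 4.0, 0.5, 0.2, 0.1, 1.5, 1.2, 0.0])
        with pytest.raises(ValueError):
            M.anaerobic_rates(state, midpoint_params)

    def test_no_pha_no_degradation(self, midpoint_params):
        state = np.array([0.2, 0, 0, 2.0, 4.0, 0, 0, 0, 1.5, 1.2, 0.0], float)
        rates = M.aerobic_rates(state, midpoint_params, vfa_gate=False)
        assert rates[5] == 0.0

    def test_polyp_formation_stops_at_maximum_fraction(self, midpoint_params):
        f_max = midpoint_params["f_PP_max"]
        state = np.array([0.2, 0, 0, 2.0, 4.0, 0.5, 0.2, 0.1, 1.5, f_max * 4.0, 0.0])
        rates = M.aerobic_rates(state, midpoint_params, vfa_gate=False)
        assert rates[7] == 0.0

    def test_closed_gate_blocks_aerobic_vfa_uptake(self, midpoint_params):
        state = np.array([0.2, 1.0, 0.5, 2.0, 4.0, 0.5, 0.2, 0.1, 1.5, 1.2, 0.0])
        closed = M.aerobic_rates(state, midpoint_params, vfa_gate=False)
        opened = M.aerobic_rates(state, midpoint_params, vfa_gate=True)
        assert closed[3] == 0.0 and closed[4] == 0.0
        assert opened[3] > 0.0 and opened[4] > 0.0


class TestStoichiometry:
    @pytest.mark.parametrize("state_idx", range(0, 200, 25))
    def test_every_process_balances_carbon_and_phosphorus(
        self, midpoint_params, random_states, state_idx
    ):
        S = M.stoichiometric_matrix(midpoint_params, random_states[state_idx])
        np.testing.assert_allclose(S[CARBON_ROWS].sum(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(S[PHOSPHORUS_ROWS].sum(axis=0), 0.0, atol=1e-9)

    def test_atp_closure_for_self_contained_processes(
        self, midpoint_params, random_states
    ):
        # columns whose ATP demand is met in-column (uptake, growth channel);
        # maintenance columns close only while reserves dwarf K_switch
        S = M.stoichiometric_matrix(midpoint_params, random_states[0])
        np.testing.assert_allclose(S[11, [0, 1, 3, 4, 5]], 0.0, atol=1e-9)
        np.testing.assert_allclose(S[11, [2, 8]], 0.0, atol=1e-3)

    def test_yield_entries_continuous_in_ph(self, midpoint_params, random_states):
        state = random_states[0]
        for ph in (6.0, 6.7, 7.4):
            a = M.stoichiometric_matrix(midpoint_params.replace(pH=ph), state)
            b = M.stoichiometric_matrix(midpoint_params.replace(pH=ph + 1e-6), state)
            assert np.max(np.abs(a - b)) < 1e-4


class TestFastKernelAgreesWithReference:
    """The compiled RHS is an independent hand-inlined formulation."""

    @pytest.mark.parametrize("aerobic,gate", [(False, False), (True, False), (True, True)])
    def test_rhs_matches_to_1e12(
        self, midpoint_params, constants, random_states, aerobic, gate
    ):
        p = midpoint_params.vector
        c = constants.vector()
        aux = _aux(p, c)
        dy = np.empty(11)
        for state in random_states:
            ref = M.reference_rhs(state, midpoint_params, aerobic, gate, constants)
            _rhs(state, p, c, aux, aerobic, gate, dy)
            np.testing.assert_allclose(dy, ref, rtol=1e-12, atol=1e-12)

    def test_rhs_matches_across_parameter_draws(
        self, random_matrix, constants, random_states
    ):
        c = constants.vector()
        dy = np.empty(11)
        for i in range(0, random_matrix.values.shape[0], 37):
            params = params_from_row(random_matrix, i)
            aux = _aux(params.vector, c)
            for state in random_states[:25]:
                ref = M.reference_rhs(state, params, True, False, constants)
                _rhs(state, params.vector, c, aux, True, False, dy)
                np.testing.assert_allclose(dy, ref, rtol=1e-12, atol=1e-12)

    def test_trajectory_matches_lsoda_reference(self, random_matrix):
        for i in (0, 11):
            params = params_from_row(random_matrix, i)
            fast = M.simulate_cycle(params, n_grid=61)
            ref = M.simulate_cycle(params, n_grid=61, method="lsoda")
            assert np.max(np.abs(fast.states - ref.states)) < 5e-4


class TestSimulateCycle:
    def test_zero_biomass_identity_trajectory(self, midpoint_params):
        # all biological pools stay at their initial values; only the
        # abiotic aeration term moves S_O2 toward saturation
        params = midpoint_params.replace(X_PAO_i=0.0)
        traj = M.simulate_cycle(params)
        np.testing.assert_array_equal(
            traj.states[:, 1:], traj.states[:1, 1:].repeat(301, 0)
        )
        np.testing.assert_array_equal(traj.states[:151, 0], 0.0)

    def test_phase_marker_switches_once_at_midpoint(self, midpoint_params):
        traj = M.simulate_cycle(midpoint_params)
        switches = np.flatnonzero(np.diff(traj.phase.astype(int)))
        assert switches.size == 1
        assert traj.times[switches[0] + 1] == pytest.approx(2.5)
        assert (np.diff(traj.times) > 0).all()

    def test_fig2_scenario_qualitative_profile(self, midpoint_params):
        traj = M.simulate_cycle(midpoint_params)
        mid = 150
        assert traj.component("S_HAc")[mid] < traj.component("S_HAc")[0]
        assert traj.component("S_HPr")[mid] < traj.component("S_HPr")[0]
        assert traj.component("S_PO4")[mid] > traj.component("S_PO4")[0]
        assert traj.component("S_PO4")[-1] < traj.component("S_PO4")[mid]
        assert traj.component("X_PAO")[-1] > traj.component("X_PAO")[mid]

    def test_anaerobic_biomass_exactly_constant(self, random_matrix):
        for i in range(0, random_matrix.values.shape[0], 29):
            traj = M.simulate_cycle(params_from_row(random_matrix, i))
            x = traj.component("X_PAO")[:151]
            assert np.max(np.abs(x - x[0])) == 0.0

    def test_mass_closure_and_nonnegativity(self, random_matrix):
        for i in range(0, random_matrix.values.shape[0], 29):
            traj = M.simulate_cycle(params_from_row(random_matrix, i))
            assert (traj.states >= 0.0).all()
            carbon = traj.states[:, CARBON_ROWS].sum(axis=1)
            assert np.max(np.abs(carbon - carbon[0])) < 1e-6 * carbon[0]
            phos = traj.states[:, PHOSPHORUS_ROWS].sum(axis=1)
            assert np.max(np.abs(phos - phos[0])) < 1e-6 * max(phos[0], 1.0)

    def test_aerobic_pha_nonincreasing_with_closed_gate(self, random_matrix):
        for i in range(0, random_matrix.values.shape[0], 29):
            traj = M.simulate_cycle(params_from_row(random_matrix, i))
            if traj.vfa_gate_open:
                continue
            pha = traj.states[150:, 5:8].sum(axis=1)
            assert (np.diff(pha) <= 1e-9).all()

    def test_negative_initial_state_rejected(self, midpoint_params):
        bad = M.initial_state(midpoint_params)
        bad[3] = -0.5
        with pytest.raises(ValueError):
            M.simulate_cycle(midpoint_params, initial=bad)

    def test_odd_grid_rejected(self, midpoint_params):
        with pytest.raises(ValueError):
            M.simulate_cycle(midpoint_params, n_grid=300)


def test_model_parameters_validation(midpoint_values):
    bad = dict(midpoint_values, q_HAc=-1.0)
    with pytest.raises(ValueError, match="q_HAc"):
        M.ModelParameters.from_dict(bad)
    bad = dict(midpoint_values, f_PP_max=1.5)
    with pytest.raises(ValueError, match="f_PP_max"):
        M.ModelParameters.from_dict(bad)
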