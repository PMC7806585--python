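"""Flow network: waveform, resistances, steady/transient solves, pressures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airwaysim import flow_network as fn
from airwaysim import morphometry as mm
from airwaysim import synthetic_data as sd
from conftest import two_outlet_table


class TestWaveform:
    def test_sedentary_peak_is_mean_times_half_pi(self):
        cycle = fn.BreathingCycle()
        assert cycle.peak_flow == pytest.approx(6.0 * math.pi / 2.0, rel=1e-12)
        assert fn.waveform_flow(cycle, 1.0) == pytest.approx(9.42, abs=5e-3)

    def test_zero_crossings_and_expiratory_peak(self):
        cycle = fn.BreathingCycle()
        assert fn.waveform_flow(cycle, 0.0) == 0.0
        assert fn.waveform_flow(cycle, 2.0) == pytest.approx(0.0, abs=1e-12)
        assert fn.waveform_flow(cycle, 3.0) == pytest.approx(-cycle.peak_flow, rel=1e-12)

    def test_waveform_integrates_to_zero_over_period(self):
        cycle = fn.BreathingCycle()
        ts = np.linspace(0, cycle.period_T, 40001)
        q = np.array([fn.waveform_flow(cycle, t) for t in ts])
        assert np.trapezoid(q, ts) == pytest.approx(0.0, abs=1e-9)

    def test_inhalation_mean_matches_configured_mean(self):
        """Time-average of |Q| over inhalation recovers the 6 L/min mean (analytic half-sine mean)."""
        cycle = fn.BreathingCycle()
        dt = 0.01
        ts = np.arange(0, cycle.period_T / 2 + dt / 2, dt)
        q = np.array([fn.waveform_flow(cycle, t) for t in ts])
        mean = np.trapezoid(q, ts) / (cycle.period_T / 2)
        assert mean == pytest.approx(6.0, rel=1e-3)


class TestResistanceAndReynolds:
    def test_tracheal_poiseuille_value(self):
        gas = fn.GasProperties()
        # direct arithmetic oracle: 128 * mu * L / (pi d^4)
        expected = 128.0 * 1.7894e-5 * 0.10 / (math.pi * 0.0156**4)
        got = fn.poiseuille_resistance(0.10, 0.0156, gas)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.231e3, rel=1e-3)

    @given(scale=st.floats(0.2, 5.0))
    @settings(max_examples=30, derandomize=True)
    def test_length_linearity_and_d4_law(self, scale):
        gas = fn.GasProperties()
        base = fn.poiseuille_resistance(0.1, 0.01, gas)
        assert fn.poiseuille_resistance(0.1 * scale, 0.01, gas) == pytest.approx(base * scale, rel=1e-12)
        assert fn.poiseuille_resistance(0.1, 0.005, gas) == pytest.approx(base * 16, rel=1e-12)

    def test_zero_diameter_rejected(self):
        with pytest.raises(fn.FlowDomainError):
            fn.poiseuille_resistance(0.1, 0.0, fn.GasProperties())

    def test_reynolds_circular_pipe(self):
        gas = fn.GasProperties()
        csa = math.pi * 0.5**2  # d = 1 cm
        assert fn.reynolds(0.0, csa, 1.0, gas) == 0.0
        # U = 1e-4 m^3/s / 7.854e-5 m^2; Re = rho U d / mu
        expected = 1.225 * (1e-4 / (csa * 1e-4)) * 0.01 / 1.7894e-5
        assert fn.reynolds(6.0, csa, 1.0, gas) == pytest.approx(expected, rel=1e-12)
        assert fn.reynolds(6.0, csa, 1.0, gas) == pytest.approx(872, abs=2)


class TestSolveSteady:
    def test_symmetric_tree_splits_exactly_in_half(self):
        tree = mm.build_tree(two_outlet_table())
        sol = fn.solve_steady(tree, 6.0)
        assert sol.branch_flow["b0"] == sol.branch_flow["b1"] == pytest.approx(3.0, rel=1e-12)

    def test_parallel_resistor_law(self):
        # same diameter, lengths 3 and 6 cm -> resistances R and 2R -> flows 2/3 and 1/3
        tree = mm.build_tree(two_outlet_table(l_a=3.0, l_b=6.0))
        sol = fn.solve_steady(tree, 6.0)
        assert sol.branch_flow["b0"] == pytest.approx(4.0, rel=1e-12)
        assert sol.branch_flow["b1"] == pytest.approx(2.0, rel=1e-12)

    def test_characteristic_tree_right_lung_share(self, characteristic_tree):
        sol = fn.solve_steady(characteristic_tree, 6.0)
        fr = fn.lobar_flow_fractions(characteristic_tree, sol)
        right = fr["RUL"] + fr["RML"] + fr["RLL"]
        assert right == pytest.approx(0.57, abs=0.01)

    def test_mass_conservation_on_characteristic_tree(self, characteristic_tree):
        sol = fn.solve_steady(characteristic_tree, 6.0)
        assert fn.mass_conservation_residual(characteristic_tree, sol) < 1e-10

    def test_lobar_fraction_mode_pins_the_configured_split(self, characteristic_tree):
        fractions = {"RUL": 0.19, "RML": 0.09, "RLL": 0.29, "LUL": 0.26, "LLL": 0.17}
        bc = fn.OutletBC(mode="lobar_fractions", fractions=fractions)
        sol = fn.solve_steady(characteristic_tree, 6.0, bc=bc)
        got = fn.lobar_flow_fractions(characteristic_tree, sol)
        for lobe, f in fractions.items():
            assert got[lobe] == pytest.approx(f, abs=1e-12)
        assert fn.mass_conservation_residual(characteristic_tree, sol) < 1e-10

    def test_negative_inflow_rejected(self, characteristic_tree):
        with pytest.raises(fn.FlowDomainError):
            fn.solve_steady(characteristic_tree, -1.0)

    def test_linearity_in_inlet_flow(self, characteristic_tree):
        losses = fn.LossModel(pedley=False, junction_K=0.0, larynx_K=0.0)
        s1 = fn.solve_steady(characteristic_tree, 3.0, losses=losses)
        s2 = fn.solve_steady(characteristic_tree, 6.0, losses=losses)
        for bid in characteristic_tree.branches:
            assert s2.branch_flow[bid] == pytest.approx(2 * s1.branch_flow[bid], rel=1e-12)
        for node in s1.node_pressure:
            assert s2.node_pressure[node] == pytest.approx(2 * s1.node_pressure[node], rel=1e-9, abs=1e-15)

    def test_dense_laplacian_oracle_small_network(self):
        """Node pressures and flows match an independent dense nodal solve on a 7-branch tree."""
        recipe = sd.TreeRecipe(mode="weibel_symmetric", max_generation=2, trachea=mm.TracheaSpec(length=5.0, diameter=1.0, posterior_cut_offset=0.3))
        table = sd.make_weibel_table(recipe)
        table.loc[table["id"] == "b0", "diameter_cm"] = 0.9  # break symmetry
        table.loc[table["id"] == "b01", "length_cm"] = 4.0
        tree = mm.build_tree(table)
        gas = fn.GasProperties()
        losses = fn.LossModel(pedley=False, junction_K=0.0, larynx_K=0.0)
        sol = fn.solve_steady(tree, 6.0, gas=gas, losses=losses)

        # independent oracle: dense Laplacian with Dirichlet 0 at the outlets
        ids = list(tree.branches)
        interior = ["inlet"] + [b for b in ids if tree.branches[b].child_ids]
        idx = {n: i for i, n in enumerate(interior)}
        n = len(interior)
        A = np.zeros((n, n))
        rhs = np.zeros(n)
        rhs[idx["inlet"]] = 6.0 * fn.LPM_TO_M3S
        for b in ids:
            seg = tree.branches[b]
            g = 1.0 / fn.poiseuille_resistance(seg.length * 1e-2, seg.diameter * 1e-2, gas)
            up = "inlet" if seg.parent_id is None else seg.parent_id
            down = b
            for a_, b_ in ((up, down),):
                ia = idx.get(a_)
                ib = idx.get(b_)
                if ia is not None:
                    A[ia, ia] += g
                if ib is not None:
                    A[ib, ib] += g
                if ia is not None and ib is not None:
                    A[ia, ib] -= g
                    A[ib, ia] -= g
        p = np.linalg.solve(A, rhs)
        # compare pressure drops from inlet and branch flows
        for b in ids:
            seg = tree.branches[b]
            up = "inlet" if seg.parent_id is None else seg.parent_id
            p_up = p[idx[up]]
            p_dn = p[idx[b]] if b in idx else 0.0
            g = 1.0 / fn.poiseuille_resistance(seg.length * 1e-2, seg.diameter * 1e-2, gas)
            q_oracle = (p_up - p_dn) * g / fn.LPM_TO_M3S
            assert sol.branch_flow[b] == pytest.approx(q_oracle, rel=1e-9)
            drop_model = sol.node_pressure["trachea_inlet" if up == "inlet" else up] - sol.node_pressure[b]
            assert drop_model == pytest.approx(p_up - p_dn, rel=1e-9, abs=1e-12)


class TestTransient:
    def test_snapshot_at_peak_equals_steady_peak_solve(self, characteristic_tree, transient_series):
        peak = next(s for s in transient_series if abs(s.time - 1.0) < 1e-9)
        steady = fn.solve_steady(characteristic_tree, fn.BreathingCycle().peak_flow, time=1.0)
        for bid in characteristic_tree.branches:
            assert peak.branch_flow[bid] == pytest.approx(steady.branch_flow[bid], rel=1e-12)

    def test_zero_crossing_snapshot_is_still(self, transient_series):
        mid = next(s for s in transient_series if abs(s.time - 2.0) < 1e-9)
        assert all(abs(q) < 1e-12 for q in mid.branch_flow.values())

    def test_inhalation_exhalation_sign_mirror(self, transient_series):
        by_time = {round(s.time, 6): s for s in transient_series}
        for t in (0.5, 1.0, 1.5):
            a, b = by_time[t], by_time[round(t + 2.0, 6)]
            for bid, q in a.branch_flow.items():
                assert b.branch_flow[bid] == pytest.approx(-q, rel=1e-9, abs=1e-12)

    def test_every_snapshot_conserves_mass(self, characteristic_tree, transient_series):
        worst = max(fn.mass_conservation_residual(characteristic_tree, s) for s in transient_series)
        assert worst < 1e-10

    def test_bad_dt_rejected(self, characteristic_tree):
        with pytest.raises(fn.FlowDomainError):
            fn.solve_transient(characteristic_tree, fn.BreathingCycle(), dt=0.3)
        with pytest.raises(fn.FlowDomainError):
            fn.solve_transient(characteristic_tree, fn.BreathingCycle(), dt=-0.01)


class TestPressure:
    def test_single_tube_poiseuille_identity(self, single_tube_table):
        tree = mm.build_tree(single_tube_table)
        gas = fn.GasProperties()
        losses = fn.LossModel(pedley=False, junction_K=0.0, larynx_K=0.0)
        sol = fn.solve_steady(tree, 6.0, gas=gas, losses=losses)
        R = fn.poiseuille_resistance(0.10, 0.0156, gas)
        assert fn.pressure_drop(sol, "trachea_inlet", "b") == pytest.approx(R * 6.0 * fn.LPM_TO_M3S, rel=1e-12)

    def test_zero_flow_snapshot_has_no_pressure_drop(self, transient_series):
        mid = next(s for s in transient_series if abs(s.time - 2.0) < 1e-9)
        nodes = list(mid.node_pressure)
        assert fn.pressure_drop(mid, nodes[0], nodes[-1]) == pytest.approx(0.0, abs=1e-12)

    def test_unknown_node_rejected(self, transient_series):
        with pytest.raises(fn.FlowStructureError):
            fn.pressure_drop(transient_series[0], "mouth", "not_a_node")

    def test_mouth_is_zero_reference(self, characteristic_tree):
        sol = fn.solve_steady(characteristic_tree, 6.0)
        assert sol.node_pressure["mouth"] == 0.0

    def test_glottis_reynolds_on_scaled_upper_airway(self, characteristic_tree):
        re_peak = fn.glottis_reynolds(characteristic_tree, fn.BreathingCycle().peak_flow)
        re_mean = fn.glottis_reynolds(characteristic_tree, 6.0)
        assert re_peak == pytest.approx(re_mean * math.pi / 2.0, rel=1e-12)
        assert 1000 < re_peak < 2300  # laminar / quasi-transitional regime
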