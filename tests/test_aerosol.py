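"""Transport numbers, deposition correlations, and bolus transport ledgers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airwaysim import aerosol as ae
from airwaysim import flow_network as fn
from airwaysim import morphometry as mm
from airwaysim import synthetic_data as sd
from conftest import two_outlet_table


class TestStokesNumber:
    def test_direct_arithmetic(self):
        p = ae.ParticleSpec(diameter_dp=7.0)
        gas = fn.GasProperties()
        expected = 998.2 * (7e-6) ** 2 * 1.0 / (36 * 1.7894e-5 * 0.0078)
        assert ae.stokes_number(p, 1.0, 0.0078, gas) == pytest.approx(expected, rel=1e-12)
        assert ae.stokes_number(p, 1.0, 0.0078, gas) == pytest.approx(9.73e-3, rel=1e-3)

    def test_zero_size_and_linearity_in_velocity(self):
        gas = fn.GasProperties()
        assert ae.stokes_number(ae.ParticleSpec(diameter_dp=0.0), 1.0, 0.01, gas) == 0.0
        p = ae.ParticleSpec(diameter_dp=10.0)
        assert ae.stokes_number(p, 2.0, 0.01, gas) == pytest.approx(2 * ae.stokes_number(p, 1.0, 0.01, gas), rel=1e-12)

    def test_zero_radius_rejected(self):
        with pytest.raises(ae.AerosolDomainError):
            ae.stokes_number(ae.ParticleSpec(), 1.0, 0.0)


class TestImpactionParameter:
    def test_conventional_units(self):
        p = ae.ParticleSpec(diameter_dp=7.0, density_rho_p=998.2)
        assert ae.impaction_parameter(p, 6.0) == pytest.approx(0.9982 * 49 * 6, rel=1e-12)
        assert ae.impaction_parameter(p, 6.0) == pytest.approx(293.5, abs=0.1)
        assert ae.impaction_parameter(p, 0.0) == 0.0

    @given(dp=st.floats(0.5, 30.0))
    @settings(max_examples=30, derandomize=True)
    def test_quadratic_in_diameter(self, dp):
        p1 = ae.ParticleSpec(diameter_dp=dp)
        p2 = ae.ParticleSpec(diameter_dp=2 * dp)
        assert ae.impaction_parameter(p2, 6.0) == pytest.approx(4 * ae.impaction_parameter(p1, 6.0), rel=1e-12)


class TestCorrelations:
    def test_stokes_form_analytic_identities(self):
        corr = ae.DECorrelation("bif1", "stokes_exp", a=1.0, b=1.0)
        assert ae.de_stokes(0.0, corr) == 0.0
        assert ae.de_stokes(math.log(2.0), corr) == pytest.approx(0.5, rel=1e-12)
        assert ae.de_stokes(1e9, corr) == pytest.approx(1.0, abs=1e-12)

    def test_ip_form_analytic_identities(self):
        corr = ae.DECorrelation("oral", "ip_exp", a=2.0)
        assert ae.de_ip(0.0, corr) == 0.0
        assert ae.de_ip(math.log(2.0) / 2.0, corr) == pytest.approx(0.5, rel=1e-12)

    def test_wrong_form_rejected(self):
        st_corr = ae.DECorrelation("bif1", "stokes_exp", a=1.0, b=1.0)
        ip_corr = ae.DECorrelation("oral", "ip_exp", a=1.0)
        with pytest.raises(ae.CorrelationError):
            ae.de_stokes(1.0, ip_corr)
        with pytest.raises(ae.CorrelationError):
            ae.de_ip(1.0, st_corr)

    @given(st1=st.floats(0, 5), st2=st.floats(0, 5), a=st.floats(0.01, 5), b=st.floats(0.3, 3))
    @settings(max_examples=60, derandomize=True)
    def test_monotone_and_bounded(self, st1, st2, a, b):
        corr = ae.DECorrelation("bif2", "stokes_exp", a=a, b=b)
        lo, hi = sorted((st1, st2))
        assert 0.0 <= ae.de_stokes(lo, corr) <= ae.de_stokes(hi, corr) <= 1.0


def _steady_series(tree, Q=6.0, T=4.0, dt=0.01, losses=None):
    sol = fn.solve_steady(tree, Q, losses=losses)
    n = int(round(T / dt))
    return [fn.FlowSolution(i * dt, sol.branch_flow, sol.branch_velocity, sol.branch_reynolds, sol.node_pressure) for i in range(n + 1)]


class TestTransport:
    def test_single_tube_deposited_fraction_matches_correlation_closed_form(self, single_tube_table):
        """One region, steady flow: the ledger reproduces the correlation exactly."""
        tree = mm.build_tree(single_tube_table)
        series = _steady_series(tree)
        p = ae.ParticleSpec(diameter_dp=10.0)
        corr = ae.DECorrelation("trachea", "stokes_exp", a=2.0, b=1.1)
        corrs = {"trachea": corr}
        rec = ae.transport(tree, series, ae.InjectionSet(t_inj=0.0), p, corrs)
        U = abs(series[0].branch_velocity["b"])
        St = ae.stokes_number(p, U, tree.branches["b"].radius * 1e-2)
        expected = ae.de_stokes(St, corr)
        assert rec.deposited["trachea"] == pytest.approx(expected, rel=1e-12)
        assert rec.escaped["RLL"] == pytest.approx(1.0 - expected, rel=1e-12)
        assert rec.conservation_residual() < 1e-12

    def test_zero_size_limit_is_pure_escape(self, characteristic_tree, correlations, transient_series):
        p = ae.ParticleSpec(diameter_dp=0.0)
        rec = ae.transport(tree=characteristic_tree, flow_series=transient_series, injection=ae.InjectionSet(t_inj=0.4), p=p, correlations=correlations)
        assert ae.total_DE(rec) == 0.0
        assert rec.total_escaped + rec.suspended == pytest.approx(1.0, abs=1e-9)

    def test_ledger_conservation(self, characteristic_tree, correlations, transient_series):
        for t_inj in (0.0, 0.8, 1.6):
            rec = ae.transport(characteristic_tree, transient_series, ae.InjectionSet(t_inj=t_inj), ae.ParticleSpec(), correlations)
            assert rec.conservation_residual() < 1e-9

    def test_missing_correlation_rejected(self, characteristic_tree, correlations, transient_series):
        incomplete = {k: v for k, v in correlations.items() if k != "bif2"}
        with pytest.raises(ae.CorrelationError):
            ae.transport(characteristic_tree, transient_series, ae.InjectionSet(), ae.ParticleSpec(), incomplete)

    def test_larynx_filtering_grows_with_particle_size(self, characteristic_tree, correlations, transient_series):
        des = []
        for size in (3.0, 7.0, 10.0, 25.0):
            rec = ae.transport(characteristic_tree, transient_series, ae.InjectionSet(t_inj=0.8), ae.ParticleSpec(diameter_dp=size), correlations)
            des.append(ae.regional_DE(rec, "larynx"))
        assert des == sorted(des)
        assert des[0] < des[-1]

    def test_total_de_monotone_in_size_and_flow(self, characteristic_tree, correlations):
        by_size = []
        for size in (3.0, 7.0, 10.0, 25.0):
            series = _steady_series(characteristic_tree, Q=6.0)
            rec = ae.transport(characteristic_tree, series, ae.InjectionSet(t_inj=0.0), ae.ParticleSpec(diameter_dp=size), correlations)
            by_size.append(ae.total_DE(rec))
        assert by_size == sorted(by_size)
        by_flow = []
        for Q in (3.0, 6.0, 9.0):
            series = _steady_series(characteristic_tree, Q=Q)
            rec = ae.transport(characteristic_tree, series, ae.InjectionSet(t_inj=0.0), ae.ParticleSpec(diameter_dp=7.0), correlations)
            by_flow.append(ae.total_DE(rec))
        assert by_flow == sorted(by_flow)

    def test_routing_matches_outlet_flow_fractions_without_deposition(self, characteristic_tree):
        """With deposition disabled, per-lobe escape equals each lobe's share of outlet flow."""
        zero = {r: ae.DECorrelation(r, "ip_exp" if r in ("oral", "pharynx", "larynx") else "stokes_exp", a=0.0, b=1.0) for r in mm.REGIONS}
        series = _steady_series(characteristic_tree)
        rec = ae.transport(characteristic_tree, series, ae.InjectionSet(t_inj=0.0), ae.ParticleSpec(), zero)
        fr = fn.lobar_flow_fractions(characteristic_tree, series[0])
        assert rec.suspended == pytest.approx(0.0, abs=1e-9)
        for lobe, f in fr.items():
            assert rec.escaped[lobe] == pytest.approx(f, abs=1e-9)

    def test_mc_mode_reproducible_and_converges_to_deterministic(self, characteristic_tree, correlations, transient_series):
        inj = sd.make_injection(2720, 2.16, 0.8, seed=7)
        p = ae.ParticleSpec(diameter_dp=7.0)
        det = ae.transport(characteristic_tree, transient_series, inj, p, correlations)
        mc1 = ae.transport(characteristic_tree, transient_series, inj, p, correlations, mode="mc")
        mc2 = ae.transport(characteristic_tree, transient_series, inj, p, correlations, mode="mc")
        assert mc1.deposited == mc2.deposited and mc1.escaped == mc2.escaped and mc1.suspended == mc2.suspended
        p_tot = ae.total_DE(det)
        se = math.sqrt(p_tot * (1 - p_tot) / inj.n_particles)
        assert abs(ae.total_DE(mc1) - p_tot) <= 3 * se
        assert mc1.conservation_residual() < 1e-9
        assert len(mc1.fates) == inj.n_particles

    def test_symmetric_tree_mirror_equality(self, weibel_tree, correlations):
        """Left/right mirror symmetry of flow and deposition on the symmetric fixture."""
        series = _steady_series(weibel_tree)
        sol = series[0]
        for bid, q in sol.branch_flow.items():
            if bid.startswith("b") and len(bid) > 1 and all(c in "01" for c in bid[1:]):
                mirror = "b" + "".join("1" if c == "0" else "0" for c in bid[1:])
                assert abs(q - sol.branch_flow[mirror]) <= 1e-12 * max(abs(q), 1e-30)
        rec = ae.transport(weibel_tree, series, ae.InjectionSet(t_inj=0.0), ae.ParticleSpec(diameter_dp=7.0), correlations)
        right = rec.escaped["RUL"] + rec.escaped["RML"] + rec.escaped["RLL"]
        left = rec.escaped["LUL"] + rec.escaped["LLL"]
        assert abs(right - left) < 1e-12


class TestRegionalDE:
    def test_ratio_definition(self):
        rec = ae.DepositionRecord(deposited={"bif1": 0.05}, per_region_entering={"bif1": 1.0})
        assert ae.regional_DE(rec, "bif1") == pytest.approx(0.05)

    def test_unvisited_region_is_not_applicable(self):
        rec = ae.DepositionRecord(deposited={}, per_region_entering={})
        assert ae.regional_DE(rec, "bif3") is None

    def test_total_de_is_sum_of_deposited_fractions(self, characteristic_tree, correlations, transient_series):
        rec = ae.transport(characteristic_tree, transient_series, ae.InjectionSet(t_inj=0.8), ae.ParticleSpec(), correlations)
        assert ae.total_DE(rec) == pytest.approx(sum(rec.deposited.values()), rel=1e-12)


class TestSweepAndComparison:
    def test_default_grid_has_ten_injection_times(self):
        times = ae.default_injection_times()
        assert times == pytest.approx([0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8])

    def test_exhalation_injection_rejected(self, characteristic_tree, correlations, cycle):
        with pytest.raises(ae.AerosolDomainError):
            ae.injection_sweep(characteristic_tree, cycle, ae.ParticleSpec(), correlations, times=[2.5])

    def test_zero_deposition_sweep_is_all_zero(self, characteristic_tree, cycle, transient_series):
        zero = {r: ae.DECorrelation(r, "ip_exp" if r in ("oral", "pharynx", "larynx") else "stokes_exp", a=0.0, b=1.0) for r in mm.REGIONS}
        sweep = ae.injection_sweep(characteristic_tree, cycle, ae.ParticleSpec(), zero, times=[0.0, 0.8], flow_series=transient_series)
        assert all(ae.total_DE(rec) == 0.0 for _, rec in sweep)

    def test_late_injections_leave_more_suspended(self, characteristic_tree, correlations, cycle, transient_series):
        sweep = dict(ae.injection_sweep(characteristic_tree, cycle, ae.ParticleSpec(diameter_dp=7.0), correlations, flow_series=transient_series))
        early = sweep[0.0].suspended
        for t in (1.4, 1.6, 1.8):
            assert sweep[t].suspended > early

    def test_transient_cycle_de_at_least_steady(self, characteristic_tree, correlations, cycle):
        comp = ae.steady_vs_transient(characteristic_tree, cycle, ae.ParticleSpec(diameter_dp=7.0), correlations)
        assert comp["transient"]["total_DE_cycle_mean"] >= comp["steady"]["total_DE"]
        assert comp["transient"]["total_DE_best"] >= comp["steady"]["total_DE"]

    def test_degenerate_constant_cycle_consistency(self, characteristic_tree, correlations):
        """With a constant waveform the 'transient' run must equal the steady one."""
        series = _steady_series(characteristic_tree, Q=6.0)
        p = ae.ParticleSpec(diameter_dp=7.0)
        rec_a = ae.transport(characteristic_tree, series, ae.InjectionSet(t_inj=0.0), p, correlations)
        rec_b = ae.transport(characteristic_tree, series, ae.InjectionSet(t_inj=0.0), p, correlations)
        assert ae.total_DE(rec_a) == pytest.approx(ae.total_DE(rec_b), abs=1e-12)
        steady_st = ae.entry_transport_numbers(characteristic_tree, series[0], p)
        peak_sol = fn.solve_steady(characteristic_tree, fn.BreathingCycle().peak_flow)
        peak_st = ae.entry_transport_numbers(characteristic_tree, peak_sol, p)
        for region in ("bif1", "bif2", "bif3", "peripheral"):
            assert peak_st[region] == pytest.approx(steady_st[region] * math.pi / 2.0, rel=1e-9)
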