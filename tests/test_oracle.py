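"""Reduced-order hemodynamic oracle: pressure, WSS, auxiliary channels."""

import numpy as np
import pytest

from conftest import make_tube
from coa_surrogate.errors import ParameterError
from coa_surrogate.geometry import BranchSpec, FlowBC, assign_flow_profile
from coa_surrogate.oracle import (
    FluidProperties,
    HemodynamicProfile,
    OracleConfig,
    compute_aux_channels,
    compute_wss,
    solve_case,
    solve_pressure,
)
from coa_surrogate.units import MMHG_PA, MM_M

INVISCID = FluidProperties(density=1060.0, viscosity=0.0)
LOSS_FREE = OracleConfig(bc_loss_coeff=0.0, gothic_loss_coeff=0.0)


def hand_bernoulli(geometry, bc, density=1060.0):
    """Independent Bernoulli calculator: p = 120 - rho/2 (v^2 - v0^2)."""
    f = assign_flow_profile(bc.inlet_flow, geometry.branches, geometry.n_points)
    v = f / (np.pi * (geometry.radius * MM_M) ** 2)
    return 120.0 - 0.5 * density * (v**2 - v[0] ** 2) / MMHG_PA


class TestPressure:
    def test_constant_radius_inviscid_is_flat_120(self, flow_bc):
        geom = make_tube(length=120.0)
        p = solve_pressure(geom, flow_bc, INVISCID, LOSS_FREE)
        assert np.allclose(p, 120.0)

    def test_matches_hand_bernoulli_on_20_random_cases(self):
        # oracle equivalence for the inviscid, loss-free configuration
        rng = np.random.default_rng(2024)
        for _ in range(20):
            geom = make_tube(
                length=float(rng.uniform(80, 300)),
                radius=float(rng.uniform(8, 12)),
                severity=float(rng.uniform(0.0, 0.6)),
                stenosis_width=int(rng.integers(5, 11)),
            )
            bc = FlowBC(inlet_flow=float(rng.uniform(200e-6, 400e-6)))
            p = solve_pressure(geom, bc, INVISCID, LOSS_FREE)
            assert np.max(np.abs(p - hand_bernoulli(geom, bc))) < 1e-9

    def test_severity_half_throat_deficit(self, flow_bc):
        # r_t = r_0/2 so v_t = 4 v_0 and the inviscid no-recovery-loss
        # deficit at the throat is 0.5*rho*15*v0^2 / 133.322 mmHg
        geom = make_tube(length=160.0, radius=10.0, severity=0.5)
        p = solve_pressure(geom, flow_bc, INVISCID, LOSS_FREE)
        v0 = flow_bc.inlet_flow / (np.pi * (10.0 * MM_M) ** 2)
        expected = 0.5 * 1060.0 * 15.0 * v0**2 / MMHG_PA
        i_t = geom.stenosis_index
        assert abs((120.0 - p[i_t]) - expected) < 1e-9

    def test_doubling_flow_quadruples_pd(self):
        # with viscosity off every remaining loss is proportional to v^2
        geom = make_tube(length=160.0, severity=0.5)
        pd = {}
        for q in (200e-6, 400e-6):
            p = solve_pressure(geom, FlowBC(inlet_flow=q), INVISCID)
            pd[q] = p[0] - p[-1]
        assert pd[400e-6] == pytest.approx(4.0 * pd[200e-6], rel=0.01)

    def test_non_negative_dissipation(self):
        # recovery coefficient < 1: inlet-outlet PD >= 0 for stenotic,
        # non-expanding geometries
        for sev in (0.0, 0.2, 0.4, 0.6):
            geom = make_tube(length=200.0, severity=sev)
            p = solve_pressure(geom, FlowBC(inlet_flow=350e-6))
            assert p[0] - p[-1] >= -1e-12

    def test_throat_pressure_minimum_within_stenosis(self):
        geom = make_tube(length=200.0, severity=0.4, stenosis_width=8)
        p = solve_pressure(geom, FlowBC(inlet_flow=300e-6))
        i_min = int(np.argmin(p))
        assert abs(i_min - geom.stenosis_index) <= 8

    def test_viscous_loss_accumulates_monotonically(self, flow_bc):
        geom = make_tube(length=200.0)
        p = solve_pressure(geom, flow_bc)  # default viscous fluid
        assert np.all(np.diff(p[1:]) <= 1e-12)
        assert p[-1] < 120.0

    def test_gothic_arch_carries_excess_pd(self):
        from coa_surrogate.geometry import sample_cohort

        # same seed and ranges, gothic vs non-gothic stratification
        g_gothic = sample_cohort(1, seed=21, gothic_fraction=1.0)[0]
        g_flat = sample_cohort(1, seed=21, gothic_fraction=0.0)[0]
        pd = []
        for geom, bc in (g_gothic, g_flat):
            p = solve_pressure(geom, bc)
            pd.append(p[0] - p[-1])
        assert pd[0] > pd[1]

    def test_inlet_always_exactly_120(self):
        geom = make_tube(length=150.0, severity=0.3)
        p = solve_pressure(geom, FlowBC(inlet_flow=250e-6))
        assert p[0] == 120.0


class TestWss:
    def test_poiseuille_formula(self, flow_bc):
        geom = make_tube(length=100.0, radius=10.0)
        f = np.full(geom.n_points, flow_bc.inlet_flow)
        wss = compute_wss(geom, f)
        v = flow_bc.inlet_flow / (np.pi * (10.0 * MM_M) ** 2)
        assert np.allclose(wss, 4.0 * 3.5e-3 * v / (10.0 * MM_M))

    def test_maximal_at_throat(self, flow_bc):
        geom = make_tube(length=160.0, severity=0.5)
        f = np.full(geom.n_points, flow_bc.inlet_flow)
        wss = compute_wss(geom, f)
        assert int(np.argmax(wss)) == geom.stenosis_index


class TestAuxChannels:
    def test_ke_definition(self, flow_bc):
        geom = make_tube(length=100.0)
        f = np.full(geom.n_points, flow_bc.inlet_flow)
        aux = compute_aux_channels(geom, f)
        assert np.allclose(aux["ke"], 500.0 * aux["v_avg"] ** 2)

    def test_ke_unit_velocity(self):
        # v_avg = 1 m/s -> ke = 500 mJ/kg: pick flow = pi r^2 * 1
        r = 10.0
        q = np.pi * (r * MM_M) ** 2
        geom = make_tube(length=100.0, radius=r)
        aux = compute_aux_channels(geom, np.full(geom.n_points, q))
        assert np.allclose(aux["v_avg"], 1.0)
        assert np.allclose(aux["ke"], 500.0)

    def test_velocity_profile_factor(self):
        geom = make_tube(length=100.0)
        f = np.full(geom.n_points, 300e-6)
        aux = compute_aux_channels(geom, f, config=OracleConfig(velocity_profile_factor=2.0))
        assert np.allclose(aux["v_max"], 2.0 * aux["v_avg"])

    def test_healthy_straight_tube_has_zero_sfd_tke(self, flow_bc):
        geom = make_tube(length=100.0)
        aux = compute_aux_channels(geom, np.full(geom.n_points, flow_bc.inlet_flow))
        assert np.allclose(aux["sfd"], 0.0)
        assert np.allclose(aux["tke_avg"], 0.0)
        assert np.allclose(aux["tke_max"], 0.0)

    def test_stenosis_generates_downstream_tke(self, flow_bc):
        geom = make_tube(length=200.0, severity=0.5)
        aux = compute_aux_channels(geom, np.full(geom.n_points, flow_bc.inlet_flow))
        i_t = geom.stenosis_index
        assert aux["tke_avg"][: i_t - 10].max() == 0.0
        assert aux["tke_avg"][i_t:].max() > 0.0
        assert np.all(aux["tke_max"] >= aux["tke_avg"])


class TestSolveCase:
    def test_profile_invariants_hold_for_generated_cohort(self, small_cohort_solved):
        for geom, bc, prof in small_cohort_solved:
            assert prof.n_points == geom.n_points
            assert prof.pressure[0] == 120.0
            assert np.all(prof.wss >= 0)
            assert np.all(prof.v_max >= prof.v_avg)
            mat = prof.as_matrix()
            assert mat.shape == (geom.n_points, 8)
            assert np.array_equal(mat[:, 0], prof.pressure)

    def test_noise_is_seeded_and_off_by_default(self, flow_bc):
        geom = make_tube(length=120.0, severity=0.3)
        a = solve_case(geom, flow_bc)
        b = solve_case(geom, flow_bc)
        assert np.array_equal(a.pressure, b.pressure)
        noisy_cfg = OracleConfig(noise_sd=0.5, noise_seed=4)
        n1 = solve_case(geom, flow_bc, config=noisy_cfg)
        n2 = solve_case(geom, flow_bc, config=noisy_cfg)
        assert np.array_equal(n1.pressure, n2.pressure)
        assert not np.array_equal(n1.pressure, a.pressure)
        assert n1.pressure[0] == 120.0  # anchor survives the noise

    def test_profile_validation(self):
        n = 20
        ok = dict(
            pressure=np.full(n, 120.0),
            wss=np.zeros(n),
            sfd=np.zeros(n),
            ke=np.zeros(n),
            tke_avg=np.zeros(n),
            tke_max=np.zeros(n),
            v_avg=np.zeros(n),
            v_max=np.zeros(n),
        )
        HemodynamicProfile(**ok)
        bad = dict(ok, pressure=np.full(n, 119.0))
        with pytest.raises(ParameterError):
            HemodynamicProfile(**bad)
        bad = dict(ok, v_avg=np.full(n, 2.0))  # v_max < v_avg
        with pytest.raises(ParameterError):
            HemodynamicProfile(**bad)
        bad = dict(ok, wss=np.full(n, -1.0))
        with pytest.raises(ParameterError):
            HemodynamicProfile(**bad)

    def test_branches_reduce_downstream_losses(self):
        # draining 30% of the flow on the arch lowers descending velocity
        # and hence the total viscous PD relative to the branchless tube
        bc = FlowBC(inlet_flow=300e-6)
        plain = make_tube(length=200.0)
        pts_n = plain.n_points
        branched = make_tube(
            length=200.0,
            branches=[BranchSpec(20, 0.1), BranchSpec(30, 0.1), BranchSpec(40, 0.1)],
        )
        p0 = solve_pressure(plain, bc)
        p1 = solve_pressure(branched, bc)
        assert p1[-1] > p0[-1]
        assert pts_n == branched.n_points
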