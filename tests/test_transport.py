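import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from carposim.errors import StateError
from carposim.transport import (
    CompartmentState,
    CrackModel,
    TransportParams,
    TransportSystem,
    VesselBoundary,
    assemble_rhs,
    crack_area_total,
    crack_fraction,
    init_state,
    integrate,
    osmotic_pressure,
    saturation_vapor_concentration,
    sugar_concentration,
    sugar_fluxes,
    transpiration,
    water_flux,
)
from carposim.vascular import ContactAreaMap


PARAMS = TransportParams()
BOUNDARY = VesselBoundary(psi_stem=-2.2, S_p=0.2)


class TestSugarConcentration:
    def test_zero_sugar(self):
        assert sugar_concentration(0.0, 5.0, 0.52) == 0.0

    def test_direct_value(self):
        assert sugar_concentration(10.0, 90.0, 0.52) == pytest.approx(5.2 / 95.2)

    def test_symmetry_at_beta_one(self):
        assert sugar_concentration(3.0, 3.0, 1.0) == pytest.approx(0.5)

    def test_rejects_nonpositive_water(self):
        with pytest.raises(ValueError):
            sugar_concentration(1.0, 0.0, 0.52)

    @given(st.floats(0, 100), st.floats(0.01, 100), st.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_bounded_below_beta_in_physical_regime(self, s, w, beta):
        # the S < beta bound holds whenever the water holds the dry matter
        # in solution, i.e. w > (1 - beta) * s
        assume((1 - beta) * s < 0.99 * w)
        S = sugar_concentration(s, w, beta)
        assert 0 <= S < beta


class TestOsmoticPressure:
    def test_no_sugar_gives_base(self):
        assert osmotic_pressure(0.0, 5.0, PARAMS) == pytest.approx(5.0)

    def test_phloem_value(self):
        # S=0.2 at 293.15 K adds ~14.2 bar of sugar osmotic pressure
        pi = osmotic_pressure(0.2, 5.0, PARAMS)
        assert pi == pytest.approx(5 + 83 * 293.15 * 0.2 / 342.3, rel=1e-12)
        assert pi == pytest.approx(19.22, abs=0.01)

    def test_flesh_value(self):
        assert osmotic_pressure(0.02, 5.0, PARAMS) == pytest.approx(6.42, abs=0.01)


class TestWaterFlux:
    def test_equal_potentials_no_flow(self):
        assert water_flux(1.0, 0.01, 2.0, 2.0, 1.0, 1.0) == 0.0

    def test_direct_value(self):
        assert water_flux(1.0, 0.01, 2.0, 1.0, 0.0, 0.0, sigma=1.0) == pytest.approx(0.01)

    def test_antisymmetric_under_swap(self):
        f = water_flux(2.0, 0.01, 2.0, 1.0, 3.0, 1.5, sigma=0.7)
        g = water_flux(2.0, 0.01, 1.0, 2.0, 1.5, 3.0, sigma=0.7)
        assert f == -g


class TestCrackLaw:
    A, B, LAM = 5.396, 0.635, 0.41

    def test_no_cracks_at_initial_mass(self):
        assert crack_area_total(60.0, self.A, self.B, self.LAM) == 0.0

    def test_continuity_at_threshold(self):
        X_thr = self.A ** (1 / self.LAM)
        assert crack_area_total(X_thr, self.A, self.B, self.LAM) == pytest.approx(0.0, abs=1e-9)
        assert crack_area_total(X_thr * 1.001, self.A, self.B, self.LAM) < 0.2

    def test_final_mass_coverage(self):
        assert crack_area_total(222.3, self.A, self.B, self.LAM) == pytest.approx(8.4, abs=0.1)

    def test_monotone_nondecreasing(self):
        X = np.linspace(20, 400, 300)
        C = crack_area_total(X, self.A, self.B, self.LAM)
        assert np.all(np.diff(C) >= 0)

    def test_rejects_bad_params(self):
        with pytest.raises(ValueError):
            crack_area_total(60.0, -1.0, self.B, self.LAM)


class TestCrackFraction:
    def test_uniform_case(self):
        z = np.full(5, 10.0)
        A = np.full(5, 2.0)
        c = crack_fraction(z, A, 7.6)
        assert np.allclose(c, 0.076)

    def test_zero_coverage(self):
        assert np.all(crack_fraction(np.array([5.0, 1.0]), np.ones(2), 0.0) == 0)

    def test_two_tet_example(self):
        c = crack_fraction(np.array([20.0, 0.0]), np.ones(2), 7.6)
        assert np.allclose(c, [0.152, 0.0])

    def test_area_weighted_mean_equals_coverage(self):
        rng = np.random.default_rng(0)
        z = rng.uniform(0, 20, 30)
        A = rng.uniform(0.1, 1.0, 30)
        c = crack_fraction(z, A, 5.0)
        assert np.average(c, weights=A) == pytest.approx(0.05)

    def test_degenerate_distribution(self):
        with pytest.raises(ValueError):
            crack_fraction(np.zeros(3), np.ones(3), 5.0)


class TestTranspiration:
    def test_equal_humidity_no_loss(self):
        p = TransportParams(H_f=0.7, H_air=0.7)
        assert transpiration(1.0, 0.0, p) == 0.0

    def test_uncracked_value(self):
        p = TransportParams(rho_ext=22.0, alpha=1.727e-5, H_f=0.996, H_air=0.7)
        assert transpiration(1.0, 0.0, p) == pytest.approx(1.125e-4, rel=1e-3)

    def test_crack_ratio(self):
        p = TransportParams(rho_ext=432.0, rho_crk=3838.0)
        assert transpiration(1.0, 1.0, p) / transpiration(1.0, 0.0, p) == pytest.approx(
            3838.0 / 432.0
        )

    def test_tetens_alpha_at_20C(self):
        assert saturation_vapor_concentration(293.15) == pytest.approx(1.73e-5, rel=0.01)

    def test_invalid_crack_fraction(self):
        with pytest.raises(ValueError):
            transpiration(1.0, 1.5, PARAMS)


class TestSugarFluxes:
    def test_no_vessels_no_active_or_diffusive_transport(self):
        p = TransportParams(sigma_p=0.9, nu_max=1e-3, k_diff=1e-3)
        V_m, V_a, V_d = sugar_fluxes(0.02, 0.0, 0.5, BOUNDARY, p)
        assert V_a == 0.0 and V_d == 0.0

    def test_impermeable_membrane_blocks_bulk_flow(self):
        p = TransportParams(sigma_p=1.0)
        V_m, _, _ = sugar_fluxes(0.02, 1.0, 5.0, BOUNDARY, p)
        assert V_m == 0.0

    def test_bulk_flow_value(self):
        p = TransportParams(sigma_p=0.9)
        bd = VesselBoundary(psi_stem=-6.0, S_p=0.18)
        V_m, _, _ = sugar_fluxes(0.05, 1.0, 0.1, bd, p)
        assert V_m == pytest.approx(0.1 * 0.1 * 0.18)

    def test_backflow_carries_local_concentration(self):
        p = TransportParams(sigma_p=0.5)
        V_m, _, _ = sugar_fluxes(0.04, 1.0, -2.0, BOUNDARY, p)
        assert V_m == pytest.approx(0.5 * (-2.0) * 0.04)


class TestInitState:
    def test_zero_sugar(self, sphere_mesh):
        st_ = init_state(sphere_mesh, 0.0, 1.0, PARAMS)
        assert np.all(st_.s == 0)
        assert np.allclose(st_.w, sphere_mesh.volumes * PARAMS.D_w)

    def test_constraints_hold_exactly(self, sphere_mesh):
        st_ = init_state(sphere_mesh, 0.02, 1.0, PARAMS)
        assert np.allclose(st_.v, sphere_mesh.volumes, rtol=1e-12)
        assert np.allclose(st_.S, 0.02, rtol=1e-12)

    def test_infeasible_concentration(self, sphere_mesh):
        with pytest.raises(ValueError):
            init_state(sphere_mesh, 0.6, 1.0, TransportParams(beta=0.52))


class TestAssembledRhs:
    def _contact(self, mesh, value=0.0, seed=None):
        n = mesh.n_tets
        if seed is None:
            A = np.full(n, value)
        else:
            A = np.random.default_rng(seed).uniform(0, 0.05, n)
        return ContactAreaMap.from_areas(A, A.copy(), mesh.total_area)

    def test_isolated_compartment_only_respires(self, sphere_mesh):
        p = TransportParams(L=0.0, rho_ext=0.0)
        st_ = init_state(sphere_mesh, 0.02, 1.0, p)
        dw, ds, dP = assemble_rhs(
            st_, sphere_mesh, self._contact(sphere_mesh), BOUNDARY, p
        )
        assert np.all(dw == 0)
        assert np.allclose(ds, -p.q_m() * st_.s / (1 + p.q_g))

    def test_identical_neighbors_exchange_nothing(self, two_tet_mesh):
        p = TransportParams(L=1e-2, rho_ext=0.0)
        st_ = init_state(two_tet_mesh, 0.02, 1.0, p)
        st_.w[:] = st_.w.mean()
        st_.s[:] = st_.s.mean()
        dw, _, _ = assemble_rhs(
            st_, two_tet_mesh, self._contact(two_tet_mesh), BOUNDARY, p
        )
        assert np.allclose(dw, 0.0, atol=1e-15)

    def test_global_water_budget_closes(self, two_tissue_mesh):
        p = TransportParams(L=1e-3)
        st_ = init_state(two_tissue_mesh, 0.02, 1.0, p)
        rng = np.random.default_rng(4)
        st_.P += rng.normal(scale=0.2, size=len(st_.P))
        contact = self._contact(two_tissue_mesh, seed=11)
        dw, _, _ = assemble_rhs(st_, two_tissue_mesh, contact, BOUNDARY, p)
        sys_ = TransportSystem(two_tissue_mesh, contact, BOUNDARY, p)
        rep = sys_.flux_report(st_)
        boundary_net = rep.U_x.sum() + rep.U_p.sum() - rep.T.sum()
        assert dw.sum() == pytest.approx(boundary_net, rel=1e-10)
        # internal exchanges cancel pairwise
        assert rep.U_neigh.sum() == pytest.approx(0.0, abs=1e-12 * np.abs(rep.U_neigh).max())

    def test_rejects_nan_state(self, two_tet_mesh):
        st_ = init_state(two_tet_mesh, 0.02, 1.0, PARAMS)
        st_.w[0] = np.nan
        with pytest.raises(StateError):
            assemble_rhs(st_, two_tet_mesh, self._contact(two_tet_mesh), BOUNDARY, PARAMS)


class TestIntegrate:
    def test_equilibrium_state_is_constant(self, sphere_mesh):
        p = TransportParams(L=0, L_x=0, L_p=0, rho_ext=0, q_m_ref=0, nu_max=0)
        st0 = init_state(sphere_mesh, 0.02, 1.0, p)
        contact = ContactAreaMap.from_areas(
            np.zeros(sphere_mesh.n_tets), np.zeros(sphere_mesh.n_tets),
            sphere_mesh.total_area,
        )
        traj = integrate(st0, sphere_mesh, contact, BOUNDARY, p, (0, 24), dt_geom=6)
        assert np.allclose(traj.w[-1], traj.w[0], rtol=1e-8)
        assert np.allclose(traj.s[-1], traj.s[0], rtol=1e-8)

    def test_crack_model_drains_more_water(self, sphere_mesh):
        p = TransportParams(L=0, L_x=0, L_p=0, nu_max=0, rho_ext=40.0, rho_crk=400.0)
        st0 = init_state(sphere_mesh, 0.02, 1.0, p)
        n = sphere_mesh.n_tets
        contact = ContactAreaMap.from_areas(
            np.zeros(n), np.zeros(n), sphere_mesh.total_area
        )
        ext = sphere_mesh.ext_area > 0
        crack = CrackModel(z=np.where(ext, 10.0, 0.0), a=1.0, b=2.0, lam=0.5)
        base = integrate(st0, sphere_mesh, contact, BOUNDARY, p, (0, 6), dt_geom=6)
        cracked = integrate(
            st0, sphere_mesh, contact, BOUNDARY, p, (0, 6), dt_geom=6, crack=crack
        )
        assert cracked.total_water[-1] < base.total_water[-1]
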