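import numpy as np
import pytest

from aortamech.datasets import RunConfig, SilicoArtery
from aortamech.hgo import PrincipalStretches, isochoric_stress
from aortamech.thickwall import (add_measurement_noise, pressure_sweep,
                                 reaction_stress_at, reduced_axial_force,
                                 residual_stress_parameter, silico_load_fraction,
                                 solve_inner_radius, stress_free_sector,
                                 transmural_gradient, transmural_profile)


def brute_force_wall(artery, state, n=20001):
    """Independent dense-trapezoid evaluation of all wall integrals.

    Re-derives the kinematics from the state's sector geometry and computes
    the luminal pressure, the reaction stress at mid-wall, the reduced axial
    force and the load-fraction integrals on a 20,001-point grid.
    """
    rho = np.linspace(state.rho_i, state.rho_o, n)
    if state.everted:
        r = np.sqrt(state.ri**2 + (state.rho_o**2 - rho**2) / (state.k * state.lam_z))
    else:
        r = np.sqrt(state.ri**2 + (rho**2 - state.rho_i**2) / (state.k * state.lam_z))
    lam_th = state.k * r / rho
    s = isochoric_stress(PrincipalStretches.plane(lam_th, state.lam_z),
                         artery.c, artery.k1, artery.k2, artery.beta)
    diff = s.iso_theta + s.aniso_theta - s.iso_r
    w = diff * rho / (state.k * state.lam_z * r**2)
    P = np.trapezoid(w, rho)
    # reaction stress at mid-wall: accumulate from the lumen side
    from scipy.integrate import cumulative_trapezoid
    accum = cumulative_trapezoid(w, rho, initial=0.0)
    if state.everted:
        accum = accum[-1] - accum
    r_mid = state.ri + 0.5 * state.h
    order = np.argsort(r)
    p_mid = np.interp(r_mid, r[order], (state.P + s.iso_r - accum)[order])
    fred = (np.pi * np.trapezoid(
        (2 * (s.iso_z + s.aniso_z) - (s.iso_theta + s.aniso_theta) - s.iso_r)
        * rho, rho) / (state.k * state.lam_z)) / 1000.0
    jac = rho / (state.k * state.lam_z * r)
    frac_th = (np.trapezoid(s.aniso_theta * jac, rho)
               / np.trapezoid((s.iso_theta + s.aniso_theta) * jac, rho))
    return {"P": P, "p_mid": p_mid, "fred": fred, "frac_th": frac_th}


class TestResidualStressParameter:
    def test_closed_ring(self):
        assert residual_stress_parameter(0.0, "full") == pytest.approx(1.0)
        assert residual_stress_parameter(0.0, "half") == pytest.approx(1.0)

    def test_half_convention_arithmetic(self):
        assert residual_stress_parameter(96.0, "half") == pytest.approx(360 / 264)

    def test_full_convention_and_eversion_sign(self):
        assert residual_stress_parameter(96.0, "full") == pytest.approx(180 / 84)
        # beyond 180 deg the ring everts: k is negative under 'full'
        assert residual_stress_parameter(335.0, "full") == pytest.approx(-180 / 155)

    def test_flat_strip_singular(self):
        with pytest.raises(ValueError):
            residual_stress_parameter(180.0, "full")

    def test_angle_range_checked(self):
        with pytest.raises(ValueError):
            residual_stress_parameter(400.0)


class TestSolveInnerRadius:
    def test_stress_free_reference_is_equilibrium(self, config):
        artery = SilicoArtery(set_id="x", group="cs", R=5.0, H=1.0, Phi0=0.0,
                              c=10.0, k1=5.0, k2=1.0, beta=40.0, lam=1.0,
                              Fred_mean_ref=0.0)
        state = solve_inner_radius(artery, 0.0, config)
        assert state.ri == pytest.approx(5.0, abs=1e-9)
        assert state.h == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_oracle(self, arteries, config):
        a = arteries["15"]
        state = solve_inner_radius(a, 13.3, config)
        oracle = brute_force_wall(a, state)
        # at the solved radius, the 20,001-point quadrature must return P
        assert oracle["P"] == pytest.approx(13.3, abs=1e-6)

    def test_radius_increases_with_pressure(self, sweeps):
        series, _ = sweeps["15"]
        assert np.all(np.diff(series.ri) > 0)

    def test_wall_thins_with_pressure(self, sweeps):
        series, _ = sweeps["15"]
        assert np.all(np.diff(series.h) < 0)


class TestQuadratureOracles:
    @pytest.mark.parametrize("set_id", ["4", "12", "15"])
    def test_gauss_matches_dense_trapezoid(self, arteries, sweeps, config, set_id):
        """Adaptive-order Gauss vs 20,001-point trapezoid on three sets."""
        a = arteries[set_id]
        state = sweeps[set_id][1][50]  # a mid-sweep pressure level
        oracle = brute_force_wall(a, state)
        assert oracle["P"] == pytest.approx(state.P, rel=1e-6)
        p_mid = reaction_stress_at(state, a, state.r_mid, config)
        assert p_mid == pytest.approx(oracle["p_mid"], rel=1e-6, abs=1e-6)
        assert reduced_axial_force(state, a, config) == pytest.approx(
            oracle["fred"], rel=1e-6, abs=1e-4)
        assert silico_load_fraction(state, a, "theta", config) == pytest.approx(
            oracle["frac_th"], rel=1e-6)


class TestTransmuralProfile:
    def test_stress_free_state_has_zero_stress(self, config):
        artery = SilicoArtery(set_id="x", group="cs", R=5.0, H=1.0, Phi0=0.0,
                              c=10.0, k1=5.0, k2=1.0, beta=40.0, lam=1.0,
                              Fred_mean_ref=0.0)
        prof = transmural_profile(solve_inner_radius(artery, 0.0, config),
                                  artery, config)
        assert np.allclose(prof.reaction_p, 20.0, atol=1e-8)  # p = 2c, sigma = 0
        assert np.allclose(prof.total_theta, 0.0, atol=1e-8)
        assert np.allclose(prof.sigma_rr, 0.0, atol=1e-8)

    def test_radial_stress_boundary_conditions(self, arteries, sweeps, config):
        for sid in ("4", "15"):
            for state in sweeps[sid][1][::25]:
                prof = transmural_profile(state, arteries[sid], config)
                assert prof.sigma_rr[0] == pytest.approx(-state.P, abs=1e-9)
                assert abs(prof.sigma_rr[-1]) < 1e-4 * max(state.P, 1.0)

    def test_grid_ordered_lumen_first(self, arteries, sweeps, config):
        for sid in ("3", "15"):  # everted and normal sector
            state = sweeps[sid][1][-1]
            prof = transmural_profile(state, arteries[sid], config)
            assert np.all(np.diff(prof.r_grid) > 0)
            assert prof.r_grid[0] == pytest.approx(state.ri)
            assert prof.r_grid[-1] == pytest.approx(state.ro)

    def test_incompressibility_pointwise(self, arteries, sweeps):
        state = sweeps["15"][1][-1]
        rho = np.linspace(state.rho_i, state.rho_o, 101)
        r = state.radius_at(rho)
        lam_th = state.k * r / rho
        s = PrincipalStretches.plane(lam_th, state.lam_z)
        assert np.allclose(s.lam_r * s.lam_th * s.lam_z, 1.0, atol=1e-12)

    def test_high_gradient_signature_increases_outward(self, arteries, sweeps, config):
        """A strongly residually stressed set loads its outer wall most."""
        state = sweeps["4"][1][-1]
        prof = transmural_profile(state, arteries["4"], config)
        assert transmural_gradient(prof, "theta") > 100.0
        assert prof.total_theta[-1] > prof.total_theta[0]

    def test_gradient_of_uniform_profile_is_zero(self, arteries, sweeps, config):
        prof = transmural_profile(sweeps["15"][1][-1], arteries["15"], config)
        prof.total_theta = np.full_like(prof.total_theta, 50.0)
        assert transmural_gradient(prof, "theta") == 0.0


class TestThinWallLimit:
    def test_laplace_law_recovered(self, config):
        """For H/R = 1e-3 the mid-wall hoop stress is the Laplace value."""
        artery = SilicoArtery(set_id="thin", group="cs", R=5.0, H=0.005,
                              Phi0=0.0, c=2.0e5, k1=1e-3, k2=0.1, beta=45.0,
                              lam=1.0, Fred_mean_ref=0.0)
        cfg = config.with_(n_levels=5)
        _, states = pressure_sweep(artery, cfg)
        for state in states:
            prof = transmural_profile(state, artery, cfg)
            mid = np.interp(state.r_mid, prof.r_grid, prof.total_theta)
            laplace = (state.ri / state.h + 0.5) * state.P
            assert mid == pytest.approx(laplace, rel=5e-3)


class TestLoadFraction:
    def test_no_collagen_means_zero(self, config):
        artery = SilicoArtery(set_id="x", group="cs", R=5.0, H=1.0, Phi0=40.0,
                              c=80.0, k1=1e-9, k2=1.0, beta=40.0, lam=1.05,
                              Fred_mean_ref=0.0)
        state = solve_inner_radius(artery, 13.3, config)
        assert silico_load_fraction(state, artery, "theta", config) < 1e-8

    def test_fraction_decreases_with_matrix_stiffness(self, config):
        base = dict(set_id="x", group="cs", R=5.0, H=1.0, Phi0=40.0,
                    k1=20.0, k2=2.0, beta=40.0, lam=1.05, Fred_mean_ref=0.0)
        fractions = []
        for c in (5.0, 20.0, 80.0):
            artery = SilicoArtery(c=c, **base)
            state = solve_inner_radius(artery, 13.3, config)
            fractions.append(silico_load_fraction(state, artery, "theta", config))
        assert fractions[0] > fractions[1] > fractions[2]

    def test_bounded_for_tensile_states(self, arteries, sweeps, config):
        for sid in ("15", "18"):
            state = sweeps[sid][1][-1]
            for d in ("theta", "z"):
                frac = silico_load_fraction(state, arteries[sid], d, config)
                assert 0.0 <= frac <= 1.0


class TestMeasurementNoise:
    def test_zero_sd_is_identity(self, sweeps):
        series = sweeps["15"][0]
        noisy = add_measurement_noise(series, 0.0, seed=1)
        assert np.array_equal(noisy.ri, series.ri)
        assert np.array_equal(noisy.h, series.h)

    def test_same_seed_reproduces(self, sweeps):
        series = sweeps["15"][0]
        a = add_measurement_noise(series, 0.05, seed=7)
        b = add_measurement_noise(series, 0.05, seed=7)
        assert np.array_equal(a.ri, b.ri)

    def test_sample_sd_near_nominal(self, sweeps):
        series = sweeps["15"][0]
        noisy = add_measurement_noise(series, 0.05, seed=11)
        sd = np.std(noisy.ri - series.ri)
        assert 0.035 < sd < 0.065  # within 30% of 0.05 at n = 101

    def test_wall_area_conserved(self, sweeps):
        """h is recomputed so the cross-section area is untouched by noise."""
        series = sweeps["15"][0]
        noisy = add_measurement_noise(series, 0.05, seed=3)
        area = series.h * (2 * series.ri + series.h)
        area_n = noisy.h * (2 * noisy.ri + noisy.h)
        assert np.allclose(area, area_n, rtol=1e-12)

    def test_negative_sd_rejected(self, sweeps):
        with pytest.raises(ValueError):
            add_measurement_noise(sweeps["15"][0], -0.1, seed=0)


def test_unloaded_ring_is_self_equilibrated(arteries, config):
    """The recovered sector closes back to the tabulated ring at zero load."""
    from aortamech.thickwall import _kappa_everted, _luminal_pressure
    for sid in ("3", "15", "18"):
        a = arteries[sid]
        kappa, everted = _kappa_everted(a, config)
        rho_i, rho_o = stress_free_sector(a, config)
        residual = _luminal_pressure(a.R, rho_i, rho_o, kappa, 1.0, everted,
                                     a, config.n_quad)
        assert abs(residual) < 1e-9
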