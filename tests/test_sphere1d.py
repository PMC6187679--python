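import numpy as np
import pytest

from spherotrap.sphere1d import (SphereProblem, first_order_profile,
                                 hypoxia_radius, solve_mm_sphere,
                                 zeroth_order_profile)

# reference problem: 100 µm radius, tumor-tissue oxygen constants
P0 = dict(radius=100e-6, K_tissue=1.83e-9, Vmax=0.0203, c_surface=0.5)


class TestZerothOrder:
    def test_center_value_closed_form(self):
        """c(0) = c_s − Vmax R²/(6K) = 0.4815 mM for the reference problem."""
        prof = zeroth_order_profile(SphereProblem(Km=0.0, **P0))
        assert prof.center_value() == pytest.approx(0.48151, abs=1e-4)

    def test_no_consumption_is_flat(self):
        p = SphereProblem(radius=100e-6, K_tissue=1.83e-9, Vmax=0.0,
                          Km=0.0, c_surface=0.5)
        prof = zeroth_order_profile(p)
        assert np.allclose(prof.c_mM, 0.5)

    def test_anoxic_core_appears_below_critical_supply(self):
        R, K, V = 100e-6, 1.83e-9, 0.0203
        crit = V * R * R / (6 * K)
        above = zeroth_order_profile(
            SphereProblem(radius=R, K_tissue=K, Vmax=V, Km=0.0,
                          c_surface=1.01 * crit))
        below = zeroth_order_profile(
            SphereProblem(radius=R, K_tissue=K, Vmax=V, Km=0.0,
                          c_surface=0.8 * crit))
        assert above.anoxic_radius_m == 0.0
        assert below.anoxic_radius_m > 0.0
        assert below.c_mM[0] == 0.0
        # surface value is honoured in both regimes
        assert below.c_mM[-1] == pytest.approx(0.8 * crit, rel=1e-9)


class TestMichaelisMentenSphere:
    def test_matches_zeroth_order_for_tiny_km(self):
        num = solve_mm_sphere(SphereProblem(Km=1e-6, **P0), 256)
        ref = zeroth_order_profile(SphereProblem(Km=0.0, **P0))
        assert num.center_value() == pytest.approx(ref.center_value(),
                                                   rel=0.01)

    def test_matches_first_order_for_large_km(self):
        km = 50.0
        p = SphereProblem(radius=100e-6, K_tissue=1.83e-9,
                          Vmax=4.385 * km * 1e-3, Km=km, c_surface=0.5)
        num = solve_mm_sphere(p, 512)
        ref = first_order_profile(p, 512)
        assert np.max(np.abs(num.c_mM - ref.c_mM)) / 0.5 < 0.005

    def test_grid_convergence(self):
        p = SphereProblem(Km=1e-6, **P0)
        a = solve_mm_sphere(p, 256).center_value()
        b = solve_mm_sphere(p, 512).center_value()
        assert abs(b - a) / b < 1e-3

    def test_profile_monotone_in_radius(self):
        prof = solve_mm_sphere(SphereProblem(Km=0.00463, **P0))
        assert (np.diff(prof.c_mM) >= -1e-12).all()

    def test_requires_enough_nodes(self):
        with pytest.raises(ValueError):
            solve_mm_sphere(SphereProblem(Km=0.00463, **P0), 8)

    def test_center_value_parameter_monotonicity(self):
        """c(0) rises with c_s and K, falls with Vmax and R."""
        base = SphereProblem(radius=100e-6, K_tissue=1.83e-9, Vmax=0.0203,
                             Km=0.00463, c_surface=0.5)
        c_base = solve_mm_sphere(base, 128).center_value()

        def c0(**kw):
            d = dict(radius=base.radius, K_tissue=base.K_tissue,
                     Vmax=base.Vmax, Km=base.Km, c_surface=base.c_surface)
            d.update(kw)
            return solve_mm_sphere(SphereProblem(**d), 128).center_value()

        assert c0(c_surface=0.6) > c_base
        assert c0(K_tissue=2.6e-9) > c_base
        assert c0(Vmax=0.03) < c_base
        assert c0(radius=130e-6) < c_base


class TestHypoxiaRadius:
    def test_threshold_above_profile_maximum(self):
        prof = zeroth_order_profile(SphereProblem(Km=0.0, **P0))
        assert hypoxia_radius(prof, 0.49) < prof.problem.radius
        assert hypoxia_radius(prof, prof.c_mM[0] - 1e-9) is None

    def test_threshold_at_surface_returns_radius(self):
        prof = zeroth_order_profile(SphereProblem(Km=0.0, **P0))
        assert hypoxia_radius(prof, 0.5) == pytest.approx(100e-6)

    def test_matches_analytic_root_of_quadratic(self):
        p = SphereProblem(Km=0.0, **P0)
        prof = zeroth_order_profile(p, 2001)
        thr = 0.49
        # c(r) = c_s − V(R²−r²)/6K  =>  r = sqrt(R² − 6K(c_s−thr)/V)
        r_exact = np.sqrt(p.radius ** 2
                          - 6 * p.K_tissue * (p.c_surface - thr) / p.Vmax)
        assert hypoxia_radius(prof, thr) == pytest.approx(r_exact, rel=1e-4)

    def test_nonmonotone_profile_rejected(self):
        prof = zeroth_order_profile(SphereProblem(Km=0.0, **P0))
        prof.c_mM[50] = 1.0
        with pytest.raises(ValueError):
            hypoxia_radius(prof, 0.49)


def test_3d_solver_cross_check_against_1d_sphere(bath_coarse_mesh):
    """A spheroid suspended in quiescent medium with a pinned surface
    concentration: the angular average of the 3D field matches the 1D
    spherical solution within 3%."""
    from spherotrap.transport import oxygen_spec, solve_steady

    mesh = bath_coarse_mesh
    cfg = mesh.config
    w_surf = 0.15
    spec = oxygen_spec(w_surf)
    fld = solve_steady(mesh, None, spec, surface_dirichlet=w_surf)
    # the Dirichlet surface lives on the stair-step interface: compare the 1D
    # model at the discrete sphere's effective radius
    centre_v = np.array(cfg.spheroid_center) * 1e-6
    surf = mesh.vertices[mesh.vertex_set("spheroid_interface")]
    r_eff = float(np.linalg.norm(surf - centre_v, axis=1).mean())
    # in the medium-equivalent variable the tissue problem has effective
    # diffusivity K·S and half-saturation Km/S
    prob = SphereProblem(radius=r_eff,
                         K_tissue=spec.K_tissue * spec.S_tissue,
                         Vmax=spec.Vmax, Km=spec.Km / spec.S_tissue,
                         c_surface=w_surf)
    ref = solve_mm_sphere(prob, 512)
    centre = centre_v
    rng = np.random.default_rng(11)
    for r_frac in (0.3, 0.6, 0.85):
        r = r_frac * prob.radius
        dirs = rng.normal(size=(400, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        pts = centre + r * dirs
        w3d = fld.transformed_at(pts)
        avg = np.nanmean(w3d)
        ref_c = np.interp(r, ref.r_m, ref.c_mM)
        assert avg == pytest.approx(ref_c, rel=0.03)
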