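import numpy as np
import pytest

from spherotrap import constants as C
from spherotrap.geometry import DOMAIN_SPHEROID, build_trap_geometry, default_config
from spherotrap.meshing import generate_mesh
from spherotrap.flow import solve_flow
from spherotrap.transport import (centerline_profile, glucose_spec,
                                  mismatch_percent, mm_rate, oxygen_spec,
                                  solve_steady, solve_transient_noflow)


class TestMichaelisMenten:
    def test_half_saturation_gives_half_vmax(self):
        assert mm_rate(0.00463, 0.0203, 0.00463) == pytest.approx(0.01015)

    def test_zero_concentration_zero_rate(self):
        assert mm_rate(0.0, 0.0203, 0.00463) == 0.0

    def test_saturation_limit(self):
        km = 0.00463
        assert mm_rate(100 * km, 0.0203, km) == pytest.approx(0.9901 * 0.0203,
                                                              rel=1e-3)

    def test_monotone_increasing(self):
        c = np.linspace(0, 1, 101)
        r = mm_rate(c, 0.0203, 0.00463)
        assert (np.diff(r) > 0).all()

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            mm_rate(-0.1, 0.0203, 0.00463)


class TestSpecies:
    def test_glucose_excluded_from_pdms(self):
        assert glucose_spec().pdms_permeable is False

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            oxygen_spec(quiescent_threshold=0.01, necrotic_threshold=0.02)

    def test_tissue_diffusivity_ratio(self):
        """Glucose diffuses ~7x slower than oxygen through tumor tissue."""
        ratio = C.K_GLC_TISSUE / C.K_O2_TISSUE
        assert ratio == pytest.approx(0.1475, abs=0.01)


def test_no_consumption_means_uniform_concentration(u500_test_mesh):
    """With Vmax = 0 and uniform supply the balance has the constant solution."""
    spec = glucose_spec(5.0, Vmax=0.0)
    fld = solve_steady(u500_test_mesh, None, spec)
    assert np.allclose(fld.w, 5.0, rtol=1e-9)


def test_oxygen_minimum_at_spheroid_bottom(u500_test_mesh, u500_test_flow):
    fld = solve_steady(u500_test_mesh, u500_test_flow, oxygen_spec(0.2))
    xod, c = centerline_profile(fld, u500_test_mesh.config)
    assert xod[np.argmin(c)] < 0.1
    # profile is asymmetric about the sphere centre
    assert abs(c[0] - c[-1]) > 0.05 * c.max()


def test_glucose_minimum_above_channel_floor(u500_test_mesh, u500_test_flow):
    """Glucose diffuses slowly in tissue: the depleted core floats above
    the floor instead of hugging it."""
    fld = solve_steady(u500_test_mesh, u500_test_flow, glucose_spec(11.0))
    xod, c = centerline_profile(fld, u500_test_mesh.config)
    assert 0.05 < xod[np.argmin(c)] < 0.6


def test_transformed_field_respects_maximum_principle(u500_test_mesh,
                                                      u500_test_flow):
    for spec in (oxygen_spec(0.2), glucose_spec(11.0)):
        fld = solve_steady(u500_test_mesh, u500_test_flow, spec)
        # bounds hold up to the streamline-diffusion overshoot at the inflow
        # corner, ~1% at this resolution and shrinking under refinement
        assert fld.w.min() >= -1e-3 * spec.c0_inlet
        assert fld.w.max() <= 1.02 * spec.c0_inlet


def test_native_concentration_jump_across_interface(u500_test_mesh,
                                                    u500_test_flow):
    """Native tissue O2 is S_tissue x the medium-equivalent level."""
    fld = solve_steady(u500_test_mesh, u500_test_flow, oxygen_spec(0.2))
    cfg = u500_test_mesh.config
    centre = np.array([[cfg.spheroid_center[0] * 1e-6,
                        cfg.spheroid_center[1] * 1e-6,
                        cfg.spheroid_center[2] * 1e-6]])
    w = fld.transformed_at(centre)[0]
    native = fld.native_at(centre)[0]
    assert native == pytest.approx(C.S_O2_TISSUE * w, rel=1e-12)


def test_clamp_mask_empty_when_supply_is_ample(u500_test_mesh, u500_test_flow):
    fld = solve_steady(u500_test_mesh, u500_test_flow, glucose_spec(11.0))
    assert fld.clamp_mask.sum() == 0


def test_clamped_volume_decreases_with_inlet_concentration(u500_test_mesh,
                                                           u500_test_flow):
    vols = []
    for c0 in (0.7, 1.5):
        fld = solve_steady(u500_test_mesh, u500_test_flow, glucose_spec(c0))
        vols.append(fld.space.vols[fld.clamp_mask].sum())
    assert vols[0] >= vols[1]


class TestMismatchPercent:
    def test_uniform_profile(self):
        assert mismatch_percent(np.full(10, 3.3)) == 0.0

    def test_two_point_profile(self):
        assert mismatch_percent(np.array([1.0, 0.5])) == pytest.approx(50.0)

    def test_min_referenced_variant(self):
        assert mismatch_percent(np.array([1.0, 0.5]),
                                reference="min") == pytest.approx(100.0)

    def test_zero_profile_rejected(self):
        with pytest.raises(ValueError):
            mismatch_percent(np.zeros(5))


def test_centerline_profile_spans_the_sphere(u500_test_mesh, u500_test_flow):
    fld = solve_steady(u500_test_mesh, u500_test_flow, oxygen_spec(0.2))
    xod, c = centerline_profile(fld, u500_test_mesh.config)
    assert xod[0] == pytest.approx(0.0, abs=0.02)
    assert xod[-1] == pytest.approx(1.0, abs=0.02)
    assert np.isfinite(c).all()


class TestTransient:
    def test_conserved_without_consumption(self, u500_test_mesh):
        spec = glucose_spec(5.0, Vmax=0.0)
        init = solve_steady(u500_test_mesh, None, spec)
        tr = solve_transient_noflow(u500_test_mesh, init, spec,
                                    t_end=600.0, dt=120.0)
        assert np.allclose(tr.spheroid_avg_mM, tr.spheroid_avg_mM[0],
                           rtol=1e-9)

    def test_average_nonincreasing_and_mass_audit(self, u500_test_mesh,
                                                  u500_test_flow):
        spec = glucose_spec(11.0)
        init = solve_steady(u500_test_mesh, u500_test_flow, spec)
        tr = solve_transient_noflow(u500_test_mesh, init, spec,
                                    t_end=1800.0, dt=120.0)
        assert (np.diff(tr.spheroid_avg_mM) <= 1e-12).all()
        lost = tr.total_mass_mol[0] - tr.total_mass_mol[-1]
        assert lost == pytest.approx(tr.consumed_mol[-1], rel=0.01)

    def test_large_spheroids_deplete_much_faster(self):
        drops = {}
        for D in (200, 500):
            cfg = default_config("integrated_u", D)
            mesh = generate_mesh(build_trap_geometry(cfg), "test")
            fl = solve_flow(mesh, 5.0, mode="stokes")
            spec = glucose_spec(11.0)
            init = solve_steady(mesh, fl, spec)
            tr = solve_transient_noflow(mesh, init, spec,
                                        t_end=3600.0, dt=180.0)
            drops[D] = tr.spheroid_avg_mM[0] - tr.spheroid_avg_mM[-1]
        assert drops[500] > 3.0 * drops[200]

    def test_rejects_bad_timestep(self, u500_test_mesh):
        spec = glucose_spec(5.0, Vmax=0.0)
        init = solve_steady(u500_test_mesh, None, spec)
        with pytest.raises(ValueError):
            solve_transient_noflow(u500_test_mesh, init, spec,
                                   t_end=10.0, dt=-1.0)
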