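"""Wall-shear-stress metric family and segment averaging."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import hemoturb as ht
from hemoturb.wss import compute_metric_maps, wss_from_near_wall_gradient

from conftest import flat_patch_surface

RHO, NU = 1060.0, 3.78e-6


def _history(surface, wss, hr=120.0):
    return ht.WallShearHistory(
        surface=surface, wss=wss, cycle=ht.CardiacCycle(hr, wss.shape[1])
    )


def _flat_history(vectors_bte):
    """History on z-normal unit elements from an array (N, B, E, 3) whose
    vectors lie in the x-y plane."""
    surf = flat_patch_surface(vectors_bte.shape[2])
    return _history(surf, vectors_bte)


class TestNearWallGradient:
    def test_linear_shear_exact(self):
        # u = k y  =>  |WSS| = rho nu k
        normals = np.array([[0.0, 0.0, 1.0]])
        k, y = 50.0, 1e-4
        v = np.array([[k * y, 0.0, 0.0]])
        tau = wss_from_near_wall_gradient(v, y, NU, RHO, normals)
        assert np.linalg.norm(tau) == pytest.approx(RHO * NU * k, rel=1e-12)

    def test_poiseuille_wall_shear(self):
        # parabolic profile u(r) = 2 Vbar (1 - r^2/R^2): wall shear 4 rho nu Vbar / R
        R, vbar = 0.005, 0.8
        y = 1e-7
        u = 2 * vbar * (1 - ((R - y) / R) ** 2)
        normals = np.array([[0.0, 1.0, 0.0]])
        tau = wss_from_near_wall_gradient(
            np.array([[u, 0.0, 0.0]]), y, NU, RHO, normals
        )
        assert np.linalg.norm(tau) == pytest.approx(4 * RHO * NU * vbar / R, rel=1e-4)

    def test_zero_velocity_zero_wss(self):
        tau = wss_from_near_wall_gradient(
            np.zeros((1, 3)), 1e-4, NU, RHO, np.array([[0.0, 0.0, 1.0]])
        )
        np.testing.assert_allclose(tau, 0.0)

    def test_normal_component_removed(self):
        normals = np.array([[0.0, 0.0, 1.0]])
        v = np.array([[1.0, 2.0, 5.0]])
        tau = wss_from_near_wall_gradient(v, 1e-4, NU, RHO, normals)
        assert tau[0, 2] == pytest.approx(0.0, abs=1e-15)

    def test_zero_wall_distance_rejected(self):
        with pytest.raises(ht.InputError):
            wss_from_near_wall_gradient(
                np.zeros((1, 3)), 0.0, NU, RHO, np.array([[0.0, 0.0, 1.0]])
            )


class TestPawssTurwss:
    def test_identical_cycles_pawss_is_single_cycle_magnitude(self, rng):
        v = rng.normal(size=(1, 6, 2, 3))
        v[..., 2] = 0.0
        wss = np.repeat(v, 5, axis=0)
        h = _flat_history(wss)
        np.testing.assert_allclose(
            ht.pawss(h), np.linalg.norm(v[0], axis=-1), rtol=1e-12
        )

    def test_opposite_vectors_cancel(self):
        wss = np.zeros((2, 4, 1, 3))
        wss[0, 1, 0, 0], wss[1, 1, 0, 0] = 3.0, -3.0
        h = _flat_history(wss)
        assert ht.pawss(h)[1, 0] == pytest.approx(0.0, abs=1e-15)

    def test_deterministic_cycles_have_zero_turwss(self, rng):
        v = rng.normal(size=(1, 6, 3, 3))
        v[..., 2] = 0.0
        h = _flat_history(np.repeat(v, 4, axis=0))
        np.testing.assert_allclose(ht.turwss(h), 0.0, atol=1e-13)

    def test_two_cycle_turwss_composed_from_half_gaps(self):
        wss = np.zeros((2, 2, 1, 3))
        wss[0, 0, 0, :2] = [2.0, 0.0]
        wss[1, 0, 0, :2] = [0.0, 4.0]
        h = _flat_history(wss)
        # component rms (|2-0|/2, |0-4|/2) = (1, 2) -> magnitude sqrt(5)
        assert ht.turwss(h)[0, 0] == pytest.approx(np.sqrt(5.0), rel=1e-12)

    def test_gaussian_turwss_sqrt3_sigma(self, rng):
        sigma, N = 0.5, 30
        wss = rng.normal(0, sigma, (N, 4, 500, 3))
        wss[..., 2] = 0.0  # keep tangent to the z-normal wall (2 components)
        h = _flat_history(wss)
        expect = sigma * np.sqrt(2.0)
        assert np.mean(ht.turwss(h)) == pytest.approx(expect, rel=0.05)

    def test_turwss_invariant_to_periodic_field(self, rng):
        wss = rng.normal(size=(6, 5, 4, 3))
        wss[..., 2] = 0.0
        periodic = rng.normal(size=(1, 5, 4, 3))
        periodic[..., 2] = 0.0
        t1 = ht.turwss(_flat_history(wss))
        t2 = ht.turwss(_flat_history(wss + periodic))
        np.testing.assert_allclose(t1, t2, atol=1e-12)

    def test_single_cycle_turwss_rejected(self, rng):
        v = rng.normal(size=(1, 4, 1, 3))
        v[..., 2] = 0.0
        with pytest.raises(ht.StatisticsError):
            ht.turwss(_flat_history(v))

    def test_jet_fixture_peak_pawss_in_patch(self):
        spec = ht.SyntheticSpec(seed=3, n_cycles=6)
        surface, _, _ = ht.make_tube_fixture(n_axial=16, n_circ=12)
        h, truth = ht.make_wss_history(spec, surface, noise_pa=0.2)
        p = ht.pawss(h)
        assert truth.labels[np.argmax(p.max(axis=0))] == "patch"


class TestTawssTransOsi:
    def test_constant_magnitude_tawss(self):
        wss = np.zeros((2, 10, 1, 3))
        wss[..., 0] = 2.5
        maps = compute_metric_maps(_flat_history(wss))
        assert maps.tawss[0] == pytest.approx(2.5, rel=1e-12)

    def test_half_on_half_off_tawss(self):
        wss = np.zeros((2, 10, 1, 3))
        wss[:, :5, 0, 0] = 3.0
        maps = compute_metric_maps(_flat_history(wss))
        assert maps.tawss[0] == pytest.approx(1.5, rel=1e-12)

    def test_unidirectional_history_zero_transwss_and_osi(self, rng):
        mags = np.abs(rng.normal(1.0, 0.3, size=(1, 12, 1, 1)))
        wss = np.zeros((1, 12, 1, 3))
        wss[..., 0] = mags[..., 0]
        wss = np.repeat(wss, 3, axis=0)
        maps = compute_metric_maps(_flat_history(wss))
        assert maps.transwss[0] == pytest.approx(0.0, abs=1e-12)
        assert maps.osi[0] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_switching_transwss(self):
        # x-shear half the cycle, y-shear the other half, magnitude tau0
        tau0 = 2.0
        wss = np.zeros((2, 10, 1, 3))
        wss[:, :5, 0, 0] = tau0
        wss[:, 5:, 0, 1] = tau0
        maps = compute_metric_maps(_flat_history(wss))
        assert maps.transwss[0] == pytest.approx(tau0 / np.sqrt(2), rel=1e-12)

    def test_pure_rotation_flagged_undefined(self):
        # constant-magnitude WSS rotating through the full circle: zero mean
        B = 8
        ang = 2 * np.pi * np.arange(B) / B
        wss = np.zeros((2, B, 1, 3))
        wss[:, :, 0, 0] = np.cos(ang)
        wss[:, :, 0, 1] = np.sin(ang)
        maps = compute_metric_maps(_flat_history(wss))
        assert np.isnan(maps.transwss[0])

    def test_symmetric_reversal_osi_half(self):
        wss = np.zeros((2, 10, 1, 3))
        wss[:, :5, 0, 0] = 1.0
        wss[:, 5:, 0, 0] = -1.0
        maps = compute_metric_maps(_flat_history(wss))
        assert maps.osi[0] == pytest.approx(0.5, abs=1e-14)

    def test_three_quarter_forward_osi_quarter(self):
        # +1 Pa for 75% of the cycle, -1 Pa for 25%: OSI = 0.25
        wss = np.zeros((2, 8, 1, 3))
        wss[:, :6, 0, 0] = 1.0
        wss[:, 6:, 0, 0] = -1.0
        maps = compute_metric_maps(_flat_history(wss))
        assert maps.osi[0] == pytest.approx(0.25, abs=1e-14)

    def test_zero_history_osi_flagged_missing(self):
        maps = compute_metric_maps(_flat_history(np.zeros((2, 4, 1, 3))))
        assert np.isnan(maps.osi[0])

    def test_transwss_bounded_by_tawss_random(self, rng):
        wss = rng.normal(size=(5, 12, 200, 3))
        wss[..., 2] = 0.0
        maps = compute_metric_maps(_flat_history(wss))
        ok = np.isfinite(maps.transwss)
        assert np.all(maps.transwss[ok] <= maps.tawss[ok] + 1e-12)
        assert np.all((maps.osi >= 0) & (maps.osi <= 0.5))

    def test_metrics_invariant_under_rigid_rotation(self, rng):
        spec = ht.SyntheticSpec(seed=5, n_cycles=5)
        surface, _, _ = ht.make_tube_fixture(n_axial=8, n_circ=10)
        h, _ = ht.make_wss_history(spec, surface, noise_pa=0.4)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 0.7]).as_matrix()
        surf_rot = ht.WallSurface.from_triangles(
            surface.points @ rot.T, surface.triangles
        )
        h_rot = ht.WallShearHistory(
            surface=surf_rot, wss=h.wss @ rot.T, cycle=h.cycle
        )
        m1 = compute_metric_maps(h)
        m2 = compute_metric_maps(h_rot)
        np.testing.assert_allclose(m1.tawss, m2.tawss, rtol=1e-9)
        np.testing.assert_allclose(m1.osi, m2.osi, atol=1e-9)
        np.testing.assert_allclose(m1.transwss, m2.transwss, rtol=1e-7, atol=1e-9)


class TestSegmentAverage:
    def test_uniform_field_front_equals_back(self, small_tube):
        surface, mask, _ = small_tube
        wss = np.zeros((2, 4, surface.n_elements, 3))
        # uniform tangential magnitude via the axial tangent direction
        spec = ht.SyntheticSpec(seed=0, n_cycles=2, n_phase_bins=4)
        h, _ = ht.make_wss_history(
            spec, surface, tau_patch_pa=1, tau_osc_pa=1, tau_switch_pa=1, tau_base_pa=1
        )
        table = ht.segment_average(compute_metric_maps(h), mask)
        assert table.loc["front", "tawss_pa"] == pytest.approx(
            table.loc["back", "tawss_pa"], rel=1e-9
        )

    def test_elevated_patch_raises_front_mean(self, small_tube):
        surface, mask, _ = small_tube
        spec = ht.SyntheticSpec(seed=0, n_cycles=3)
        h, _ = ht.make_wss_history(spec, surface, tau_patch_pa=40.0)
        table = ht.segment_average(compute_metric_maps(h), mask)
        assert table.loc["front", "pawss_pa"] > table.loc["back", "pawss_pa"]

    def test_empty_mask_rejected(self, small_tube):
        surface, _, _ = small_tube
        spec = ht.SyntheticSpec(seed=0, n_cycles=2)
        h, _ = ht.make_wss_history(spec, surface)
        mask = ht.SegmentMask(np.full(surface.n_elements, "none"))
        with pytest.raises(ht.InputError):
            ht.segment_average(compute_metric_maps(h), mask)
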