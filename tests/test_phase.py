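"""Triple decomposition, phase statistics, energies, convergence."""

import numpy as np
import pytest
from scipy import stats

import hemoturb as ht
from hemoturb.phase import bin_cycles, convergence_check

RHO = 1060.0


def _ensemble(values, hr=120.0):
    return ht.CycleEnsemble(ht.CardiacCycle(hr, values.shape[1]), values)


class TestBinCycles:
    def test_twenty_analysis_cycles_from_21(self, rng):
        cycle = ht.CardiacCycle(120.0, 50)
        t = np.arange(21 * 50) * (cycle.period_s / 50)
        e = bin_cycles(t, rng.normal(size=t.size), cycle, discard_first=True)
        assert e.n_cycles == 20

    def test_two_cycles_kept_without_discard(self, rng):
        cycle = ht.CardiacCycle(120.0, 10)
        t = np.arange(20) * 0.05
        e = bin_cycles(t, rng.normal(size=20), cycle, discard_first=False)
        assert e.n_cycles == 2

    def test_sample_at_period_lands_in_next_cycle_bin_zero(self):
        cycle = ht.CardiacCycle(120.0, 5)
        # three cycles of 5 samples; the sample at exactly t = T starts cycle 1
        t = np.arange(15) * 0.1
        x = np.arange(15.0)
        e = bin_cycles(t, x, cycle, discard_first=False)
        assert e.values[1, 0, 0] == 5.0  # sample index 5 is at t = T

    def test_too_few_cycles_rejected(self):
        cycle = ht.CardiacCycle(120.0, 10)
        t = np.arange(20) * 0.05
        with pytest.raises(ht.InputError):
            bin_cycles(t, np.ones(20), cycle, discard_first=True)

    def test_sub_bin_samples_averaged(self):
        cycle = ht.CardiacCycle(120.0, 5)
        t = np.arange(30) * (0.5 / 15)  # 3 samples per bin, 2 cycles
        x = np.ones(30)
        x[::3] = 4.0  # per-bin mean (4+1+1)/3 = 2
        e = bin_cycles(t, x, cycle, discard_first=False)
        np.testing.assert_allclose(e.values, 2.0)


class TestPhaseMeanAndRms:
    def test_identical_cycles_mean_is_any_cycle(self, rng):
        one = rng.normal(size=(1, 50, 3))
        e = _ensemble(np.repeat(one, 5, axis=0))
        np.testing.assert_allclose(ht.phase_mean(e).phase_mean, one[0])

    def test_mean_of_noisy_sine_within_clt_bound(self, rng):
        cycle = ht.CardiacCycle(120.0, 50)
        clean = np.sin(2 * np.pi * np.arange(50) / 50)
        sigma, N = 0.3, 20
        vals = clean[None, :, None] + rng.normal(0, sigma, (N, 50, 1))
        pm = ht.phase_mean(_ensemble(vals)).phase_mean[:, 0]
        assert np.all(np.abs(pm - clean) < 4 * sigma / np.sqrt(N))

    def test_deterministic_ensemble_has_zero_rms(self, rng):
        one = rng.normal(size=(1, 20, 2))
        e = _ensemble(np.repeat(one, 6, axis=0))
        np.testing.assert_allclose(ht.phase_rms(e).phase_rms, 0.0, atol=1e-14)

    def test_two_cycle_rms_is_half_gap(self):
        vals = np.zeros((2, 4, 1))
        vals[0, 2, 0], vals[1, 2, 0] = 7.0, 3.0
        rms = ht.phase_rms(_ensemble(vals)).phase_rms
        assert rms[2, 0] == pytest.approx(2.0)  # |a - b| / 2

    def test_gaussian_rms_within_chi_quantiles(self, rng):
        # N sigma^2_hat / sigma^2 ~ chi2(N-1) for the population-form RMS
        sigma, N, B = 0.1, 30, 200
        vals = rng.normal(0, sigma, (N, B, 1))
        rms = ht.phase_rms(_ensemble(vals)).phase_rms[:, 0]
        lo = np.sqrt(stats.chi2.ppf(0.025, N - 1) / N) * sigma
        hi = np.sqrt(stats.chi2.ppf(0.975, N - 1) / N) * sigma
        frac_inside = np.mean((rms > lo) & (rms < hi))
        assert frac_inside > 0.90

    def test_rms_needs_two_cycles(self, rng):
        with pytest.raises(ht.StatisticsError):
            ht.phase_rms(_ensemble(rng.normal(size=(1, 10, 1))))

    def test_rms_invariant_to_periodic_offset(self, rng):
        vals = rng.normal(size=(8, 30, 2))
        periodic = rng.normal(size=(1, 30, 2))
        r1 = ht.phase_rms(_ensemble(vals)).phase_rms
        r2 = ht.phase_rms(_ensemble(vals + periodic)).phase_rms
        np.testing.assert_allclose(r1, r2, atol=1e-12)


class TestTripleDecompose:
    def test_reconstruction_identity(self, rng):
        e = _ensemble(rng.normal(size=(7, 25, 3)))
        avg, tilde, res = ht.triple_decompose(e)
        assert np.max(np.abs(avg + tilde + res - e.values)) < 1e-14

    def test_pure_periodic_signal_has_zero_residuals(self, rng):
        one = rng.normal(size=(1, 25, 2))
        e = _ensemble(np.repeat(one, 4, axis=0))
        _, _, res = ht.triple_decompose(e)
        np.testing.assert_allclose(res, 0.0, atol=1e-14)

    def test_residuals_have_zero_per_bin_mean(self, rng):
        e = _ensemble(rng.normal(size=(9, 25, 1)))
        _, _, res = ht.triple_decompose(e)
        np.testing.assert_allclose(res.mean(axis=0), 0.0, atol=1e-14)


class TestKineticEnergies:
    def test_ke_of_unit_mean_velocity(self):
        vals = np.zeros((3, 10, 1, 3))
        vals[..., 0] = 1.0
        es = ht.kinetic_energies(_ensemble(vals), rho=RHO)
        np.testing.assert_allclose(es.ke_t, RHO / 2)
        np.testing.assert_allclose(es.tke_t, 0.0, atol=1e-12)

    def test_tke_from_component_rms(self, rng):
        # component rms (0.1, 0.2, 0.2) => TKE = 530 * 0.09 = 47.7 Pa
        N, B = 4000, 4
        vals = np.stack(
            [rng.normal(0, s, (N, B, 1)) for s in (0.1, 0.2, 0.2)], axis=-1
        )
        es = ht.kinetic_energies(_ensemble(vals), rho=RHO)
        assert np.mean(es.tke_t) == pytest.approx(47.7, rel=0.05)

    def test_scalar_ensemble_rejected(self, rng):
        with pytest.raises(ht.InputError):
            ht.kinetic_energies(_ensemble(rng.normal(size=(3, 10, 2))))

    def test_per_bin_energy_identity(self, rng):
        # phase-mean of rho/2 |u|^2 equals KE + TKE exactly
        e = _ensemble(rng.normal(size=(15, 30, 2, 3)))
        es = ht.kinetic_energies(e, rho=RHO)
        total = RHO / 2 * (e.values**2).sum(axis=-1).mean(axis=0)
        np.testing.assert_allclose(total, es.ke_t + es.tke_t, rtol=1e-12)

    def test_volume_integration(self, rng):
        e = _ensemble(np.abs(rng.normal(size=(4, 10, 3, 3))))
        vols = np.array([1.0, 2.0, 3.0])
        es_int = ht.kinetic_energies(e, rho=RHO, cell_volumes=vols)
        es = ht.kinetic_energies(e, rho=RHO)
        np.testing.assert_allclose(es_int.ke_t, es.ke_t @ vols, rtol=1e-12)


class TestConvergenceCheck:
    @staticmethod
    def _vector_ensemble(vals_scalar):
        v = np.zeros(vals_scalar.shape + (3,))
        v[..., 0] = vals_scalar
        return _ensemble(v)

    def test_deterministic_input_passes_at_three_cycles(self):
        vals = np.tile(np.linspace(1, 2, 10)[None, :, None], (3, 1, 1))
        res = convergence_check(self._vector_ensemble(vals), peak_bin=5)
        assert res["passed"] and res["ke_rel_change"] == 0.0

    def test_stationary_noise_converges_within_60_cycles(self, rng):
        # relative change decays ~1/N (further damped by entity averaging,
        # as for the volume-integrated energies used in practice);
        # sigma/mean = 0.3 passes well before 60 cycles
        mean = 2.0
        passed_at = None
        vals = mean + 0.3 * mean * rng.standard_normal((60, 10, 100))
        for n in range(5, 61):
            res = convergence_check(
                self._vector_ensemble(vals[:n]), peak_bin=3
            )
            if res["passed"]:
                passed_at = n
                break
        assert passed_at is not None and 5 <= passed_at <= 60

    def test_drifting_amplitude_keeps_failing(self):
        # injected linear trend: the phase mean never settles
        n = np.arange(40)
        vals = (1.0 + 0.25 * n)[:, None, None] * np.ones((40, 10, 1))
        fails = [
            not convergence_check(self._vector_ensemble(vals[:k]), 3)["passed"]
            for k in range(10, 41, 10)
        ]
        assert all(fails)

    def test_identically_zero_energy_trivially_converged(self):
        vals = np.zeros((5, 10, 1))
        res = convergence_check(self._vector_ensemble(vals), peak_bin=0)
        assert res["passed"] and res["ke_rel_change"] == 0.0

    def test_zero_reference_with_late_signal_rejected(self):
        vals = np.zeros((5, 10, 1))
        vals[-1] = 1.0  # energy appears only in the newest cycle
        with pytest.raises(ht.InputError):
            convergence_check(self._vector_ensemble(vals), peak_bin=0)
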