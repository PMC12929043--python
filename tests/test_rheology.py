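"""MSD estimators, trap calibration, GSER moduli and stress correlation."""

import numpy as np
import pytest

from nucleopack.rheology import (
    KB,
    BeadTrajectory,
    ComplexModulus,
    complex_modulus,
    msd,
    stress_relaxation,
    trap_stiffness,
    viscosity_and_crossovers,
)
from nucleopack.synthetic import gen_trapped_bead


def make_traj(positions, dt=1e-3, a=0.5, T=298.0, kappa=None):
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.shape[0] < positions.shape[1]:
        positions = positions.T
    return BeadTrajectory(times=np.arange(positions.shape[0]) * dt,
                          positions=positions, bead_radius_um=a,
                          temperature_K=T, trap_stiffness_N_per_m=kappa)


class TestMsd:
    def test_ballistic_is_quadratic(self):
        v = 3.0
        t = np.arange(2000) * 1e-3
        out = msd(make_traj(v * t), max_lag=100)
        assert np.allclose(out["msd_total"], (v * out["lag_s"]) ** 2, rtol=1e-9)

    def test_iid_gaussian_is_flat(self, rng):
        sigma = 2.0
        x = rng.normal(0, sigma, size=40_000)
        out = msd(make_traj(x), max_lag=50)
        assert np.allclose(out["msd_total"], 2 * sigma**2, rtol=0.05)

    def test_matches_double_loop(self, rng):
        x = rng.normal(size=1000)
        out = msd(make_traj(x), max_lag=40)
        for k in range(1, 41):
            brute = np.mean((x[k:] - x[:-k]) ** 2)
            assert out["msd_total"].iloc[k - 1] == pytest.approx(brute, rel=1e-9)

    def test_max_lag_bound(self, rng):
        x = rng.normal(size=100)
        with pytest.raises(ValueError, match="max_lag"):
            msd(make_traj(x), max_lag=90)


class TestTrapStiffness:
    def test_ou_recovery_within_three_percent(self):
        # low viscosity so the record holds ~1e4 correlation times: the
        # equipartition variance is then precise to a couple of percent
        tb = gen_trapped_bead(material="newtonian", eta=0.01, kappa=1e-5,
                              a_um=0.5, dt=1e-4, n=1_000_000, seed=1)
        k = trap_stiffness(tb)
        assert np.mean(k) == pytest.approx(1e-5, rel=0.03)

    def test_axes_agree_for_isotropic_input(self):
        tb = gen_trapped_bead(material="newtonian", eta=1.0, kappa=1e-5,
                              a_um=0.5, dt=1e-3, n=200_000, seed=2)
        k = trap_stiffness(tb)
        assert abs(k[0] / k[1] - 1.0) < 0.05

    def test_doubling_variance_halves_kappa(self):
        tb = gen_trapped_bead(material="newtonian", eta=1.0, kappa=1e-5,
                              a_um=0.5, dt=1e-3, n=100_000, seed=3, n_axes=1)
        scaled = make_traj(tb.positions * np.sqrt(2.0), dt=tb.dt)
        k0 = trap_stiffness(tb)[0]
        k1 = trap_stiffness(scaled)[0]
        assert k1 == pytest.approx(k0 / 2.0, rel=1e-9)

    def test_drift_raises(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1.0, 50_000) + np.linspace(0, 50, 50_000)
        with pytest.raises(ValueError, match="drift"):
            trap_stiffness(make_traj(x))


class TestComplexModulus:
    def test_newtonian_loss_modulus(self):
        tb = gen_trapped_bead(material="newtonian", eta=1.0, kappa=1e-5,
                              a_um=0.5, dt=1e-3, n=200_000, seed=1)
        G = complex_modulus(tb)
        f = G.frequencies_hz
        omega = 2 * np.pi * f
        gm = np.sqrt(f[0] * f[-1])
        central = (f >= gm / np.sqrt(10)) & (f <= gm * np.sqrt(10))
        ratio = G.G_double_prime_pa[central] / omega[central]
        assert np.all(np.abs(ratio - 1.0) < 0.10)
        assert np.all(G.G_prime_pa[central] < 0.15 * G.G_double_prime_pa[central])

    def test_kelvin_voigt_plateau(self):
        tb = gen_trapped_bead(material="kelvin_voigt", G0=1.0, eta=0.5,
                              kappa=1e-5, a_um=0.5, dt=1e-3, n=200_000, seed=3)
        G = complex_modulus(tb)
        low = G.frequencies_hz < 0.5
        assert np.mean(G.G_prime_pa[low]) == pytest.approx(1.0, rel=0.15)

    def test_deterministic_for_fixed_input(self):
        tb = gen_trapped_bead(material="newtonian", eta=1.0, kappa=1e-5,
                              a_um=0.5, dt=1e-3, n=50_000, seed=4)
        g1, g2 = complex_modulus(tb), complex_modulus(tb)
        assert np.array_equal(g1.frequencies_hz, g2.frequencies_hz)
        assert np.array_equal(g1.G_double_prime_pa, g2.G_double_prime_pa)

    def test_short_record_rejected(self, rng):
        with pytest.raises(ValueError, match="1e4"):
            complex_modulus(make_traj(rng.normal(size=500), kappa=1e-5))


def analytic_modulus(freqs, fn):
    omega = 2 * np.pi * freqs
    g = fn(omega)
    return ComplexModulus(frequencies_hz=freqs, G_prime_pa=g.real,
                          G_double_prime_pa=g.imag)


class TestViscosityAndCrossovers:
    freqs = np.logspace(-2, 2, 80)

    def test_newtonian_analytic(self):
        G = analytic_modulus(self.freqs, lambda w: 1e-9 + 1j * w * 1.0)
        out = viscosity_and_crossovers(G)
        assert out["eta0_pa_s"] == pytest.approx(1.0, rel=1e-6)
        assert out["crossover_frequencies_hz"] == []

    def test_maxwell_crossover_at_inverse_relaxation_time(self):
        G0, lam = 2.0, 0.5

        def maxwell(w):
            x = 1j * w * lam
            return G0 * x / (1 + x)

        G = analytic_modulus(self.freqs, maxwell)
        out = viscosity_and_crossovers(G)
        assert len(out["crossover_frequencies_hz"]) == 1
        assert out["crossover_frequencies_hz"][0] == pytest.approx(
            1.0 / (2 * np.pi * lam), rel=0.02)

    def test_homogeneity(self):
        G0, lam = 2.0, 0.5

        def maxwell(w):
            x = 1j * w * lam
            return G0 * x / (1 + x)

        g1 = viscosity_and_crossovers(analytic_modulus(self.freqs, maxwell))
        g2 = viscosity_and_crossovers(
            analytic_modulus(self.freqs, lambda w: 2 * maxwell(w)))
        assert g2["eta0_pa_s"] == pytest.approx(2 * g1["eta0_pa_s"], rel=1e-6)
        assert g2["crossover_frequencies_hz"][0] == pytest.approx(
            g1["crossover_frequencies_hz"][0], rel=1e-6)

    def test_elastic_dominated_flags_lower_bound(self):
        G = analytic_modulus(self.freqs, lambda w: 5.0 + 1j * w * 0.001)
        out = viscosity_and_crossovers(G)
        assert out["eta0_is_lower_bound"]

    def test_eta0_stable_under_subsampling(self):
        tb = gen_trapped_bead(material="newtonian", eta=1.0, kappa=1e-5,
                              a_um=0.5, dt=1e-3, n=200_000, seed=5)
        sub = BeadTrajectory(times=tb.times[::2], positions=tb.positions[::2],
                             bead_radius_um=tb.bead_radius_um,
                             temperature_K=tb.temperature_K,
                             trap_stiffness_N_per_m=tb.trap_stiffness_N_per_m)
        e1 = viscosity_and_crossovers(complex_modulus(tb))["eta0_pa_s"]
        e2 = viscosity_and_crossovers(complex_modulus(sub))["eta0_pa_s"]
        assert abs(e2 / e1 - 1.0) < 0.15


class TestStressRelaxation:
    def test_constant_stress(self):
        sigma0, V, T = 2.0, 1e6, 298.0
        g = stress_relaxation(np.full(500, sigma0), dt=1e-3, volume_nm3=V,
                              temperature_K=T, max_lag=100)
        expected = V * 1e-27 * sigma0**2 / (KB * T)
        assert np.allclose(g["G_pa"], expected, rtol=1e-9)

    def test_white_noise_decorrelates(self, rng):
        s = rng.normal(0, 1.0, 200_000)
        g = stress_relaxation(s, dt=1e-3, volume_nm3=1e6, max_lag=50)
        assert abs(g["G_pa"].iloc[10]) < 0.02 * g["G_pa"].iloc[0]

    def test_matches_double_loop(self, rng):
        s = rng.normal(size=500)
        V, T = 1e6, 298.0
        g = stress_relaxation(s, dt=1e-3, volume_nm3=V, temperature_K=T,
                              max_lag=60)
        scale = V * 1e-27 / (KB * T)
        for k in (0, 1, 7, 33, 60):
            brute = scale * np.mean(s[: len(s) - k] * s[k:])
            assert g["G_pa"].iloc[k] == pytest.approx(brute, rel=1e-9)

    def test_truncation_warning(self, rng):
        s = rng.normal(size=50)
        with pytest.warns(UserWarning, match="origins"):
            stress_relaxation(s, dt=1e-3, volume_nm3=1e6, max_lag=45)
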