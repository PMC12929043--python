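"""Passive microrheology with optical traps (pMOT) and stress-correlation
rheology.

A bead of radius ``a`` held in a harmonic trap of stiffness ``kappa``
inside a viscoelastic medium has a mean-squared displacement whose
normalised form Pi(t) = kappa * MSD(t) / (2 kB T) rises from 0 to 1.
The trap-corrected generalised Stokes-Einstein relation converts the
one-sided Fourier transform of Pi into the complex shear modulus

    G*(omega) = kappa / (6 pi a) * ( 1 / (i omega Pi_hat(omega)) - 1 ),

with G' = Re G* (elastic/storage) and G'' = Im G* (viscous/loss).
Pi_hat is evaluated exactly for the piecewise-linear interpolant of the
measured Pi with a constant plateau beyond the last lag, so a Newtonian
medium (exponential Pi) returns exactly G* = i omega eta in the
continuum limit.

The shear stress relaxation modulus from simulation stress series is
G(t) = (V / kB T) <sigma_ab(t0) sigma_ab(t0 + t)>, averaged over
off-diagonal components and time origins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KB",
    "BeadTrajectory",
    "ComplexModulus",
    "msd",
    "trap_stiffness",
    "complex_modulus",
    "viscosity_and_crossovers",
    "stress_relaxation",
]

KB = 1.380649e-23  # J/K


@dataclass
class BeadTrajectory:
    """Trapped-bead trajectory: uniform time base, positions in nm."""

    times: np.ndarray  # s
    positions: np.ndarray  # (n, d) nm
    bead_radius_um: float
    temperature_K: float = 298.0
    trap_stiffness_N_per_m: np.ndarray | float | None = None  # per axis
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        x = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if x.shape[0] == len(t) or x.shape[1] == len(t):
            if x.shape[0] != len(t):
                x = x.T
        else:
            raise ValueError("positions and times have incompatible lengths")
        dt = np.diff(t)
        if len(dt) and (np.max(dt) - np.min(dt)) > 1e-9 * np.mean(dt):
            raise ValueError("sampling must be uniform")
        if self.bead_radius_um is None or self.bead_radius_um <= 0:
            raise ValueError("bead radius is mandatory and must be positive")
        self.times = t
        self.positions = x

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def ndim(self) -> int:
        return self.positions.shape[1]


def _msd_fft_1d(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Time-averaged MSD over overlapping windows, exact via FFT.

    MSD[k] = mean_i (x[i+k] - x[i])^2 for k = 0..max_lag; identical to
    the O(n^2) double loop up to floating-point rounding.
    """
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(fx * np.conj(fx), nfft)[: max_lag + 1]
    sq = x * x
    css = np.concatenate([[0.0], np.cumsum(sq)])
    total = css[-1]
    k = np.arange(max_lag + 1)
    # sum_i x_i^2 + x_{i+k}^2 over valid i, minus twice the autocorrelation
    head = css[n - k] - css[0]
    tail = total - css[k]
    return (head + tail - 2.0 * acf) / (n - k)


def msd(
    t: "BeadTrajectory | np.ndarray",
    max_lag: int | None = None,
    dt: float | None = None,
) -> pd.DataFrame:
    """Time-averaged mean-squared displacement with overlapping windows.

    Accepts a :class:`BeadTrajectory` (or any object with ``positions``
    and ``dt``) or a raw (n, d) position array plus ``dt``.  Returns a
    table with per-axis MSD and their sum, in position units squared.
    """
    if hasattr(t, "positions"):
        x = np.atleast_2d(t.positions)
        dt = t.dt
    else:
        x = np.atleast_2d(np.asarray(t, dtype=float))
        if x.shape[0] < x.shape[1]:
            x = x.T
        if dt is None:
            raise ValueError("dt is required for raw position arrays")
    n = x.shape[0]
    if max_lag is None:
        max_lag = n // 4
    if not 0 < max_lag < n / 4 + 1:
        raise ValueError("max_lag must satisfy 0 < max_lag < n/4")
    lags = np.arange(1, max_lag + 1)
    out = {"lag_s": lags * dt}
    total = np.zeros(max_lag)
    for ax in range(x.shape[1]):
        m = _msd_fft_1d(x[:, ax], max_lag)[1:]
        out[f"msd_axis{ax}"] = m
        total += m
    out["msd_total"] = total
    return pd.DataFrame(out)


def trap_stiffness(
    t: BeadTrajectory, drift_tolerance_sigmas: float = 1.0
) -> np.ndarray:
    """Per-axis trap stiffness (N/m) by equipartition: kappa = kB T / Var(x).

    A linear drift larger than ``drift_tolerance_sigmas`` residual
    standard deviations over the record is treated as non-stationarity.
    """
    kappas = []
    tt = t.times - t.times[0]
    for ax in range(t.ndim):
        x_m = t.positions[:, ax] * 1e-9
        slope, intercept = np.polyfit(tt, x_m, 1)
        resid = x_m - (slope * tt + intercept)
        drift_span = abs(slope) * (tt[-1] - tt[0])
        if drift_span > drift_tolerance_sigmas * np.std(resid):
            raise ValueError(
                "linear drift detected; detrend the trajectory before "
                "estimating trap stiffness"
            )
        var = float(np.var(x_m))
        if var <= 0:
            raise ValueError("zero positional variance")
        kappas.append(KB * t.temperature_K / var)
    return np.array(kappas)


@dataclass
class ComplexModulus:
    """Storage and loss moduli on an ascending frequency grid."""

    frequencies_hz: np.ndarray
    G_prime_pa: np.ndarray
    G_double_prime_pa: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        f = np.asarray(self.frequencies_hz, dtype=float)
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be positive and ascending")
        if not (np.all(np.isfinite(self.G_prime_pa))
                and np.all(np.isfinite(self.G_double_prime_pa))):
            raise ValueError("moduli must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "freq_hz": self.frequencies_hz,
                "G_prime_pa": self.G_prime_pa,
                "G_double_prime_pa": self.G_double_prime_pa,
            }
        )


def _one_sided_ft_pwl(lag: np.ndarray, pi: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Exact one-sided Fourier transform of the piecewise-linear
    interpolant of (lag, pi), anchored at (0, 0), with a constant plateau
    beyond the last lag."""
    t_knots = np.concatenate([[0.0], lag])
    p_knots = np.concatenate([[0.0], pi])
    a = t_knots[:-1][None, :]
    b = t_knots[1:][None, :]
    pa = p_knots[:-1][None, :]
    pb = p_knots[1:][None, :]
    w = omega[:, None]
    iw = 1j * w
    ea = np.exp(-iw * a)
    eb = np.exp(-iw * b)
    slope = (pb - pa) / (b - a)
    seg = pa * (ea - eb) / iw + slope * (-(b - a) * eb / iw + (ea - eb) / (iw * iw))
    tail = p_knots[-1] * np.exp(-1j * omega * t_knots[-1]) / (1j * omega)
    return seg.sum(axis=1) + tail


def _select_lags(max_lag: int, dense_upto: int = 1000, n_log: int = 300) -> np.ndarray:
    """Every integer lag up to ``dense_upto``, log-spaced beyond.

    Dense short-lag knots keep the piecewise-linear interpolation error
    of the transform negligible at high frequencies.
    """
    dense = np.arange(1, min(dense_upto, max_lag) + 1)
    if max_lag > dense_upto:
        tail = np.round(
            np.logspace(np.log10(dense_upto), np.log10(max_lag), n_log)
        ).astype(int)
        return np.unique(np.concatenate([dense, tail]))
    return dense


def _smooth_pi(
    t_lag: np.ndarray, pi_raw: np.ndarray, t_total: float, dt: float,
    n_modes: int = 24,
) -> np.ndarray:
    """Project the measured Pi onto a non-negative relaxation-mode basis.

    Pi is fitted as sum_i a_i (1 - exp(-t / theta_i)) with a_i >= 0 over
    a log-spaced grid of relaxation times (non-negative least squares,
    decade-balanced weights).  Any linear viscoelastic medium in a
    harmonic trap has a Pi of exactly this completely-monotone-derivative
    form, so the projection suppresses the statistical noise of the
    long-lag MSD without constraining the admissible physics.
    """
    from scipy.optimize import nnls

    thetas = np.logspace(np.log10(dt / 2.0), np.log10(t_total / 2.0), n_modes)
    basis = 1.0 - np.exp(-t_lag[:, None] / thetas[None, :])
    w = np.gradient(np.log(t_lag))
    w = np.sqrt(w / w.sum())
    coef, _ = nnls(basis * w[:, None], pi_raw * w)
    return basis @ coef


def complex_modulus(
    t: BeadTrajectory,
    n_frequencies: int = 50,
    kappa: np.ndarray | float | None = None,
    smooth: bool = True,
) -> ComplexModulus:
    """Trap-corrected GSER estimate of G*(omega) from a trapped bead.

    The normalised MSD Pi (averaged over axes) is sampled at the lag
    knots, optionally denoised by the relaxation-mode projection of
    :func:`_smooth_pi`, transformed exactly as a piecewise-linear
    function, and converted to G' and G'' on a log-spaced frequency grid
    spanning one decade inside both the record-length and Nyquist
    limits.  Frequencies where either modulus is negative (outside the
    reliable band) are trimmed.
    """
    if t.n < 10_000:
        raise ValueError("modulus estimation needs at least 1e4 samples")
    if kappa is None:
        kappa = t.trap_stiffness_N_per_m
    if kappa is None:
        kappa = trap_stiffness(t)
    kappa = np.broadcast_to(np.atleast_1d(np.asarray(kappa, dtype=float)), (t.ndim,))
    a_m = t.bead_radius_um * 1e-6
    kbt = KB * t.temperature_K
    dt = t.dt
    max_lag = t.n // 4
    all_lags = _select_lags(max_lag)
    f_lo = 10.0 / (t.n * dt)
    f_hi = 1.0 / (10.0 * dt)
    if f_hi <= f_lo:
        raise ValueError("record too short for a reliable frequency band")
    freqs = np.logspace(np.log10(f_lo), np.log10(f_hi), n_frequencies)
    omega = 2.0 * np.pi * freqs

    pi_mean = np.zeros(len(all_lags))
    for ax in range(t.ndim):
        m_full = _msd_fft_1d(t.positions[:, ax] * 1e-9, max_lag)
        pi_mean += kappa[ax] * m_full[all_lags] / (2.0 * kbt)
    pi_mean /= t.ndim
    if np.any(np.diff(pi_mean) < -0.05 * max(pi_mean.max(), 1e-12)):
        warnings.warn(
            "normalised MSD is non-monotone beyond the noise floor", stacklevel=2
        )
    pi_used = _smooth_pi(all_lags * dt, pi_mean, t.n * dt, dt) if smooth else pi_mean
    pi_hat = _one_sided_ft_pwl(all_lags * dt, pi_used, omega)
    kappa_eff = float(np.mean(kappa))
    g_mean = kappa_eff / (6.0 * np.pi * a_m) * (1.0 / (1j * omega * pi_hat) - 1.0)
    gp, gpp = g_mean.real, g_mean.imag
    keep = (gp >= 0) & (gpp >= 0)
    if not np.all(keep):
        warnings.warn(
            f"trimmed {int((~keep).sum())} frequencies with negative moduli "
            "outside the reliable band",
            stacklevel=2,
        )
    return ComplexModulus(
        frequencies_hz=freqs[keep],
        G_prime_pa=gp[keep],
        G_double_prime_pa=gpp[keep],
        meta={
            "kappa_N_per_m": kappa.tolist(),
            "bead_radius_um": t.bead_radius_um,
            "temperature_K": t.temperature_K,
            "n_samples": t.n,
        },
    )


def viscosity_and_crossovers(G: ComplexModulus, viscous_ratio: float = 3.0) -> dict:
    """Zero-shear viscosity and G'/G'' crossover frequencies.

    eta0 is the slope of G'' versus omega fitted through the origin over
    the lowest reliable decade in which the response is viscosity
    dominated (G'' > ``viscous_ratio`` * G'); crossovers are sign changes
    of log G' - log G'' located by log-log interpolation.
    """
    f = G.frequencies_hz
    if f[-1] / f[0] < 100.0:
        raise ValueError("modulus must span at least two decades")
    omega = 2.0 * np.pi * f
    gp, gpp = G.G_prime_pa, G.G_double_prime_pa
    viscous = gpp > viscous_ratio * gp
    lower_bound = False
    if viscous.any():
        f0 = f[viscous][0]
        sel = viscous & (f <= 10.0 * f0)
    else:
        lower_bound = True
        sel = f <= 10.0 * f[0]
    eta0 = float(np.sum(gpp[sel] * omega[sel]) / np.sum(omega[sel] ** 2))

    crossovers = []
    ok = (gp > 0) & (gpp > 0)
    lf, s = np.log10(f[ok]), np.log10(gp[ok]) - np.log10(gpp[ok])
    for i in range(len(s) - 1):
        if s[i] == 0.0:
            crossovers.append(10 ** lf[i])
        elif s[i] * s[i + 1] < 0:
            frac = -s[i] / (s[i + 1] - s[i])
            crossovers.append(10 ** (lf[i] + frac * (lf[i + 1] - lf[i])))
    return {
        "eta0_pa_s": eta0,
        "eta0_is_lower_bound": lower_bound,
        "crossover_frequencies_hz": crossovers,
    }


def stress_relaxation(
    stress_series: np.ndarray,
    dt: float,
    volume_nm3: float,
    temperature_K: float = 298.0,
    max_lag: int | None = None,
) -> pd.DataFrame:
    """Shear stress relaxation modulus G(t) from off-diagonal stress series.

    ``stress_series`` is (n,) or (n, k) in Pa, one column per
    off-diagonal component; the raw (not mean-subtracted) autocorrelation
    is averaged over components and time origins and scaled by
    V / (kB T).  Lags with fewer than 10 time origins are truncated.
    """
    s = np.atleast_2d(np.asarray(stress_series, dtype=float))
    if s.shape[0] < s.shape[1]:
        s = s.T
    n = s.shape[0]
    if dt <= 0 or volume_nm3 <= 0:
        raise ValueError("dt and volume must be positive")
    if max_lag is None:
        max_lag = n // 2
    if n - max_lag < 10:
        warnings.warn(
            "fewer than 10 time origins at the largest lag; truncating",
            stacklevel=2,
        )
        max_lag = n - 10
    lags = np.arange(0, max_lag + 1)
    acf = np.zeros(max_lag + 1)
    nfft = 1 << (2 * n - 1).bit_length()
    for col in range(s.shape[1]):
        fx = np.fft.rfft(s[:, col], nfft)
        raw = np.fft.irfft(fx * np.conj(fx), nfft)[: max_lag + 1]
        acf += raw / (n - lags)
    acf /= s.shape[1]
    scale = volume_nm3 * 1e-27 / (KB * temperature_K)
    return pd.DataFrame({"t_s": lags * dt, "G_pa": scale * acf})
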