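"""Energy spectral density of velocity probe signals.

The discrete energy spectral density is E(f) = |DFT(u)|² / L for a signal of
L samples, presented one-sided (non-DC, non-Nyquist bins doubled) so that
Σ_f E(f) equals the signal energy Σ_n u_n² (Parseval).  Utilities cover
cumulative-energy cutoff frequencies, least-squares slope fits in the
inertial range (Kolmogorov −5/3 scaling), and identification of the heart
rate fundamental and its harmonics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = [
    "VelocitySignal",
    "Spectrum",
    "esd",
    "welch_esd",
    "cumulative_cutoff",
    "inertial_slope",
    "fundamental_and_harmonics",
]


@dataclass(frozen=True)
class VelocitySignal:
    """Uniformly sampled scalar velocity signal."""

    fs_hz: float
    samples: np.ndarray = field(repr=False)

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if self.fs_hz <= 0:
            raise InputError("sampling frequency must be positive")
        if s.ndim != 1 or s.size < 16:
            raise InputError("signal must be 1-D with at least 16 samples")
        if not np.all(np.isfinite(s)):
            raise InputError("signal contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @classmethod
    def from_times(cls, t_s, u, rtol: float = 1e-6) -> "VelocitySignal":
        """Build from explicit sample times, enforcing uniform sampling."""
        t_s = np.asarray(t_s, dtype=float)
        dt = np.diff(t_s)
        if dt.size == 0 or np.any(np.abs(dt - dt[0]) > rtol * dt[0]):
            raise InputError("non-uniform sampling")
        return cls(fs_hz=1.0 / dt[0], samples=np.asarray(u, dtype=float))


@dataclass(frozen=True)
class Spectrum:
    """One-sided energy spectral density with Parseval bookkeeping."""

    freqs_hz: np.ndarray = field(repr=False)
    esd: np.ndarray = field(repr=False)
    total_energy: float = 0.0

    def __post_init__(self):
        if np.any(np.asarray(self.esd) < -1e-30):
            raise InputError("energy spectral density must be non-negative")


def _one_sided(u: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    L = u.size
    F = np.fft.rfft(u)
    e = np.abs(F) ** 2 / L
    # fold negative frequencies onto positive ones: double all bins except
    # DC and (for even L) Nyquist, preserving Parseval's sum
    fold = np.full(e.size, 2.0)
    fold[0] = 1.0
    if L % 2 == 0:
        fold[-1] = 1.0
    return np.fft.rfftfreq(L, d=1.0 / fs), e * fold


def esd(sig: VelocitySignal, detrend: bool = False, window: str | None = None) -> Spectrum:
    """Energy spectral density E(f) = |F(u)|² / L, one-sided.

    ``detrend`` removes the sample mean first; ``window="hann"`` applies a
    Hann taper for leakage studies (energy-normalised so Parseval holds for
    the tapered signal).  No taper by default.
    """
    u = sig.samples
    if detrend:
        u = u - u.mean()
    if window == "hann":
        u = u * np.hanning(u.size)
    elif window is not None:
        raise InputError(f"unknown window {window!r}")
    freqs, e = _one_sided(u, sig.fs_hz)
    return Spectrum(freqs_hz=freqs, esd=e, total_energy=float(np.sum(u**2)))


def welch_esd(
    sig: VelocitySignal, n_blocks: int, detrend: bool = False
) -> Spectrum:
    """Block-averaged ESD: the signal is cut into ``n_blocks`` equal
    non-overlapping blocks (one per cardiac cycle in the standard workflow)
    and their spectra averaged, trading resolution for variance."""
    if n_blocks < 1 or sig.n_samples // n_blocks < 16:
        raise InputError("too many blocks for the signal length")
    blen = sig.n_samples // n_blocks
    specs = []
    energy = 0.0
    for i in range(n_blocks):
        block = VelocitySignal(sig.fs_hz, sig.samples[i * blen : (i + 1) * blen])
        s = esd(block, detrend=detrend)
        specs.append(s.esd)
        energy += s.total_energy
    return Spectrum(
        freqs_hz=np.fft.rfftfreq(blen, d=1.0 / sig.fs_hz),
        esd=np.mean(specs, axis=0),
        total_energy=energy / n_blocks,
    )


def cumulative_cutoff(s: Spectrum, fraction: float) -> float:
    """Smallest frequency at which the cumulative energy, ascending in f,
    reaches ``fraction`` of the total (e.g. 0.99 or 0.999)."""
    if not 0.0 < fraction <= 1.0:
        raise InputError("fraction must be in (0, 1]")
    total = float(np.sum(s.esd))
    if total <= 0:
        raise InputError("spectrum has no energy")
    cum = np.cumsum(s.esd) / total
    idx = int(np.searchsorted(cum, fraction - 1e-12))
    return float(s.freqs_hz[min(idx, s.freqs_hz.size - 1)])


def inertial_slope(
    s: Spectrum, f_lo: float, f_hi: float
) -> tuple[float, float]:
    """Least-squares slope of log10 E vs log10 f over [f_lo, f_hi].

    Returns ``(slope, stderr)``.  An exact power law E ∝ f^a returns a to
    machine precision.  Requires at least 8 positive-energy bins in band.
    """
    if not f_lo < f_hi:
        raise InputError("need f_lo < f_hi")
    mask = (s.freqs_hz >= f_lo) & (s.freqs_hz <= f_hi) & (s.esd > 0)
    if mask.sum() < 8:
        raise InputError(
            f"only {int(mask.sum())} usable bins in [{f_lo:g}, {f_hi:g}] Hz; need >= 8"
        )
    res = stats.linregress(np.log10(s.freqs_hz[mask]), np.log10(s.esd[mask]))
    return float(res.slope), float(res.stderr)


def fundamental_and_harmonics(
    s: Spectrum, hr_bpm: float, k_max: int = 5
) -> pd.DataFrame:
    """Locate spectral peaks nearest the heart-rate fundamental f0 = HR/60
    and its harmonics k·f0, k = 1..k_max.

    Each harmonic is searched for within ±f0/2 of its nominal frequency; the
    bin of maximum energy in that window is reported with its offset and
    energy.  Raises if the frequency resolution is coarser than f0.
    """
    f0 = hr_bpm / 60.0
    df = float(s.freqs_hz[1] - s.freqs_hz[0]) if s.freqs_hz.size > 1 else np.inf
    if df > f0:
        raise InputError(
            f"frequency resolution {df:g} Hz cannot resolve the {f0:g} Hz fundamental"
        )
    rows = []
    for k in range(1, k_max + 1):
        target = k * f0
        if target > s.freqs_hz[-1]:
            break
        mask = np.abs(s.freqs_hz - target) <= f0 / 2
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        peak = idx[np.argmax(s.esd[idx])]
        rows.append(
            {
                "harmonic": k,
                "f_nominal_hz": target,
                "f_peak_hz": float(s.freqs_hz[peak]),
                "offset_hz": float(s.freqs_hz[peak] - target),
                "energy": float(s.esd[peak]),
            }
        )
    return pd.DataFrame(rows)
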