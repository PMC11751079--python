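"""Inlet flow waveforms: smoothing, heart-rate rescaling, parabolic profiles.

The inlet boundary condition for an aortic model is a one-cycle flow-rate
waveform Q(t), typically digitised from pulsed-wave Doppler echocardiography
as a velocity trace and converted to flow rate through the inlet
cross-section area.  Waveforms at other heart rates are derived from a
measured baseline by the constant-stroke-volume rule: the time axis is
compressed or dilated with the period while the amplitude is scaled
inversely, so the ejected volume per beat is unchanged and the waveform
shape, as a function of cycle fraction, is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateInputError, InputError

__all__ = [
    "CardiacCycle",
    "FlowWaveform",
    "InletGeometry",
    "smooth_and_normalise",
    "stroke_volume",
    "rescale_to_hr",
    "parabolic_profile",
    "peak_systole_time",
]


@dataclass(frozen=True)
class CardiacCycle:
    """Temporal frame of the cardiac cycle.

    Parameters
    ----------
    hr_bpm
        Heart rate in beats per minute; must be positive.
    n_phase_bins
        Number of equal phase bins the cycle is divided into for
        phase-averaged statistics (default 50).
    """

    hr_bpm: float
    n_phase_bins: int = 50

    def __post_init__(self):
        if not np.isfinite(self.hr_bpm) or self.hr_bpm <= 0:
            raise InputError(f"heart rate must be positive, got {self.hr_bpm}")
        if self.n_phase_bins < 2:
            raise InputError("need at least 2 phase bins")

    @property
    def period_s(self) -> float:
        """Cycle period T = 60 / HR in seconds."""
        return 60.0 / self.hr_bpm

    @property
    def bin_edges(self) -> np.ndarray:
        """Half-open phase-bin edges [0, T], length ``n_phase_bins + 1``."""
        return np.linspace(0.0, self.period_s, self.n_phase_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.bin_edges
        return 0.5 * (e[:-1] + e[1:])


@dataclass(frozen=True)
class InletGeometry:
    """Inlet cross-section; radius is the equivalent circular radius."""

    area_m2: float

    def __post_init__(self):
        if not np.isfinite(self.area_m2) or self.area_m2 <= 0:
            raise InputError(f"inlet area must be positive, got {self.area_m2}")

    @property
    def radius_m(self) -> float:
        return float(np.sqrt(self.area_m2 / np.pi))


@dataclass(frozen=True)
class FlowWaveform:
    """One-cycle flow-rate waveform on a uniform, periodic time grid.

    ``t_s`` covers [0, T) half-open; the sample at t = T is identified
    with the one at t = 0 by periodicity.
    """

    cycle: CardiacCycle
    t_s: np.ndarray = field(repr=False)
    q_m3s: np.ndarray = field(repr=False)

    def __post_init__(self):
        t = np.asarray(self.t_s, dtype=float)
        q = np.asarray(self.q_m3s, dtype=float)
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "q_m3s", q)
        if t.ndim != 1 or t.shape != q.shape:
            raise InputError("t_s and q_m3s must be 1-D arrays of equal length")
        if t.size < 2:
            raise InputError("waveform needs at least 2 samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(q))):
            raise InputError("waveform contains non-finite values")
        if t[0] != 0.0:
            raise InputError("waveform time axis must start at 0")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise InputError("waveform times must be strictly increasing")
        T = self.cycle.period_s
        if t[-1] > T + 1e-12 or T - t[-1] > np.max(dt) * (1 + 1e-9):
            raise InputError(
                f"waveform must cover one period: last sample {t[-1]:g}, period {T:g}"
            )

    @property
    def n_samples(self) -> int:
        return self.t_s.size

    def q_at(self, t: float | np.ndarray) -> np.ndarray:
        """Flow rate at arbitrary time, periodic linear interpolation."""
        T = self.cycle.period_s
        tw = np.asarray(t, dtype=float) % T
        tp = np.concatenate([self.t_s, [T]])
        qp = np.concatenate([self.q_m3s, [self.q_m3s[0]]])
        return np.interp(tw, tp, qp)


def _uniform_grid(cycle: CardiacCycle, samples_per_bin: int) -> np.ndarray:
    m = cycle.n_phase_bins * samples_per_bin
    return np.arange(m) * (cycle.period_s / m)


def smooth_and_normalise(
    t_raw: np.ndarray,
    v_raw: np.ndarray,
    target_cycle: CardiacCycle,
    area: InletGeometry | None = None,
    *,
    samples_per_bin: int = 10,
    smooth_window_fraction: float = 0.05,
    clip_negative: bool = False,
) -> FlowWaveform:
    """Resample, smooth, and convert a raw digitised trace to a flow waveform.

    The raw time axis (one cycle, arbitrary duration) is normalised onto the
    target cycle's period, linearly resampled onto a uniform grid of
    ``n_phase_bins * samples_per_bin`` points, and smoothed with a
    second-order Savitzky-Golay filter whose window spans
    ``smooth_window_fraction`` of the cycle (periodic wrap-around, so
    q(0) = q(T) is built in).  If ``area`` is given, samples are treated as
    velocities (m/s) and multiplied by the inlet area to give flow rate.

    Raises
    ------
    InputError
        Fewer than 10 samples or non-monotonic times.
    DegenerateInputError
        An all-zero signal.
    """
    t_raw = np.asarray(t_raw, dtype=float)
    v_raw = np.asarray(v_raw, dtype=float)
    if t_raw.size < 10:
        raise InputError("need at least 10 raw samples")
    if np.any(np.diff(t_raw) <= 0):
        raise InputError("raw sample times must be strictly increasing")
    if np.all(v_raw == 0):
        raise DegenerateInputError("raw signal is identically zero")

    T = target_cycle.period_s
    span = t_raw[-1] - t_raw[0]
    # normalise the raw cycle duration onto the target period; treat the raw
    # trace as one full cycle with periodic continuation
    t_norm = (t_raw - t_raw[0]) / span * T
    grid = _uniform_grid(target_cycle, samples_per_bin)
    tp = np.concatenate([t_norm, [T]])
    vp = np.concatenate([v_raw, [v_raw[0]]])
    v = np.interp(grid, tp, vp)

    window = int(round(smooth_window_fraction * grid.size))
    window = max(5, window | 1)  # odd, at least 5
    v = savgol_filter(v, window_length=window, polyorder=2, mode="wrap")

    q = v * area.area_m2 if area is not None else v
    if clip_negative:
        q = np.clip(q, 0.0, None)
    return FlowWaveform(cycle=target_cycle, t_s=grid, q_m3s=q)


def stroke_volume(w: FlowWaveform) -> float:
    """Ejected volume per beat: the trapezoidal integral of Q over one period,
    closing the cycle periodically at t = T."""
    T = w.cycle.period_s
    t = np.concatenate([w.t_s, [T]])
    q = np.concatenate([w.q_m3s, [w.q_m3s[0]]])
    return float(np.trapezoid(q, t))


def rescale_to_hr(w: FlowWaveform, new_hr_bpm: float) -> FlowWaveform:
    """Rescale a waveform to a new heart rate at constant stroke volume.

    The time axis scales with the new period and the amplitude scales
    inversely, so the shape as a function of cycle fraction is unchanged and
    the stroke volume is preserved to machine precision.
    """
    if not np.isfinite(new_hr_bpm) or new_hr_bpm <= 0:
        raise InputError(f"heart rate must be positive, got {new_hr_bpm}")
    new_cycle = replace(w.cycle, hr_bpm=float(new_hr_bpm))
    scale = w.cycle.hr_bpm / new_hr_bpm  # = T_new / T_old
    return FlowWaveform(
        cycle=new_cycle, t_s=w.t_s * scale, q_m3s=w.q_m3s / scale
    )


def parabolic_profile(w: FlowWaveform, geom: InletGeometry, t: float):
    """Parabolic (Poiseuille-shaped) inlet velocity profile at time ``t``.

    Returns a callable u(r) = 2 V̄(t) (1 - r²/R²) with V̄(t) = Q(t)/A, whose
    flux integral over the inlet disc reproduces Q(t) exactly.  ``t`` is
    wrapped by cycle periodicity; querying r > R raises :class:`InputError`.
    """
    vbar = float(w.q_at(t)) / geom.area_m2
    R = geom.radius_m

    def u(r):
        r = np.asarray(r, dtype=float)
        if np.any(r > R * (1 + 1e-12)) or np.any(r < 0):
            raise InputError(f"radial query outside inlet disc of radius {R:g}")
        return 2.0 * vbar * (1.0 - (r / R) ** 2)

    u.vbar = vbar
    u.radius_m = R
    return u


def peak_systole_time(w: FlowWaveform) -> tuple[float, float]:
    """Time and cycle fraction of peak inlet flow (global maximum of Q).

    Ties are broken by the earliest time.  A constant waveform has no unique
    peak and raises :class:`DegenerateInputError`.
    """
    q = w.q_m3s
    if np.ptp(q) == 0:
        raise DegenerateInputError("constant waveform has no unique peak")
    i = int(np.argmax(q))
    t_peak = float(w.t_s[i])
    return t_peak, t_peak / w.cycle.period_s
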