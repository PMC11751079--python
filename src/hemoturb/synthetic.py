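"""Synthetic pulsatile-jet data with analytically known ground truth.

The generator emulates the statistical structure of post-stenotic aortic
flow — a periodic pulsatile mean with peak systole at a fixed cycle
fraction, zero-phase-mean turbulent fluctuations whose intensity peaks
during systolic deceleration, a −5/3 inertial-range spectrum, and a wall
field with an eccentric high-shear impingement patch plus oscillatory
low-shear regions — without solving any flow equations.  Every statistic a
downstream stage computes (phase means, per-bin σ(t), TKE(t), the WSS
metric maps) is recorded as ground truth at construction, so pipeline
recovery can be checked against known values.

All randomness flows from a single seed through ``numpy.random.default_rng``
(PCG64); identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .phase import CycleEnsemble
from .spectral import VelocitySignal
from .waveform import CardiacCycle, FlowWaveform, InletGeometry
from .wss import SegmentMask, WallShearHistory, WallSurface

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "default_inlet_waveform",
    "make_tube_fixture",
    "make_velocity_ensemble",
    "make_wss_history",
    "make_probe_signal",
    "colored_noise",
]

#: Baseline study conditions: resting heart rate and inlet geometry.
BASELINE_HR_BPM = 120.0
INLET_AREA_M2 = 99.63e-6
PEAK_SYSTOLE_FRACTION = 0.16


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions: baseline 120 BPM, 50 phase bins,
    21 simulated cycles (20 analysed after discarding the first), peak
    systole at cycle fraction 0.16, turbulence intensity peaking during
    systolic deceleration (1.5× the peak-systole fraction), and a −5/3
    spectral slope target for the fluctuations.
    """

    seed: int = 0
    hr_bpm: float = BASELINE_HR_BPM
    n_cycles: int = 21
    n_phase_bins: int = 50
    samples_per_bin: int = 10
    peak_fraction: float = PEAK_SYSTOLE_FRACTION
    peak_inlet_velocity_ms: float = 1.5
    inlet_area_m2: float = INLET_AREA_M2
    turbulence_intensity: float = 0.2
    intensity_peak_fraction: float = 1.5 * PEAK_SYSTOLE_FRACTION
    spectral_slope: float = -5.0 / 3.0
    rho: float = 1060.0

    def __post_init__(self):
        for name in (
            "hr_bpm",
            "peak_inlet_velocity_ms",
            "inlet_area_m2",
        ):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.turbulence_intensity < 0:
            raise InputError("turbulence intensity must be non-negative")

    @property
    def cycle(self) -> CardiacCycle:
        return CardiacCycle(self.hr_bpm, self.n_phase_bins)

    @property
    def geometry(self) -> InletGeometry:
        return InletGeometry(self.inlet_area_m2)

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually imposed, for recovery checks."""

    phase_mean: np.ndarray | None = field(repr=False, default=None)
    sigma_t: np.ndarray | None = field(repr=False, default=None)
    tke_t: np.ndarray | None = field(repr=False, default=None)
    labels: np.ndarray | None = field(repr=False, default=None)
    expected: dict = field(default_factory=dict)


def _pulse_shape(x: np.ndarray, peak_fraction: float) -> np.ndarray:
    """Dimensionless one-cycle flow shape: half-cosine systolic rise to the
    peak, half-cosine fall to end systole (cycle fraction 0.45), a short
    diastolic backflow dip, and quiescent diastole."""
    x = np.asarray(x, dtype=float) % 1.0
    xe = 0.45  # end of systole as cycle fraction
    dip_len = 0.10
    s = np.zeros_like(x)
    rise = x <= peak_fraction
    s[rise] = 0.5 * (1 - np.cos(np.pi * x[rise] / peak_fraction))
    fall = (x > peak_fraction) & (x <= xe)
    s[fall] = 0.5 * (1 + np.cos(np.pi * (x[fall] - peak_fraction) / (xe - peak_fraction)))
    dip = (x > xe) & (x <= xe + dip_len)
    s[dip] = -0.12 * np.sin(np.pi * (x[dip] - xe) / dip_len)
    return s


def default_inlet_waveform(
    hr_bpm: float = BASELINE_HR_BPM,
    *,
    n_phase_bins: int = 50,
    samples_per_bin: int = 10,
    peak_fraction: float = PEAK_SYSTOLE_FRACTION,
    peak_inlet_velocity_ms: float = 1.5,
    area_m2: float = INLET_AREA_M2,
) -> FlowWaveform:
    """Canonical one-cycle inlet flow waveform.

    A smooth physiologic pulse with its global maximum exactly at cycle
    fraction ``peak_fraction`` (0.16 ⇒ peak at 0.08 s for the 120 BPM
    baseline), systolic ejection ending at 45% of the cycle, and a small
    diastolic backflow dip.  The amplitude is set by the peak inlet velocity
    times the inlet area.
    """
    cycle = CardiacCycle(hr_bpm, n_phase_bins)
    m = n_phase_bins * samples_per_bin
    t = np.arange(m) * (cycle.period_s / m)
    q = _pulse_shape(t / cycle.period_s, peak_fraction) * (
        peak_inlet_velocity_ms * area_m2
    )
    return FlowWaveform(cycle=cycle, t_s=t, q_m3s=q)


def colored_noise(
    rng: np.random.Generator,
    n: int,
    fs_hz: float,
    band_hz: tuple[float, float],
    slope: float = -5.0 / 3.0,
) -> np.ndarray:
    """Unit-variance Gaussian noise with E(f) ∝ f**slope inside a band.

    White Gaussian noise is shaped in the frequency domain by the transfer
    amplitude g(f) = f**(slope/2) inside ``band_hz`` and zero outside, then
    rescaled so the expected sample variance is exactly 1.  The expected ESD
    follows the target power law exactly; realisation-to-realisation scatter
    is the usual chi-squared spectral noise.
    """
    f_lo, f_hi = band_hz
    if not 0 < f_lo < f_hi:
        raise InputError("need 0 < f_lo < f_hi")
    if f_hi > fs_hz / 2:
        raise InputError("band extends beyond the Nyquist frequency")
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    g = np.zeros_like(freqs)
    sel = (freqs >= f_lo) & (freqs <= f_hi)
    g[sel] = freqs[sel] ** (slope / 2.0)
    if not np.any(sel):
        raise InputError("band contains no resolvable frequency bins")
    # expected output variance of white noise filtered by g, two-sided sum
    fold = np.full(freqs.size, 2.0)
    fold[0] = 1.0
    if n % 2 == 0:
        fold[-1] = 1.0
    var = np.sum(fold * g**2) / n
    w = rng.standard_normal(n)
    x = np.fft.irfft(np.fft.rfft(w) * g, n)
    return x / np.sqrt(var)


def _intensity_envelope(x: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """Turbulence-intensity envelope over the cycle: a floor plus a Gaussian
    bump centred in systolic deceleration (TKE lags KE)."""
    x = np.asarray(x, dtype=float) % 1.0
    bump = np.exp(-(((x - spec.intensity_peak_fraction) / 0.12) ** 2))
    return spec.turbulence_intensity * (0.15 + 0.85 * bump)


def make_velocity_ensemble(
    spec: SyntheticSpec,
    waveform: FlowWaveform | None = None,
    *,
    n_entities: int = 4,
    colored: bool = True,
    intensity_constant: float | None = None,
) -> tuple[CycleEnsemble, GroundTruth]:
    """Cycle-resolved 3-vector velocity ensemble at phase-bin resolution.

    Each entity (probe) carries a deterministic periodic streamwise velocity
    proportional to the inlet waveform, plus zero-mean Gaussian fluctuations
    with per-bin standard deviation σ(t) = I(t)·V̄(t) per component.  With
    ``colored=True`` the fluctuations are drawn from the −5/3-shaped
    generator (independent across cycles, entities, and components);
    ``intensity_constant`` overrides the deceleration-peaked envelope with a
    constant intensity.
    """
    cycle = spec.cycle
    if waveform is None:
        waveform = default_inlet_waveform(
            spec.hr_bpm,
            n_phase_bins=spec.n_phase_bins,
            samples_per_bin=spec.samples_per_bin,
            peak_fraction=spec.peak_fraction,
            peak_inlet_velocity_ms=spec.peak_inlet_velocity_ms,
            area_m2=spec.inlet_area_m2,
        )
    B = cycle.n_phase_bins
    xc = cycle.bin_centers / cycle.period_s
    vbar = waveform.q_at(cycle.bin_centers) / spec.inlet_area_m2  # (B,)

    # entity amplitude factors: stronger jet signal at downstream probes
    amp = np.linspace(0.6, 1.2, n_entities)
    mean = np.zeros((B, n_entities, 3))
    mean[:, :, 2] = vbar[:, None] * amp[None, :]  # streamwise ẑ

    if intensity_constant is not None:
        intensity = np.full(B, float(intensity_constant))
    else:
        intensity = _intensity_envelope(xc, spec)
    sigma = intensity[:, None] * np.abs(vbar)[:, None] * np.ones(n_entities)  # (B, E)

    rng = spec.rng(stream=1)
    fs = B / cycle.period_s
    noise = np.empty((spec.n_cycles, B, n_entities, 3))
    for n in range(spec.n_cycles):
        for e in range(n_entities):
            for k in range(3):
                if colored:
                    band = (fs / B * 2, fs / 2)  # resolvable band at bin rate
                    noise[n, :, e, k] = colored_noise(
                        rng, B, fs, band, spec.spectral_slope
                    )
                else:
                    noise[n, :, e, k] = rng.standard_normal(B)
    values = mean[None] + noise * sigma[None, :, :, None]
    truth = GroundTruth(
        phase_mean=mean,
        sigma_t=sigma,
        tke_t=0.5 * spec.rho * 3.0 * sigma**2,
        expected={"intensity": intensity, "vbar": vbar},
    )
    return CycleEnsemble(cycle, values), truth


def make_tube_fixture(
    radius_m: float = 0.008,
    length_m: float = 0.08,
    constriction_factor: float = 0.4,
    *,
    n_axial: int = 40,
    n_circ: int = 24,
) -> tuple[WallSurface, SegmentMask, np.ndarray]:
    """Straight tube with a smooth Gaussian constriction, as a stand-in for
    a coarcted aorta.

    The wall radius is r(z) = R·(1 − (1 − c)·exp(−((z − L/2)/(L/8))²)) with
    throat radius c·R at mid-length.  Returns the triangulated wall surface
    with outward unit normals, an equal-area front/back mask split by the
    x–z plane, and a centreline point cloud (z, local radius) for volume
    sampling.
    """
    if not 0 < constriction_factor <= 1:
        raise InputError("constriction factor must be in (0, 1]")
    if radius_m <= 0 or length_m <= 0 or n_axial < 2 or n_circ < 8:
        raise InputError("degenerate tube dimensions")

    z = np.linspace(0.0, length_m, n_axial + 1)
    r = radius_m * (
        1.0
        - (1.0 - constriction_factor)
        * np.exp(-(((z - length_m / 2) / (length_m / 8)) ** 2))
    )
    # half-bin azimuthal offset keeps element centres off the y = 0 plane
    theta = (np.arange(n_circ) + 0.5) * (2 * np.pi / n_circ)
    pts = np.empty(((n_axial + 1) * n_circ, 3))
    for j in range(n_axial + 1):
        pts[j * n_circ : (j + 1) * n_circ, 0] = r[j] * np.cos(theta)
        pts[j * n_circ : (j + 1) * n_circ, 1] = r[j] * np.sin(theta)
        pts[j * n_circ : (j + 1) * n_circ, 2] = z[j]

    tris = []
    for j in range(n_axial):
        for i in range(n_circ):
            a = j * n_circ + i
            b = j * n_circ + (i + 1) % n_circ
            c = (j + 1) * n_circ + i
            d = (j + 1) * n_circ + (i + 1) % n_circ
            tris.append([a, b, d])
            tris.append([a, d, c])
    tris = np.asarray(tris, dtype=int)

    surface = WallSurface.from_triangles(pts, tris)
    # orient normals outward (positive radial component at element centre)
    centers = surface.element_centers()
    radial = centers.copy()
    radial[:, 2] = 0.0
    rad_norm = np.linalg.norm(radial, axis=1, keepdims=True)
    outward = np.einsum("ek,ek->e", surface.normals, radial / rad_norm)
    flip = outward < 0
    if np.any(flip):
        tris_fixed = tris.copy()
        tris_fixed[flip] = tris_fixed[flip][:, ::-1]
        surface = WallSurface.from_triangles(pts, tris_fixed)

    labels = np.where(surface.element_centers()[:, 1] > 0, "front", "back")
    centreline = np.column_stack([np.zeros_like(z), np.zeros_like(z), z, r])
    return surface, SegmentMask(labels), centreline


def make_wss_history(
    spec: SyntheticSpec,
    surface: WallSurface,
    *,
    tau_patch_pa: float = 30.0,
    tau_osc_pa: float = 5.0,
    tau_switch_pa: float = 8.0,
    tau_base_pa: float = 2.0,
    noise_pa: float = 0.0,
) -> tuple[WallShearHistory, GroundTruth]:
    """Tangential WSS history with regions of analytically known metrics.

    Regions on the tube (by element centre z, L = tube length):

    * ``patch`` (0.55L–0.75L, front): constant unidirectional axial shear
      ``tau_patch_pa`` — jet impingement.  OSI 0, TransWSS 0, TAWSS = τ.
    * ``oscillation`` (same band, back): symmetric ± reversal of axial shear
      ``tau_osc_pa`` — OSI exactly 0.5; TransWSS undefined (zero mean).
    * ``switching`` (0.78L–0.90L): axial for the first half cycle,
      circumferential for the second, magnitude ``tau_switch_pa`` —
      TransWSS = τ/√2, OSI = ½(1 − 1/√2).
    * ``base`` elsewhere: weak unidirectional axial shear ``tau_base_pa``.

    ``noise_pa`` adds zero-mean Gaussian fluctuations (per tangent-plane
    component, σ = noise_pa) across cycles; the noise-free expectations are
    returned in the ground truth.
    """
    cycle = spec.cycle
    B = cycle.n_phase_bins
    if B % 2:
        raise InputError("symmetric-reversal regions need an even bin count")
    N = spec.n_cycles
    E = surface.n_elements
    centers = surface.element_centers()
    z = centers[:, 2]
    L = z.max()
    nrm = surface.normals
    zhat = np.array([0.0, 0.0, 1.0])
    axial = zhat[None, :] - nrm * nrm[:, 2:3]
    axial /= np.linalg.norm(axial, axis=1, keepdims=True)
    circ = np.cross(nrm, axial)

    labels = np.full(E, "base", dtype=object)
    in_band = (z > 0.55 * L) & (z < 0.75 * L)
    labels[in_band & (centers[:, 1] > 0)] = "patch"
    labels[in_band & (centers[:, 1] <= 0)] = "oscillation"
    labels[(z > 0.78 * L) & (z < 0.90 * L)] = "switching"

    half = np.ones(B)
    half[B // 2 :] = -1.0  # +1 first half cycle, −1 second half

    mean = np.zeros((B, E, 3))
    for e in range(E):
        lab = labels[e]
        if lab == "patch":
            mean[:, e, :] = tau_patch_pa * axial[e]
        elif lab == "oscillation":
            mean[:, e, :] = half[:, None] * tau_osc_pa * axial[e]
        elif lab == "switching":
            first = half > 0
            mean[first, e, :] = tau_switch_pa * axial[e]
            mean[~first, e, :] = tau_switch_pa * circ[e]
        else:
            mean[:, e, :] = tau_base_pa * axial[e]

    wss = np.broadcast_to(mean, (N, B, E, 3)).copy()
    if noise_pa > 0:
        rng = spec.rng(stream=2)
        n1 = rng.standard_normal((N, B, E)) * noise_pa
        n2 = rng.standard_normal((N, B, E)) * noise_pa
        wss = wss + n1[..., None] * axial[None, None] + n2[..., None] * circ[None, None]

    expected_tawss = np.where(
        labels == "patch",
        tau_patch_pa,
        np.where(
            labels == "oscillation",
            tau_osc_pa,
            np.where(labels == "switching", tau_switch_pa, tau_base_pa),
        ),
    ).astype(float)
    expected_osi = np.where(
        labels == "oscillation",
        0.5,
        np.where(labels == "switching", 0.5 * (1 - 1 / np.sqrt(2)), 0.0),
    )
    expected_transwss = np.where(
        labels == "switching",
        tau_switch_pa / np.sqrt(2),
        np.where(labels == "oscillation", np.nan, 0.0),
    )
    truth = GroundTruth(
        phase_mean=mean,
        sigma_t=np.full((B, E), float(noise_pa)),
        labels=labels,
        expected={
            "tawss": expected_tawss,
            "osi": expected_osi,
            "transwss": expected_transwss,
        },
    )
    history = WallShearHistory(
        surface=surface, wss=wss, cycle=cycle, tangency_tol=1e-6
    )
    return history, truth


def make_probe_signal(
    spec: SyntheticSpec,
    *,
    fs_hz: float = 10_000.0,
    n_cycles: int = 20,
    harmonic_amps: tuple[float, ...] = (1.0, 0.5, 0.25),
    noise_band_hz: tuple[float, float] = (20.0, 2000.0),
    noise_rms: float = 0.2,
) -> tuple[VelocitySignal, GroundTruth]:
    """Probe-style velocity signal: heart-rate fundamental plus harmonics
    plus band-limited −5/3 turbulence.

    Harmonic k has amplitude ``harmonic_amps[k-1]`` at k·HR/60 Hz; the noise
    floor has RMS ``noise_rms`` with E(f) ∝ f^slope inside ``noise_band_hz``.
    Raises on aliasing (band beyond Nyquist).  Set ``harmonic_amps=()`` or
    ``noise_rms=0`` for pure-noise / pure-tone variants.
    """
    if noise_band_hz[1] > fs_hz / 2:
        raise InputError("noise band exceeds the Nyquist frequency")
    f0 = spec.hr_bpm / 60.0
    T_total = n_cycles * 60.0 / spec.hr_bpm
    n = int(round(T_total * fs_hz))
    t = np.arange(n) / fs_hz
    u = np.zeros(n)
    for k, a in enumerate(harmonic_amps, start=1):
        u += a * np.sin(2 * np.pi * k * f0 * t)
    if noise_rms > 0:
        u += noise_rms * colored_noise(
            spec.rng(stream=3), n, fs_hz, noise_band_hz, spec.spectral_slope
        )
    harmonic_energy = {
        k: a**2 / 2 * n for k, a in enumerate(harmonic_amps, start=1)
    }
    truth = GroundTruth(
        expected={
            "f0_hz": f0,
            "harmonic_energy": harmonic_energy,
            "noise_rms": noise_rms,
            "noise_band_hz": noise_band_hz,
            "slope": spec.spectral_slope,
        }
    )
    return VelocitySignal(fs_hz=fs_hz, samples=u), truth
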