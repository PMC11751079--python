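"""Phase-averaged (triple-decomposition) turbulence statistics.

In a pulsatile turbulent flow, a quantity φ sampled over many cardiac cycles
splits into a long-time mean, a deterministic periodic pulsation, and a
turbulent cycle-to-cycle fluctuation:

    φ_n(t) = φ_avg + φ̃(t) + φ'_n(t),     ⟨φ⟩(t) = φ_avg + φ̃(t)

where ⟨φ⟩(t) is the phase average — the mean over cycles at fixed phase t —
and the fluctuation amplitude is its per-phase root-mean-square (population
form, 1/N).  Mean and turbulent kinetic energy per unit volume follow as

    KE(t)  = ρ/2 ⟨u⟩(t)·⟨u⟩(t),      TKE(t) = ρ/2 Σ_i ⟨u_i'⟩(t)²

and obey the per-phase identity ⟨ρ/2 u·u⟩ = KE + TKE exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, StatisticsError
from .waveform import CardiacCycle

__all__ = [
    "CycleEnsemble",
    "PhaseStats",
    "EnergySeries",
    "bin_cycles",
    "phase_mean",
    "phase_rms",
    "triple_decompose",
    "kinetic_energies",
    "convergence_check",
]


@dataclass(frozen=True)
class CycleEnsemble:
    """A quantity sampled over N cycles at aligned phase bins.

    ``values`` has shape (N, B, E) for scalars or (N, B, E, 3) for vectors:
    N cycles, B phase bins, E entities (probes, mesh nodes, or surface
    elements).
    """

    cycle: CardiacCycle
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim not in (3, 4) or (v.ndim == 4 and v.shape[3] != 3):
            raise InputError(
                "values must have shape (N, B, E) or (N, B, E, 3), "
                f"got {v.shape}"
            )
        if v.shape[1] != self.cycle.n_phase_bins:
            raise InputError(
                f"phase-bin axis {v.shape[1]} does not match the cycle's "
                f"{self.cycle.n_phase_bins} bins"
            )

    @property
    def n_cycles(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def n_entities(self) -> int:
        return self.values.shape[2]

    @property
    def is_vector(self) -> bool:
        return self.values.ndim == 4

    def truncated(self, n_cycles: int) -> "CycleEnsemble":
        """Sub-ensemble of the first ``n_cycles`` cycles."""
        return CycleEnsemble(self.cycle, self.values[:n_cycles])


@dataclass(frozen=True)
class PhaseStats:
    """Phase-averaged mean, fluctuation RMS, and long-time mean."""

    cycle: CardiacCycle
    phase_mean: np.ndarray = field(repr=False)
    phase_rms: np.ndarray | None = field(repr=False, default=None)
    long_time_mean: np.ndarray | None = field(repr=False, default=None)


@dataclass(frozen=True)
class EnergySeries:
    """KE and TKE per phase bin (Pa = J/m³), or volume-integrated (J)."""

    cycle: CardiacCycle
    ke_t: np.ndarray = field(repr=False)
    tke_t: np.ndarray = field(repr=False)
    rho: float = 1060.0


def bin_cycles(
    t_s: np.ndarray,
    x: np.ndarray,
    cycle: CardiacCycle,
    discard_first: bool = True,
) -> CycleEnsemble:
    """Assign a time series to (cycle, phase-bin) cells and average within bins.

    Samples are placed by ``t mod T`` into half-open bins, so a sample at
    exactly t = T lands in bin 0 of the next cycle.  The first cycle is
    dropped when ``discard_first`` (transient removal) and any incomplete
    trailing cycle is dropped.  Multiple samples within one bin of one cycle
    are averaged before cross-cycle statistics.

    ``x`` may be (M,), (M, E), or (M, E, 3) for M time samples.
    """
    t_s = np.asarray(t_s, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != t_s.size:
        raise InputError("time and value arrays disagree in length")
    T = cycle.period_s
    B = cycle.n_phase_bins

    cyc_idx = np.floor(t_s / T + 1e-12).astype(int)
    phase = t_s - cyc_idx * T
    bin_idx = np.clip(np.floor(phase / T * B + 1e-9).astype(int), 0, B - 1)

    first = 1 if discard_first else 0
    n_full = 0
    counts_by_cycle = {}
    for c in range(first, cyc_idx.max() + 1):
        sel = cyc_idx == c
        filled = np.unique(bin_idx[sel])
        if filled.size == B:
            counts_by_cycle[c] = sel
            n_full += 1
        else:
            break  # trailing partial cycle
    if n_full < 2:
        raise InputError(
            f"need at least 2 complete cycles after discard, got {n_full}"
        )

    tail = x.shape[1:]
    out = np.zeros((n_full, B) + tail)
    for row, (c, sel) in enumerate(counts_by_cycle.items()):
        b = bin_idx[sel]
        xv = x[sel]
        counts = np.bincount(b, minlength=B)
        for axis_idx in np.ndindex(tail):
            out[(row, slice(None)) + axis_idx] = (
                np.bincount(
                    b, weights=xv[(slice(None),) + axis_idx], minlength=B
                )
                / counts
            )
    return CycleEnsemble(cycle, out)


def phase_mean(e: CycleEnsemble) -> PhaseStats:
    """Per-bin arithmetic mean over cycles (the phase average ⟨φ⟩(t))."""
    pm = e.values.mean(axis=0)
    return PhaseStats(e.cycle, phase_mean=pm, long_time_mean=pm.mean(axis=0))


def phase_rms(e: CycleEnsemble) -> PhaseStats:
    """Per-bin RMS of deviations from the per-bin mean (population form,
    denominator N), component-wise for vector ensembles."""
    if e.n_cycles < 2:
        raise StatisticsError("fluctuation statistics need at least 2 cycles")
    pm = e.values.mean(axis=0)
    rms = np.sqrt(np.mean((e.values - pm) ** 2, axis=0))
    return PhaseStats(e.cycle, phase_mean=pm, phase_rms=rms)


def triple_decompose(
    e: CycleEnsemble,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split an ensemble into long-time mean, periodic pulsation, and
    per-cycle residual fluctuation.

    Returns ``(phi_avg, phi_tilde, residuals)`` with shapes (E, ...),
    (B, E, ...), and (N, B, E, ...).  Reconstruction
    ``phi_avg + phi_tilde + residuals`` equals the input at machine
    precision, and residuals have exactly zero per-bin mean.
    """
    if e.n_cycles < 2:
        raise StatisticsError("triple decomposition needs at least 2 cycles")
    pm = e.values.mean(axis=0)
    phi_avg = pm.mean(axis=0)
    phi_tilde = pm - phi_avg
    residuals = e.values - pm
    return phi_avg, phi_tilde, residuals


def kinetic_energies(
    e: CycleEnsemble,
    rho: float = 1060.0,
    cell_volumes: np.ndarray | None = None,
) -> EnergySeries:
    """Phase-resolved mean and turbulent kinetic energy of a velocity ensemble.

    KE(t) = ρ/2 |⟨u⟩(t)|² and TKE(t) = ρ/2 Σ_i rms_i(t)² per entity, in Pa.
    With ``cell_volumes`` (shape (E,)) both are volume-integrated to a single
    series per phase bin, in J.
    """
    if not e.is_vector:
        raise InputError("kinetic energies require a 3-vector ensemble")
    pm = e.values.mean(axis=0)  # (B, E, 3)
    ke = 0.5 * rho * np.sum(pm**2, axis=-1)  # (B, E)
    if e.n_cycles >= 2:
        var = np.mean((e.values - pm) ** 2, axis=0)  # population variance
        tke = 0.5 * rho * np.sum(var, axis=-1)
    else:
        tke = np.zeros_like(ke)
    if cell_volumes is not None:
        vol = np.asarray(cell_volumes, dtype=float)
        ke = ke @ vol
        tke = tke @ vol
    return EnergySeries(e.cycle, ke_t=ke, tke_t=tke, rho=rho)


def convergence_check(
    e: CycleEnsemble,
    peak_bin: int,
    rho: float = 1060.0,
    tol: float = 0.01,
    cell_volumes: np.ndarray | None = None,
) -> dict:
    """Cycle-count convergence of phase-averaged KE and TKE at peak systole.

    Compares the ensemble of the first N−1 cycles against all N cycles: the
    relative change of KE and TKE at ``peak_bin`` (entity-summed, or
    volume-integrated when ``cell_volumes`` is given) must both be below
    ``tol`` (default 1%) to pass.
    """
    if e.n_cycles < 3:
        raise StatisticsError("convergence check needs at least 3 cycles")

    def at_peak(sub):
        es = kinetic_energies(sub, rho=rho, cell_volumes=cell_volumes)
        ke, tke = es.ke_t[peak_bin], es.tke_t[peak_bin]
        if np.ndim(ke) > 0:
            ke, tke = float(np.sum(ke)), float(np.sum(tke))
        return float(ke), float(tke)

    ke_prev, tke_prev = at_peak(e.truncated(e.n_cycles - 1))
    ke_now, tke_now = at_peak(e)

    def rel_change(prev, now):
        if prev == 0:
            if now == 0:
                return 0.0  # identically zero energy has trivially converged
            raise InputError("zero reference energy: relative change undefined")
        return abs(now - prev) / abs(prev)

    dke = rel_change(ke_prev, ke_now)
    dtke = rel_change(tke_prev, tke_now)
    return {
        "ke_rel_change": dke,
        "tke_rel_change": dtke,
        "passed": bool(dke < tol and dtke < tol),
        "n_cycles": e.n_cycles,
    }
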