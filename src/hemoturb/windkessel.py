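"""Three-element Windkessel (3EWK) outlet models: simulation and calibration.

Each outlet is a lumped RCR circuit: a proximal (characteristic) resistance
in series with a parallel distal resistance / compliance pair, referenced to
a downstream pressure.  Outlet pressure follows

    p(t) = p_dist(t) + q(t) * r_prox + p_out
    c_art * dp_dist/dt = q(t) - p_dist(t) / r_dist

Calibration distributes a total peripheral resistance, set by a target mean
arterial pressure and the mean inflow, across outlets in inverse proportion
to their target flow fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, InputError
from .waveform import FlowWaveform

__all__ = [
    "MMHG_PA",
    "WindkesselParams",
    "OutletSet",
    "WindkesselSolution",
    "integrate_cycle",
    "simulate_pressure",
    "cycle_flow_fractions",
    "split_flows",
    "calibrate",
    "map_from_sys_dia",
]

#: Pascals per millimetre of mercury.
MMHG_PA = 133.322


def map_from_sys_dia(systolic_mmhg: float, diastolic_mmhg: float) -> float:
    """Mean arterial pressure (mmHg) from a systolic/diastolic pair,
    MAP = diastolic + pulse pressure / 3."""
    return diastolic_mmhg + (systolic_mmhg - diastolic_mmhg) / 3.0


@dataclass(frozen=True)
class WindkesselParams:
    """RCR parameters in SI units (Pa·s/m³ for resistances, m³/Pa for
    compliance, Pa for the reference pressure)."""

    r_prox: float
    r_dist: float
    c_art: float
    p_out: float = 0.0

    def __post_init__(self):
        if self.r_prox < 0:
            raise InputError("proximal resistance must be non-negative")
        if self.r_dist <= 0 or self.c_art <= 0:
            raise InputError("distal resistance and compliance must be positive")

    @property
    def r_total(self) -> float:
        return self.r_prox + self.r_dist

    @property
    def tau_s(self) -> float:
        """RC decay constant of the distal compartment."""
        return self.r_dist * self.c_art


@dataclass(frozen=True)
class OutletSet:
    """Named, calibrated outlets with their target flow fractions."""

    outlets: dict[str, WindkesselParams]
    target_splits: dict[str, float]

    def __post_init__(self):
        if set(self.outlets) != set(self.target_splits):
            raise InputError("outlet names and split names must match")
        total = sum(self.target_splits.values())
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"target splits must sum to 1, got {total:g}")

    @property
    def names(self) -> list[str]:
        return list(self.outlets)


@dataclass(frozen=True)
class WindkesselSolution:
    """Periodic-steady-state pressure over the final simulated cycle."""

    t_s: np.ndarray
    p_pa: np.ndarray
    p_dist_pa: np.ndarray
    n_cycles_run: int
    converged: bool

    @property
    def mean_pa(self) -> float:
        return float(np.mean(self.p_pa))

    @property
    def pulse_pa(self) -> float:
        return float(np.ptp(self.p_pa))


def integrate_cycle(
    params: WindkesselParams, q: FlowWaveform, p_dist0: float
) -> tuple[np.ndarray, float]:
    """Integrate the distal-compartment ODE over one cycle.

    Implicit trapezoidal scheme with fixed step equal to the waveform sample
    spacing (A-stable, safe for stiff RC systems).  Returns the distal
    pressure at the waveform sample times t_0..t_{M-1} (with
    ``p_dist[0] == p_dist0``) and the end-of-cycle state at t = T.
    """
    T = q.cycle.period_s
    qs = np.concatenate([q.q_m3s, [q.q_m3s[0]]])  # periodic closure
    dt = np.diff(np.concatenate([q.t_s, [T]]))
    c, rd = params.c_art, params.r_dist

    p_dist = np.empty(q.n_samples)
    pd = float(p_dist0)
    p_dist[0] = pd
    for k in range(q.n_samples):
        h = dt[k]
        # trapezoidal: c (pd1 - pd0)/h = ((q0 - pd0/rd) + (q1 - pd1/rd))/2
        a = c / h + 0.5 / rd
        b = c / h - 0.5 / rd
        pd = (b * pd + 0.5 * (qs[k] + qs[k + 1])) / a
        if k + 1 < q.n_samples:
            p_dist[k + 1] = pd
    return p_dist, pd


def simulate_pressure(
    params: WindkesselParams,
    q: FlowWaveform,
    n_cycles: int = 100,
    *,
    rel_tol: float = 1e-3,
    p_dist0: float | None = None,
) -> WindkesselSolution:
    """Integrate the 3EWK ODE to periodic steady state.

    Cycles are repeated until the cycle-mean pressure changes by less than
    ``rel_tol`` (default 0.1%) between consecutive cycles; exceeding
    ``n_cycles`` raises :class:`ConvergenceError`.  By default the integration
    starts from the steady state of the mean inflow, which makes the
    transient short.
    """
    if n_cycles < 1:
        raise InputError("n_cycles must be at least 1")
    pd0 = (
        float(np.mean(q.q_m3s)) * params.r_dist if p_dist0 is None else float(p_dist0)
    )
    prev_mean = None
    history = []
    for cyc in range(1, n_cycles + 1):
        p_dist, pd_end = integrate_cycle(params, q, pd0)
        p = p_dist + q.q_m3s * params.r_prox + params.p_out
        mean_p = float(np.mean(p))
        history.append(mean_p)
        if prev_mean is not None and abs(mean_p - prev_mean) <= rel_tol * abs(prev_mean):
            return WindkesselSolution(q.t_s, p, p_dist, cyc, True)
        prev_mean = mean_p
        pd0 = pd_end
    raise ConvergenceError(
        f"Windkessel mean pressure not periodic to {rel_tol:.1%} "
        f"within {n_cycles} cycles",
        diagnostics={"mean_pressure_history": history},
    )


def split_flows(outlets: OutletSet, q_in: FlowWaveform) -> dict[str, FlowWaveform]:
    """Distribute inflow across outlets by the lumped resistance network.

    Uses the equal-pressure-node approximation: at each instant every outlet
    sees the same node pressure, so flows divide in proportion to branch
    conductance 1/(r_prox + r_dist).  Summed outflow equals inflow exactly.
    """
    g = np.array([1.0 / outlets.outlets[n].r_total for n in outlets.names])
    frac = g / g.sum()
    return {
        name: FlowWaveform(q_in.cycle, q_in.t_s, q_in.q_m3s * f)
        for name, f in zip(outlets.names, frac)
    }


def calibrate(
    q_in: FlowWaveform,
    map_target_pa: float,
    splits: dict[str, float],
    *,
    p_out_pa: float = 0.0,
    r_prox_fraction: float = 0.05,
    tau_s: float = 1.0,
) -> OutletSet:
    """Calibrate an outlet set to a target mean arterial pressure and flow split.

    Total peripheral resistance is R_tot = (MAP - p_out) / mean(Q); each
    outlet gets R_i = R_tot / split_i so the conductance-weighted split
    reproduces the targets.  Within each outlet, ``r_prox_fraction`` of R_i
    is proximal (characteristic-impedance heuristic) and the compliance is
    set from the distal decay constant ``tau_s`` = r_dist · c_art.
    """
    if abs(sum(splits.values()) - 1.0) > 1e-9:
        raise InputError("splits must sum to 1")
    if any(s <= 0 for s in splits.values()):
        raise InputError("every split fraction must be positive")
    if map_target_pa <= p_out_pa:
        raise InputError("target MAP must exceed the reference pressure")
    mean_q = float(np.mean(q_in.q_m3s))
    if mean_q == 0:
        raise InputError("zero mean inflow: resistance undefined")

    r_tot = (map_target_pa - p_out_pa) / mean_q
    outlets = {}
    for name, s in splits.items():
        r_i = r_tot / s
        r_prox = r_prox_fraction * r_i
        r_dist = r_i - r_prox
        outlets[name] = WindkesselParams(
            r_prox=r_prox, r_dist=r_dist, c_art=tau_s / r_dist, p_out=p_out_pa
        )
    return OutletSet(outlets=outlets, target_splits=dict(splits))


def cycle_flow_fractions(
    outlets: OutletSet, q_in: FlowWaveform
) -> dict[str, float]:
    """Cycle-integrated outflow fraction per outlet from a re-simulated split."""
    flows = split_flows(outlets, q_in)
    from .waveform import stroke_volume

    vol = {name: stroke_volume(w) for name, w in flows.items()}
    total = sum(vol.values())
    return {name: v / total for name, v in vol.items()}
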