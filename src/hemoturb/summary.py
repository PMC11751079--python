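"""Clinically framed scalar summaries of a coarctation run.

Covers trans-stenotic pressure drops (with the 20 mmHg intervention
threshold flag), coarctation-site Reynolds numbers, turbulence energy and
wall-shear ratios, and percent-change reports across heart rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .windkessel import MMHG_PA

__all__ = [
    "INTERVENTION_THRESHOLD_MMHG",
    "PressureDropResult",
    "pressure_drop_series",
    "reynolds_numbers",
    "energy_ratios",
    "cross_hr_report",
    "pa_to_mmhg",
    "mmhg_to_pa",
]

#: Trans-coarctation peak pressure drop above which intervention is indicated.
INTERVENTION_THRESHOLD_MMHG = 20.0


def pa_to_mmhg(p_pa):
    return np.asarray(p_pa, dtype=float) / MMHG_PA


def mmhg_to_pa(p_mmhg):
    return np.asarray(p_mmhg, dtype=float) * MMHG_PA


@dataclass(frozen=True)
class PressureDropResult:
    """Signed pressure-drop series (upstream minus downstream) in mmHg."""

    pd_mmhg: np.ndarray = field(repr=False)
    max_mmhg: float = 0.0
    t_max_index: int = 0
    exceeds_threshold: bool = False

    @property
    def zero_referenced(self) -> np.ndarray:
        """Series shifted so its minimum is zero (display convention)."""
        return self.pd_mmhg - self.pd_mmhg.min()


def pressure_drop_series(
    p_upstream_pa: np.ndarray,
    p_downstream_pa: np.ndarray,
    threshold_mmhg: float = INTERVENTION_THRESHOLD_MMHG,
) -> PressureDropResult:
    """PD(t) = p_upstream − p_downstream across a probe pair, in mmHg.

    Positive values are a drop across the constriction.  The result flags
    whether the peak drop exceeds the intervention threshold (default
    20 mmHg).  Both series must share one phase grid.
    """
    pa = np.asarray(p_upstream_pa, dtype=float)
    pb = np.asarray(p_downstream_pa, dtype=float)
    if pa.shape != pb.shape:
        raise InputError("probe series are not on the same grid")
    pd_mmhg = pa_to_mmhg(pa - pb)
    i = int(np.argmax(pd_mmhg))
    mx = float(pd_mmhg[i])
    return PressureDropResult(
        pd_mmhg=pd_mmhg,
        max_mmhg=mx,
        t_max_index=i,
        exceeds_threshold=mx > threshold_mmhg,
    )


def reynolds_numbers(
    velocity_ms: np.ndarray, radius_m: float, nu_m2s: float
) -> tuple[float, float]:
    """Mean and peak Reynolds number Re = U r / ν at the coarctation site.

    ``velocity_ms`` is the phase series of site velocity magnitude; the mean
    Re uses its cycle average and the max Re its peak-systolic value.  The
    length scale is the local radius (a diameter-based convention simply
    doubles both numbers).
    """
    if radius_m <= 0:
        raise InputError("radius must be positive")
    if nu_m2s <= 0:
        raise InputError("kinematic viscosity must be positive")
    v = np.abs(np.asarray(velocity_ms, dtype=float))
    return (
        float(v.mean() * radius_m / nu_m2s),
        float(v.max() * radius_m / nu_m2s),
    )


def energy_ratios(
    ke: float, tke: float, pawss_total: float = None, turwss_total: float = None
) -> dict:
    """Turbulence fractions: TKE/(TKE+KE) and TurWSS/(TurWSS+PAWSS).

    Inputs are absolute (non-negative) integral quantities; a zero
    denominator raises :class:`InputError`.
    """
    ke, tke = abs(float(ke)), abs(float(tke))
    if ke + tke == 0:
        raise InputError("zero total energy: ratio undefined")
    out = {"tke_fraction": tke / (tke + ke)}
    if pawss_total is not None and turwss_total is not None:
        p, t = abs(float(pawss_total)), abs(float(turwss_total))
        if p + t == 0:
            raise InputError("zero total WSS: ratio undefined")
        out["turwss_fraction"] = t / (t + p)
    return out


def cross_hr_report(records: dict[float, dict[str, float]]) -> pd.DataFrame:
    """Percent changes of each metric between the lowest and highest HR.

    ``records`` maps heart rate (BPM) to a dict of metric values.  For every
    metric present at both extremes the report carries the raw values and
    the percent change in both directions — low→high (increase with HR) and
    high→low (change when HR is reduced) — rounded to integer percent for
    printing, with the raw floats retained.  Metrics missing at either
    extreme are flagged and carry NaN changes.
    """
    if len(records) < 2:
        raise InputError("need records at two or more heart rates")
    hr_lo, hr_hi = min(records), max(records)
    lo, hi = records[hr_lo], records[hr_hi]
    rows = []
    for metric in sorted(set(lo) | set(hi)):
        if metric not in lo or metric not in hi:
            rows.append(
                {
                    "metric": metric,
                    "hr_low": hr_lo,
                    "hr_high": hr_hi,
                    "value_low": lo.get(metric, np.nan),
                    "value_high": hi.get(metric, np.nan),
                    "pct_low_to_high": np.nan,
                    "pct_high_to_low": np.nan,
                    "pct_low_to_high_rounded": np.nan,
                    "pct_high_to_low_rounded": np.nan,
                    "missing": True,
                }
            )
            continue
        a, b = float(lo[metric]), float(hi[metric])
        up = (b - a) / a * 100.0 if a != 0 else np.nan
        down = (a - b) / b * 100.0 if b != 0 else np.nan
        rows.append(
            {
                "metric": metric,
                "hr_low": hr_lo,
                "hr_high": hr_hi,
                "value_low": a,
                "value_high": b,
                "pct_low_to_high": up,
                "pct_high_to_low": down,
                "pct_low_to_high_rounded": int(round(up)) if np.isfinite(up) else np.nan,
                "pct_high_to_low_rounded": int(round(down)) if np.isfinite(down) else np.nan,
                "missing": False,
            }
        )
    return pd.DataFrame(rows).set_index("metric")
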