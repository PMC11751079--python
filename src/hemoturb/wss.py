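"""Wall-shear-stress metric family for pulsatile turbulent flow.

All metrics operate on phase-averaged wall shear vector histories on a
triangulated wall surface:

* **PAWSS** — magnitude of the cross-cycle mean WSS vector at each phase.
* **TurWSS** — magnitude of the component-wise RMS of cycle-to-cycle WSS
  fluctuations about the phase mean (population form).
* **TAWSS** — cycle-time average of PAWSS.
* **TransWSS** — time average of the WSS component perpendicular, within the
  tangent plane, to the time-mean WSS direction; captures multidirectional
  ("disturbed") shear that TAWSS cancels out.
* **OSI** — ½(1 − |time-mean WSS vector| / time-mean |WSS vector|), 0 for
  unidirectional shear, 0.5 for perfectly reversing shear.

Elements whose time-mean WSS vector vanishes have no preferred direction;
TransWSS and OSI are reported as NaN (missing) there rather than zero, so
spatial averages are not biased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, StatisticsError
from .waveform import CardiacCycle

__all__ = [
    "WallSurface",
    "WallShearHistory",
    "WSSMetricMaps",
    "SegmentMask",
    "wss_from_near_wall_gradient",
    "pawss",
    "turwss",
    "tawss",
    "transwss",
    "osi",
    "compute_metric_maps",
    "segment_average",
]


@dataclass(frozen=True)
class WallSurface:
    """Triangulated wall surface with per-element areas and outward normals."""

    points: np.ndarray = field(repr=False)
    triangles: np.ndarray = field(repr=False)
    areas: np.ndarray = field(repr=False)
    normals: np.ndarray = field(repr=False)

    def __post_init__(self):
        n = np.asarray(self.normals, dtype=float)
        a = np.asarray(self.areas, dtype=float)
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float))
        object.__setattr__(self, "triangles", np.asarray(self.triangles, dtype=int))
        object.__setattr__(self, "areas", a)
        object.__setattr__(self, "normals", n)
        if np.any(a <= 0):
            raise InputError("element areas must be positive")
        norms = np.linalg.norm(n, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise InputError("normals must be unit vectors")

    @property
    def n_elements(self) -> int:
        return self.triangles.shape[0]

    @classmethod
    def from_triangles(cls, points, triangles) -> "WallSurface":
        """Compute areas and (right-hand-rule) unit normals from connectivity."""
        points = np.asarray(points, dtype=float)
        triangles = np.asarray(triangles, dtype=int)
        p0, p1, p2 = (points[triangles[:, k]] for k in range(3))
        cross = np.cross(p1 - p0, p2 - p0)
        doubled = np.linalg.norm(cross, axis=1)
        if np.any(doubled <= 0):
            raise InputError("degenerate triangle (zero area)")
        return cls(points, triangles, doubled / 2.0, cross / doubled[:, None])

    def element_centers(self) -> np.ndarray:
        return self.points[self.triangles].mean(axis=1)


@dataclass(frozen=True)
class WallShearHistory:
    """WSS vectors (Pa) per (cycle, phase bin, element) on a wall surface."""

    surface: WallSurface
    wss: np.ndarray = field(repr=False)
    cycle: CardiacCycle = None
    tangency_tol: float = 1e-6

    def __post_init__(self):
        w = np.asarray(self.wss, dtype=float)
        object.__setattr__(self, "wss", w)
        if w.ndim != 4 or w.shape[3] != 3:
            raise InputError(f"wss must have shape (N, B, E, 3), got {w.shape}")
        if w.shape[2] != self.surface.n_elements:
            raise InputError("element axis does not match the surface")
        normal_cmp = np.abs(np.einsum("nbek,ek->nbe", w, self.surface.normals))
        mag = np.linalg.norm(w, axis=-1)
        bad = normal_cmp > self.tangency_tol * np.maximum(mag, 1e-300)
        if np.any(bad & (mag > 0)):
            raise InputError(
                "WSS vectors are not tangent to the wall within tolerance"
            )

    @property
    def n_cycles(self) -> int:
        return self.wss.shape[0]

    @property
    def n_bins(self) -> int:
        return self.wss.shape[1]

    def phase_mean_wss(self) -> np.ndarray:
        """Cross-cycle mean WSS vector per (bin, element), shape (B, E, 3)."""
        return self.wss.mean(axis=0)


@dataclass(frozen=True)
class WSSMetricMaps:
    """The full metric family on one surface.

    ``pawss``/``turwss`` are (B, E) phase-resolved maps; ``tawss``,
    ``transwss``, ``osi`` are per-element scalars (NaN where undefined).
    """

    surface: WallSurface
    pawss: np.ndarray = field(repr=False)
    turwss: np.ndarray = field(repr=False)
    tawss: np.ndarray = field(repr=False)
    transwss: np.ndarray = field(repr=False)
    osi: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class SegmentMask:
    """Per-element segment labels (e.g. 'front' / 'back' / 'none')."""

    labels: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "labels", np.asarray(self.labels))

    def segment_names(self) -> list[str]:
        return [str(s) for s in np.unique(self.labels) if str(s) != "none"]

    def area(self, surface: WallSurface, name: str) -> float:
        return float(surface.areas[self.labels == name].sum())


def wss_from_near_wall_gradient(
    velocity: np.ndarray,
    wall_distance: float,
    nu: float,
    rho: float,
    normals: np.ndarray,
) -> np.ndarray:
    """First-order one-sided WSS estimate from wall-adjacent velocity.

    τ = ρ ν u_t / y with u_t the velocity projected onto the tangent plane
    of each element and y the wall-normal distance of the sample point.
    ``velocity`` has shape (..., E, 3) matching ``normals`` (E, 3); output
    is in Pa with the same shape.
    """
    if wall_distance <= 0:
        raise InputError("wall distance must be positive")
    v = np.asarray(velocity, dtype=float)
    n = np.asarray(normals, dtype=float)
    v_t = v - np.einsum("...ek,ek->...e", v, n)[..., None] * n
    return rho * nu * v_t / wall_distance


def pawss(h: WallShearHistory) -> np.ndarray:
    """Phase-averaged WSS magnitude: |mean over cycles of the WSS vector|
    per (phase bin, element)."""
    return np.linalg.norm(h.phase_mean_wss(), axis=-1)


def turwss(h: WallShearHistory) -> np.ndarray:
    """Turbulent WSS: magnitude of the component-wise RMS of fluctuations
    about the phase-mean vector (population form), per (bin, element)."""
    if h.n_cycles < 2:
        raise StatisticsError("turbulent WSS needs at least 2 cycles")
    pm = h.phase_mean_wss()
    var = np.mean((h.wss - pm) ** 2, axis=0)  # (B, E, 3)
    return np.sqrt(np.sum(var, axis=-1))


def tawss(pawss_map: np.ndarray, cycle: CardiacCycle) -> np.ndarray:
    """Time-averaged WSS: (1/T) ∫ PAWSS dt over the cycle.

    Phase bins are uniform and the series is periodic, so the trapezoidal
    integral with wrap-around closure reduces to the plain bin mean.
    """
    pawss_map = np.asarray(pawss_map, dtype=float)
    if pawss_map.shape[0] != cycle.n_phase_bins:
        raise InputError("PAWSS map does not cover the full cycle")
    return pawss_map.mean(axis=0)


def _mean_direction(pm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Time-mean WSS vector and its unit direction.

    Elements whose time-mean vector is negligible relative to the typical
    instantaneous magnitude (perfect reversal up to round-off) have no
    defined direction and get NaN.
    """
    mean_vec = pm.mean(axis=0)  # (E, 3)
    mag = np.linalg.norm(mean_vec, axis=-1)
    scale = np.linalg.norm(pm, axis=-1).mean(axis=0)
    ok = mag > 1e-12 * np.maximum(scale, 1e-300)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(ok[:, None], mean_vec / mag[:, None], np.nan)
    return mean_vec, unit


def transwss(h: WallShearHistory) -> np.ndarray:
    """Transverse WSS per element.

    Time average of |(n̂ × ŝ) · ⟨WSS⟩(t)| where ŝ is the unit time-mean WSS
    direction of that element and n̂ its outward normal.  Elements with a
    vanishing time-mean vector have no defined direction and return NaN.
    """
    pm = h.phase_mean_wss()
    _, unit = _mean_direction(pm)
    perp = np.cross(h.surface.normals, unit)  # (E, 3), in tangent plane
    comp = np.abs(np.einsum("bek,ek->be", pm, perp))
    return comp.mean(axis=0)


def osi(h: WallShearHistory) -> np.ndarray:
    """Oscillatory shear index per element, clamped to [0, 0.5].

    ½(1 − |time-mean WSS vector| / time-mean |WSS vector|); NaN where the
    time-mean magnitude (TAWSS) is zero.
    """
    pm = h.phase_mean_wss()
    mean_vec = pm.mean(axis=0)
    num = np.linalg.norm(mean_vec, axis=-1)
    den = np.linalg.norm(pm, axis=-1).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 0.5 * (1.0 - num / den)
    out = np.where(den > 0, out, np.nan)
    return np.clip(out, 0.0, 0.5)


def compute_metric_maps(h: WallShearHistory) -> WSSMetricMaps:
    """Evaluate the full metric family on one wall-shear history."""
    p = pawss(h)
    return WSSMetricMaps(
        surface=h.surface,
        pawss=p,
        turwss=turwss(h),
        tawss=tawss(p, h.cycle),
        transwss=transwss(h),
        osi=osi(h),
    )


def segment_average(
    maps: WSSMetricMaps, mask: SegmentMask
) -> pd.DataFrame:
    """Area-weighted spatial means of |metric| per segment.

    Phase-resolved maps (PAWSS, TurWSS) are additionally time-averaged to
    per-cycle totals; NaN (undefined) elements are excluded from the
    averages they cannot contribute to.  Returns one row per segment.
    """
    areas = maps.surface.areas
    rows = []
    names = mask.segment_names()
    if not names:
        raise InputError("mask defines no segments")
    for name in names:
        sel = mask.labels == name
        if not sel.any():
            raise InputError(f"segment {name!r} is empty")
        a = areas[sel]

        def wmean(values):
            v = np.abs(np.asarray(values, dtype=float))
            ok = np.isfinite(v)
            if v.ndim == 1:
                return float(np.sum(v[ok] * a[ok]) / np.sum(a[ok]))
            # (B, E_sel): weight over elements per bin, then time-average
            w = np.where(ok, a[None, :], 0.0)
            per_bin = np.sum(np.where(ok, v, 0.0) * w, axis=1) / np.sum(w, axis=1)
            return float(per_bin.mean())

        rows.append(
            {
                "segment": name,
                "area_m2": float(a.sum()),
                "pawss_pa": wmean(maps.pawss[:, sel]),
                "turwss_pa": wmean(maps.turwss[:, sel]),
                "tawss_pa": wmean(maps.tawss[sel]),
                "transwss_pa": wmean(maps.transwss[sel]),
                "osi": wmean(maps.osi[sel]),
            }
        )
    return pd.DataFrame(rows).set_index("segment")
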