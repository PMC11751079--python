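"""Readers and writers for the on-disk formats.

All on-disk quantities are SI (m, s, m³/s, Pa); mmHg appears only in
human-facing report tables.  Formats:

* waveform CSV — ``time_s,flow_m3s`` (or ``time_s,velocity_ms`` + inlet area)
* probe CSV — ``t_s,u_x,u_y,u_z[,p]``
* spectrum CSV — ``f_hz,esd``
* VTK legacy ASCII — polydata surfaces with cell data, unstructured grids
  with point data (parsed and written directly; the legacy format is plain
  line-oriented text)
* STL — surfaces, via trimesh
* HDF5 — cycle ensembles, layout ``/cycles/{n}/bins/{b}/{field}``
* TOML — run configuration
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import InputError
from .phase import CycleEnsemble
from .waveform import CardiacCycle, FlowWaveform, InletGeometry
from .wss import WallShearHistory, WallSurface

__all__ = [
    "RunConfig",
    "load_config",
    "read_waveform_csv",
    "write_waveform_csv",
    "read_probe_csv",
    "write_probe_csv",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_vtk_polydata",
    "read_vtk_polydata",
    "write_vtk_unstructured",
    "read_field_snapshot",
    "read_stl_surface",
    "write_ensemble_h5",
    "read_ensemble_h5",
    "write_wss_history_h5",
    "read_wss_history_h5",
    "file_sha256",
]


# ---------------------------------------------------------------- config


@dataclass(frozen=True)
class RunConfig:
    """Run-wide configuration with blood-property defaults."""

    rho_kgm3: float = 1060.0
    nu_m2s: float = 3.78e-6
    n_phase_bins: int = 50
    discard_first: bool = True
    hr_list_bpm: tuple[float, ...] = (100.0, 120.0, 160.0)
    seed: int = 0
    n_cycles: int = 21
    inlet_area_m2: float = 99.63e-6
    map_mmhg: float | None = None
    arch_split: float = 0.723
    clip_negative_flow: bool = False

    def __post_init__(self):
        if self.rho_kgm3 <= 0 or self.nu_m2s <= 0:
            raise InputError("density and viscosity must be positive")


def load_config(path) -> RunConfig:
    """Load a TOML run configuration; unknown keys are rejected."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    run = raw.get("run", raw)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(run) - known
    if unknown:
        raise InputError(f"unknown config keys: {sorted(unknown)}")
    if "hr_list_bpm" in run:
        run["hr_list_bpm"] = tuple(run["hr_list_bpm"])
    return RunConfig(**run)


# ---------------------------------------------------------------- CSV


def read_waveform_csv(
    path, cycle: CardiacCycle, area: InletGeometry | None = None
) -> FlowWaveform:
    """Read ``time_s,flow_m3s`` (or ``time_s,velocity_ms`` with ``area``)."""
    df = pd.read_csv(path)
    if "flow_m3s" in df.columns:
        q = df["flow_m3s"].to_numpy()
    elif "velocity_ms" in df.columns:
        if area is None:
            raise InputError(
                "velocity waveform requires the inlet area to convert to flow"
            )
        q = df["velocity_ms"].to_numpy() * area.area_m2
    else:
        raise InputError(
            f"{path}: expected a 'flow_m3s' or 'velocity_ms' column, "
            f"got {list(df.columns)}"
        )
    if "time_s" not in df.columns:
        raise InputError(f"{path}: missing 'time_s' column")
    return FlowWaveform(cycle=cycle, t_s=df["time_s"].to_numpy(), q_m3s=q)


def write_waveform_csv(path, w: FlowWaveform) -> None:
    pd.DataFrame({"time_s": w.t_s, "flow_m3s": w.q_m3s}).to_csv(path, index=False)


def read_probe_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"t_s", "u_x", "u_y", "u_z"}
    missing = need - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing probe columns {sorted(missing)}")
    return df


def write_probe_csv(path, t_s, u_xyz, p=None) -> None:
    u = np.asarray(u_xyz)
    data = {"t_s": t_s, "u_x": u[:, 0], "u_y": u[:, 1], "u_z": u[:, 2]}
    if p is not None:
        data["p"] = p
    pd.DataFrame(data).to_csv(path, index=False)


def write_spectrum_csv(path, spectrum) -> None:
    pd.DataFrame({"f_hz": spectrum.freqs_hz, "esd": spectrum.esd}).to_csv(
        path, index=False
    )


def read_spectrum_csv(path):
    from .spectral import Spectrum

    df = pd.read_csv(path)
    e = df["esd"].to_numpy()
    return Spectrum(
        freqs_hz=df["f_hz"].to_numpy(), esd=e, total_energy=float(e.sum())
    )


# ---------------------------------------------------------------- VTK legacy


def _fmt_rows(arr, per_row=1) -> str:
    arr = np.asarray(arr)
    return "\n".join(
        " ".join(f"{v:.12g}" for v in np.atleast_1d(row)) for row in arr
    )


def write_vtk_polydata(path, surface: WallSurface, cell_data: dict | None = None):
    """Write a triangulated surface (and optional per-element data) as VTK
    legacy ASCII POLYDATA."""
    lines = [
        "# vtk DataFile Version 3.0",
        "hemoturb surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(surface.points)} double",
        _fmt_rows(surface.points),
        f"POLYGONS {surface.n_elements} {surface.n_elements * 4}",
        "\n".join("3 " + " ".join(map(str, t)) for t in surface.triangles),
    ]
    if cell_data:
        lines.append(f"CELL_DATA {surface.n_elements}")
        for name, values in cell_data.items():
            v = np.asarray(values, dtype=float)
            if v.ndim == 1:
                lines += [
                    f"SCALARS {name} double 1",
                    "LOOKUP_TABLE default",
                    _fmt_rows(v),
                ]
            elif v.ndim == 2 and v.shape[1] == 3:
                lines += [f"VECTORS {name} double", _fmt_rows(v)]
            else:
                raise InputError(
                    f"cell data {name!r} must be (E,) or (E, 3), got {v.shape}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


class _VtkScanner:
    """Token scanner over a VTK legacy ASCII file, tracking line numbers."""

    def __init__(self, path):
        self.path = str(path)
        self.lines = Path(path).read_text().splitlines()
        self.i = 0

    def error(self, msg):
        raise InputError(f"{self.path}:{self.i + 1}: {msg}")

    def next_line(self):
        while self.i < len(self.lines):
            line = self.lines[self.i].strip()
            self.i += 1
            if line:
                return line
        return None

    def read_floats(self, count):
        vals = []
        while len(vals) < count:
            line = self.next_line()
            if line is None:
                self.error(f"unexpected end of file, needed {count} numbers")
            try:
                vals.extend(float(tok) for tok in line.split())
            except ValueError:
                self.error(f"malformed numeric data: {line!r}")
        return np.asarray(vals[:count])


def _read_vtk(path) -> dict:
    sc = _VtkScanner(path)
    header = sc.next_line()
    if header is None or not header.startswith("# vtk"):
        sc.error("not a VTK legacy file")
    sc.next_line()  # title
    fmt = sc.next_line()
    if fmt != "ASCII":
        sc.error(f"only ASCII VTK supported, got {fmt!r}")
    dataset_line = sc.next_line()
    if not dataset_line or not dataset_line.startswith("DATASET"):
        sc.error("missing DATASET declaration")
    kind = dataset_line.split()[1]
    out = {"kind": kind, "point_data": {}, "cell_data": {}}

    n_points = n_cells = 0
    line = sc.next_line()
    while line is not None:
        tok = line.split()
        key = tok[0]
        if key == "POINTS":
            n_points = int(tok[1])
            out["points"] = sc.read_floats(n_points * 3).reshape(n_points, 3)
        elif key in ("POLYGONS", "CELLS"):
            n_cells = int(tok[1])
            flat = sc.read_floats(int(tok[2])).astype(int)
            cells, i = [], 0
            while i < flat.size:
                k = flat[i]
                cells.append(flat[i + 1 : i + 1 + k])
                i += 1 + k
            out["cells"] = cells
        elif key == "CELL_TYPES":
            out["cell_types"] = sc.read_floats(int(tok[1])).astype(int)
        elif key in ("POINT_DATA", "CELL_DATA"):
            target = "point_data" if key == "POINT_DATA" else "cell_data"
            n = int(tok[1])
            line = sc.next_line()
            while line is not None:
                dtok = line.split()
                if dtok[0] == "SCALARS":
                    sc.next_line()  # LOOKUP_TABLE
                    out[target][dtok[1]] = sc.read_floats(n)
                elif dtok[0] == "VECTORS":
                    out[target][dtok[1]] = sc.read_floats(n * 3).reshape(n, 3)
                else:
                    break
                line = sc.next_line()
            continue
        else:
            sc.error(f"unrecognised section {key!r}")
        line = sc.next_line()
    return out


def read_vtk_polydata(path) -> tuple[WallSurface, dict]:
    """Read a VTK legacy ASCII POLYDATA surface with its cell data."""
    raw = _read_vtk(path)
    if raw["kind"] != "POLYDATA":
        raise InputError(f"{path}: expected POLYDATA, got {raw['kind']}")
    tris = [c for c in raw.get("cells", []) if len(c) == 3]
    if not tris:
        raise InputError(f"{path}: no triangles found")
    surface = WallSurface.from_triangles(raw["points"], np.asarray(tris))
    return surface, raw["cell_data"]


def write_vtk_unstructured(path, points, point_data: dict | None = None):
    """Write a point cloud (VTK_VERTEX cells) with point data as a legacy
    ASCII unstructured grid."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    lines = [
        "# vtk DataFile Version 3.0",
        "hemoturb field",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
        _fmt_rows(points),
        f"CELLS {n} {2 * n}",
        "\n".join(f"1 {i}" for i in range(n)),
        f"CELL_TYPES {n}",
        "\n".join("1" for _ in range(n)),
    ]
    if point_data:
        lines.append(f"POINT_DATA {n}")
        for name, values in point_data.items():
            v = np.asarray(values, dtype=float)
            if v.ndim == 1:
                lines += [
                    f"SCALARS {name} double 1",
                    "LOOKUP_TABLE default",
                    _fmt_rows(v),
                ]
            else:
                lines += [f"VECTORS {name} double", _fmt_rows(v)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_field_snapshot(path, require: tuple[str, ...] = ()) -> dict:
    """Parse a VTK legacy ASCII snapshot (polydata or unstructured grid).

    Returns points, cells, and point/cell data arrays; ``require`` names
    fields that must be present in either data block (schema check).
    """
    raw = _read_vtk(path)
    present = set(raw["point_data"]) | set(raw["cell_data"])
    missing = set(require) - present
    if missing:
        raise InputError(
            f"{path}: missing required field(s) {sorted(missing)}; "
            f"found {sorted(present)}"
        )
    return raw


def read_stl_surface(path) -> WallSurface:
    """Load an STL surface via trimesh."""
    import trimesh

    mesh = trimesh.load_mesh(str(path), file_type="stl")
    return WallSurface.from_triangles(
        np.asarray(mesh.vertices), np.asarray(mesh.faces)
    )


# ---------------------------------------------------------------- HDF5


def write_ensemble_h5(path, e: CycleEnsemble, name: str = "velocity") -> None:
    """Write a cycle ensemble under ``/cycles/{n}/bins/{b}/{name}``."""
    with h5py.File(path, "w") as fh:
        fh.attrs["hr_bpm"] = e.cycle.hr_bpm
        fh.attrs["n_phase_bins"] = e.cycle.n_phase_bins
        for n in range(e.n_cycles):
            for b in range(e.n_bins):
                fh.create_dataset(
                    f"cycles/{n}/bins/{b}/{name}", data=e.values[n, b]
                )


def read_ensemble_h5(path, name: str = "velocity") -> CycleEnsemble:
    with h5py.File(path, "r") as fh:
        cycle = CardiacCycle(
            float(fh.attrs["hr_bpm"]), int(fh.attrs["n_phase_bins"])
        )
        n_cycles = len(fh["cycles"])
        rows = []
        for n in range(n_cycles):
            grp = fh[f"cycles/{n}/bins"]
            rows.append([grp[f"{b}/{name}"][()] for b in range(len(grp))])
        return CycleEnsemble(cycle, np.asarray(rows))


def write_wss_history_h5(path, h: WallShearHistory) -> None:
    """Write a WSS history plus its surface in one container."""
    with h5py.File(path, "w") as fh:
        fh.attrs["hr_bpm"] = h.cycle.hr_bpm
        fh.attrs["n_phase_bins"] = h.cycle.n_phase_bins
        fh.create_dataset("surface/points", data=h.surface.points)
        fh.create_dataset("surface/triangles", data=h.surface.triangles)
        for n in range(h.n_cycles):
            for b in range(h.n_bins):
                fh.create_dataset(f"cycles/{n}/bins/{b}/wss", data=h.wss[n, b])


def read_wss_history_h5(path) -> WallShearHistory:
    with h5py.File(path, "r") as fh:
        cycle = CardiacCycle(
            float(fh.attrs["hr_bpm"]), int(fh.attrs["n_phase_bins"])
        )
        surface = WallSurface.from_triangles(
            fh["surface/points"][()], fh["surface/triangles"][()]
        )
        rows = []
        for n in range(len(fh["cycles"])):
            grp = fh[f"cycles/{n}/bins"]
            rows.append([grp[f"{b}/wss"][()] for b in range(len(grp))])
        return WallShearHistory(
            surface=surface, wss=np.asarray(rows), cycle=cycle
        )


# ---------------------------------------------------------------- manifest


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, entries: dict, extra: dict | None = None) -> None:
    manifest = {"files": entries}
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
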