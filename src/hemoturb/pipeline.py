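"""End-to-end orchestration: synthesis → phase statistics → spectra →
WSS metrics → cross-HR report.

The pipeline runs the whole analysis chain on synthetic data for each heart
rate in the configuration, mirroring the staged protocol used for
cycle-resolved CFD output: generate (or load) cycle data, check phase-average
convergence at peak systole, accumulate energy and WSS statistics, and
condense everything into a per-HR summary with cross-HR percent changes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import io as hio
from . import phase, spectral, summary, synthetic, waveform, windkessel, wss
from .errors import InputError

__all__ = ["run_pipeline"]


def _hr_record(cfg: hio.RunConfig, hr: float, base_wave) -> dict:
    """All per-HR scalar metrics from a fresh synthetic realisation."""
    w = waveform.rescale_to_hr(base_wave, hr)
    t_peak, frac_peak = waveform.peak_systole_time(w)
    spec = synthetic.SyntheticSpec(
        seed=cfg.seed,
        hr_bpm=hr,
        n_cycles=cfg.n_cycles,
        n_phase_bins=cfg.n_phase_bins,
        inlet_area_m2=cfg.inlet_area_m2,
        rho=cfg.rho_kgm3,
    )
    ensemble, _ = synthetic.make_velocity_ensemble(spec, w, n_entities=2)
    if cfg.discard_first:
        ensemble = phase.CycleEnsemble(ensemble.cycle, ensemble.values[1:])
    peak_bin = int(frac_peak * cfg.n_phase_bins)
    conv = phase.convergence_check(ensemble, peak_bin, rho=cfg.rho_kgm3)
    energies = phase.kinetic_energies(ensemble, rho=cfg.rho_kgm3)
    ke_max = float(energies.ke_t.sum(axis=-1).max())
    tke_max = float(energies.tke_t.sum(axis=-1).max())

    surface, mask, _ = synthetic.make_tube_fixture(n_axial=20, n_circ=16)
    history, _ = synthetic.make_wss_history(spec, surface, noise_pa=0.5)
    maps = wss.compute_metric_maps(history)
    seg = wss.segment_average(maps, mask)
    areas = surface.areas
    pawss_total = float(np.sum(maps.pawss.mean(axis=0) * areas))
    turwss_total = float(np.sum(maps.turwss.mean(axis=0) * areas))
    ratios = summary.energy_ratios(ke_max, tke_max, pawss_total, turwss_total)

    vmax = float(np.max(np.abs(w.q_m3s))) / cfg.inlet_area_m2
    return {
        "hr_bpm": hr,
        "peak_systole_s": t_peak,
        "peak_fraction": frac_peak,
        "stroke_volume_m3": waveform.stroke_volume(w),
        "max_inlet_velocity_ms": vmax,
        "max_integrated_ke": ke_max,
        "max_integrated_tke": tke_max,
        "tke_fraction": ratios["tke_fraction"],
        "turwss_fraction": ratios["turwss_fraction"],
        "convergence": conv,
        "segments": seg.reset_index().to_dict(orient="records"),
        "waveform": w,
        "maps": maps,
    }


def run_pipeline(cfg: hio.RunConfig, outdir) -> dict:
    """Run the full synthetic analysis chain and write the artefact tree.

    Writes per-HR waveform CSVs, the baseline probe spectrum, WSS metric
    maps as VTK polydata, a Windkessel calibration JSON, the cross-HR
    report, and a manifest with seeds and per-file checksums.  Returns the
    report dictionary.
    """
    if len(cfg.hr_list_bpm) < 2:
        raise InputError("pipeline needs at least two heart rates to compare")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    base_wave = synthetic.default_inlet_waveform(
        synthetic.BASELINE_HR_BPM,
        n_phase_bins=cfg.n_phase_bins,
        area_m2=cfg.inlet_area_m2,
    )

    records = {}
    written = {}
    for hr in cfg.hr_list_bpm:
        rec = _hr_record(cfg, hr, base_wave)
        path = out / f"waveform_bpm{int(hr)}.csv"
        hio.write_waveform_csv(path, rec.pop("waveform"))
        written[path.name] = hio.file_sha256(path)
        maps = rec.pop("maps")
        vtk_path = out / f"wss_maps_bpm{int(hr)}.vtk"
        hio.write_vtk_polydata(
            vtk_path,
            maps.surface,
            {
                "TAWSS": maps.tawss,
                "TransWSS": np.nan_to_num(maps.transwss),
                "OSI": np.nan_to_num(maps.osi),
            },
        )
        written[vtk_path.name] = hio.file_sha256(vtk_path)
        records[hr] = rec

    # baseline probe spectrum with cycle-block Welch averaging
    spec = synthetic.SyntheticSpec(seed=cfg.seed, hr_bpm=synthetic.BASELINE_HR_BPM)
    sig, _ = synthetic.make_probe_signal(spec, n_cycles=20)
    spectrum = spectral.welch_esd(sig, n_blocks=20)
    spath = out / "probe_spectrum.csv"
    hio.write_spectrum_csv(spath, spectrum)
    written[spath.name] = hio.file_sha256(spath)
    slope, slope_se = spectral.inertial_slope(spectrum, 50.0, 1000.0)

    # Windkessel calibration to the study's split and pressure targets
    map_mmhg = (
        cfg.map_mmhg
        if cfg.map_mmhg is not None
        else windkessel.map_from_sys_dia(123.0, 60.0)
    )
    splits = arch_splits(cfg.arch_split)
    outlets = windkessel.calibrate(
        base_wave, map_mmhg * windkessel.MMHG_PA, splits
    )
    fractions = windkessel.cycle_flow_fractions(outlets, base_wave)
    wk_path = out / "windkessel.json"
    wk_path.write_text(
        json.dumps(
            {
                "map_mmhg": map_mmhg,
                "fractions": fractions,
                "outlets": {
                    name: {
                        "r_prox": p.r_prox,
                        "r_dist": p.r_dist,
                        "c_art": p.c_art,
                        "p_out": p.p_out,
                    }
                    for name, p in outlets.outlets.items()
                },
            },
            indent=2,
        )
    )
    written[wk_path.name] = hio.file_sha256(wk_path)

    metric_keys = (
        "max_inlet_velocity_ms",
        "max_integrated_ke",
        "max_integrated_tke",
        "tke_fraction",
        "turwss_fraction",
    )
    cross = summary.cross_hr_report(
        {hr: {k: rec[k] for k in metric_keys} for hr, rec in records.items()}
    )

    report = {
        "per_hr": {str(hr): _scrub(rec) for hr, rec in records.items()},
        "cross_hr": cross.reset_index().to_dict(orient="records"),
        "spectral_slope": {"slope": slope, "stderr": slope_se},
        "windkessel": {
            "map_mmhg": map_mmhg,
            "arch_fraction": sum(
                fractions[n] for n in ("innominate", "l_carotid", "l_subclavian")
            ),
        },
        "seed": cfg.seed,
    }
    rpath = out / "report.json"
    rpath.write_text(json.dumps(report, indent=2, default=float) + "\n")
    written[rpath.name] = hio.file_sha256(rpath)
    hio.write_manifest(out / "manifest.json", written, {"seed": cfg.seed})
    return report


def arch_splits(arch_fraction: float) -> dict[str, float]:
    """Four-outlet flow split: the aortic-arch branches (innominate, left
    common carotid, left subclavian) share ``arch_fraction`` of the outflow
    2:1:1, the descending aorta carries the rest."""
    if not 0 < arch_fraction < 1:
        raise InputError("arch fraction must be in (0, 1)")
    return {
        "innominate": arch_fraction / 2,
        "l_carotid": arch_fraction / 4,
        "l_subclavian": arch_fraction / 4,
        "descending_aorta": 1.0 - arch_fraction,
    }


def _scrub(rec: dict) -> dict:
    return {
        k: v for k, v in rec.items() if k not in ("waveform", "maps")
    }
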