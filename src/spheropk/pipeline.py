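"""End-to-end pipeline: simulate → 2D size analysis → 3D single-cell
analysis → growth dynamics → QC, with a fixed on-disk layout.

Layout of one run directory::

    out/
      config.yaml          archived effective configuration
      log.txt              plain-text run log
      stacks/s01_t000.tif  rendered frames (multi-page TIFF)
      tables/truth.csv     ground-truth nuclei (frame, cell_id, x, y, z, r)
      tables/summary.csv   per-frame truth summary (n_cells, conc_uM)
      tables/area.csv      2D size series with QC flags
      tables/nuclei.csv    3D per-nucleus table (region, n_neighbors)
      tables/density.csv   mean neighbour count per region over time
      tables/crossings.csv shrink↔grow transitions with concentrations
      tables/profile.csv   applied dosing profile
      qc/report.csv        per-series QC decisions
      summary.json         headline numbers of the run

Identical configs (same seed) reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import dynamics as dyn
from . import nuclei as nuc
from . import pk
from . import projection as proj
from .config import RunConfig
from .experiment import simulate_experiment
from .qc import apply_qc

__all__ = ["build_dosing_profile", "run_pipeline"]


def build_dosing_profile(cfg: RunConfig) -> pk.PKProfile:
    """Dosing profile for the configured regimen.

    "pk": ramp+decay cycles with the decay rate calibrated so the cycle
    average equals the AUC-matched constant; "constant": that constant,
    flat; "vehicle": zero.
    """
    c = cfg.pk
    duration = c.cycle_length_h * c.n_cycles
    if c.mode == "vehicle":
        return pk.constant_profile(0.0, duration, c.cycle_length_h)
    if c.mode == "constant":
        return pk.constant_profile(c.target_constant_uM, duration, c.cycle_length_h)
    rate = pk.calibrate_decay_to_constant(
        c.peak_uM, c.t_peak_h, c.n_decay_steps, c.target_constant_uM, c.cycle_length_h
    )
    one = pk.build_profile(
        c.peak_uM, c.t_peak_h, c.n_decay_steps, rate, c.cycle_length_h
    )
    return pk.repeat_cycles(one, c.n_cycles)


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full chain and write the run directory.

    Returns the summary dictionary (also written to summary.json).
    Partial failures leave an ``error.json`` marker in the run directory
    instead of silently truncated outputs.
    """
    seed = cfg.require_seed()
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    (out / "stacks").mkdir(parents=True, exist_ok=True)
    (out / "tables").mkdir(exist_ok=True)
    (out / "qc").mkdir(exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    try:
        cfg.to_yaml(out / "config.yaml")
        profile = build_dosing_profile(cfg)
        pk.write_profile_csv(profile, out / "tables" / "profile.csv")
        log(f"profile: mode={cfg.pk.mode} span={profile.t_end} h")

        result = simulate_experiment(
            profile,
            cfg.pd,
            cfg.protocol,
            cfg.render,
            seed=seed,
            target_diameter=cfg.target_diameter_um,
            nucleus_radius=cfg.nucleus_radius_um,
        )
        log(f"simulated {result.n_frames} frames")
        for frame, stack in enumerate(result.stacks):
            tifffile.imwrite(out / "stacks" / f"s01_t{frame:03d}.tif", stack)
        _write_csv(result.truth, out / "tables" / "truth.csv")
        _write_csv(result.summary, out / "tables" / "summary.csv")

        # 2D chain
        px = cfg.render.voxel_size[2]
        areas = proj.area_series(result.stacks, result.times, pixel_size=px)
        report = apply_qc(areas, cfg.qc)
        rel = np.full(len(areas), np.nan)
        finite = np.isfinite(areas["area_um2"].to_numpy())
        if finite.any():
            ref = int(np.flatnonzero(finite)[0])
            rel = areas["area_um2"].to_numpy() / areas["area_um2"].to_numpy()[ref]
        areas = areas.assign(rel_area=rel)
        _write_csv(areas, out / "tables" / "area.csv")
        _write_csv(report.to_frame(), out / "qc" / "report.csv")
        log(f"2D analysis: {len(areas)} frames, included={report.included_ids()}")

        # 3D chain (optionally strided)
        stride = max(1, cfg.analysis.analyze3d_stride)
        frames3d, times3d = [], []
        for frame in range(0, result.n_frames, stride):
            table, _ = nuc.analyze_stack_3d(
                result.stacks[frame].astype(np.float64),
                expected_diameter=cfg.analysis.nucleus_diameter_um,
                neighbor_radius=cfg.analysis.neighbor_radius_um,
                band=cfg.analysis.region_band_um,
                voxel_size=cfg.render.voxel_size,
                ball_radius=cfg.analysis.rolling_ball_um,
            )
            table.insert(0, "frame", frame)
            table.insert(1, "time_h", float(result.times[frame]))
            table.insert(0, "spheroid_id", "s01")
            frames3d.append(table)
            times3d.append(float(result.times[frame]))
        nuclei_all = pd.concat(frames3d, ignore_index=True)
        _write_csv(nuclei_all, out / "tables" / "nuclei.csv")
        if len(frames3d) >= 2:
            density = nuc.region_density_series(
                frames3d, np.asarray(times3d), cfg.analysis.spacing_min
            )
        else:  # a single analysed frame cannot be interpolated
            sec = frames3d[0][frames3d[0]["in_section"]]
            density = pd.DataFrame(
                {
                    "time_h": times3d[0],
                    "region": ["center", "shell"],
                    "mean_neighbors": [
                        sec[sec["region"].isin([r, "both"])]["n_neighbors"].mean()
                        for r in ("center", "shell")
                    ],
                }
            )
        _write_csv(density, out / "tables" / "density.csv")
        log(f"3D analysis: {len(frames3d)} frames (stride {stride})")

        # growth dynamics
        ok = np.isfinite(areas["area_um2"].to_numpy())
        change = dyn.relative_change(
            areas["time_h"].to_numpy()[ok], areas["area_um2"].to_numpy()[ok]
        )
        window = min(cfg.analysis.lowess_window, change.times.size)
        smoothed = dyn.lowess_smooth(change, window)
        transitions = dyn.transition_concentration(
            dyn.detect_transitions(smoothed), profile
        )
        crossings = pd.DataFrame(
            {
                "time_h": transitions.times,
                "direction": transitions.directions,
                "conc_uM": (
                    transitions.concentrations
                    if transitions.concentrations is not None
                    else np.full(transitions.n_crossings, np.nan)
                ),
            }
        )
        _write_csv(crossings, out / "tables" / "crossings.csv")
        per_cycle = dyn.crossings_per_cycle(
            transitions, cfg.pk.cycle_length_h, cfg.pk.n_cycles
        )
        summary = {
            "seed": seed,
            "mode": cfg.pk.mode,
            "n_frames": result.n_frames,
            "final_cell_count": int(result.summary["n_cells"].iloc[-1]),
            "area_fold_change": _fold_change(areas),
            "threshold_estimate_uM": transitions.threshold_estimate,
            "n_crossings": int(transitions.n_crossings),
            "neg_to_pos_per_cycle": per_cycle["neg_to_pos"].tolist(),
            "included_series": report.included_ids(),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        (out / "log.txt").write_text("\n".join(log_lines) + "\n")
        return summary
    except Exception as exc:
        (out / "error.json").write_text(
            json.dumps({"error": type(exc).__name__, "message": str(exc)})
        )
        (out / "log.txt").write_text("\n".join(log_lines) + f"\nFAILED: {exc}\n")
        raise


def _fold_change(areas: pd.DataFrame) -> float | None:
    a = areas["area_um2"].to_numpy(dtype=float)
    ok = np.isfinite(a)
    if ok.sum() < 2:
        return None
    idx = np.flatnonzero(ok)
    return float(a[idx[-1]] / a[idx[0]])


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")
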