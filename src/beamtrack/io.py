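"""File formats: TIFF for images/volumes, JSON for manifests and metrics,
CSV for curves, YAML for configuration.

A simulated or measured scan lives in a directory with one TIFF per frame
and a ``manifest.json`` listing, for every frame: path, type (flat / dark /
sample), rotation angle, raster offset indices and the beamlet-grid layout.
Downstream stages read and write self-describing pairs (TIFF + JSON
sidecar) so every artefact carries its sampling pitch, angles and
provenance (config hash, seed, package version).
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import __version__
from .core import SetupGeometry
from .phase import PhaseMap
from .simulator import BeamletFrame, ScanSimulation
from .tomo import Volume
from .tracking import StitchedProjection

__all__ = [
    "config_hash",
    "load_config",
    "save_scan",
    "load_scan",
    "save_projections",
    "load_projections",
    "save_phase_maps",
    "load_phase_maps",
    "save_volume",
    "load_volume",
    "save_frc_curve",
    "provenance",
]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "geometry" not in cfg:
        raise ValueError("config must be a mapping with a 'geometry' section")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping, for provenance stamps."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def provenance(cfg: dict, seed) -> dict:
    return {"config_hash": config_hash(cfg), "seed": seed, "version": __version__}


def _frame_record(key: str, frame: BeamletFrame, ftype: str, angle, raster) -> dict:
    return {
        "path": f"{key}.tif",
        "type": ftype,
        "angle": angle,
        "raster": list(raster),
        "grid_origin": list(frame.grid_origin),
        "grid_pitch": frame.grid_pitch,
        "grid_shape": list(frame.grid_shape),
        "modulator_offset": list(frame.modulator_offset),
    }


def save_scan(sim: ScanSimulation, outdir, cfg: dict | None = None, seed=None) -> Path:
    """Write all frames of a simulated scan plus manifest and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for (a, b), frame in sim.flats.items():
        key = f"flat_a{a}_b{b}"
        tifffile.imwrite(outdir / f"{key}.tif", frame.intensity.astype(np.float32), photometric="minisblack")
        records.append(_frame_record(key, frame, "flat", None, (a, b)))
    if sim.dark is not None:
        tifffile.imwrite(outdir / "dark.tif", sim.dark.astype(np.float32))
    for (ia, a, b), frame in sim.frames.items():
        key = f"sample_p{ia:05d}_a{a}_b{b}"
        tifffile.imwrite(outdir / f"{key}.tif", frame.intensity.astype(np.float32), photometric="minisblack")
        records.append(_frame_record(key, frame, "sample", float(sim.angles[ia]), (a, b)))
    manifest = {
        "frames": records,
        "dark": "dark.tif" if sim.dark is not None else None,
        "angles": [float(a) for a in sim.angles],
        "n_subpitch": sim.geom.n_subpitch,
    }
    if cfg is not None:
        manifest["provenance"] = provenance(cfg, seed)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    if sim.truth:
        truth_t = np.stack([f.t for f in sim.truth]).astype(np.float32)
        truth_phi = np.stack([f.dphi for f in sim.truth]).astype(np.float32)
        tifffile.imwrite(outdir / "truth_t.tif", truth_t, photometric="minisblack")
        tifffile.imwrite(outdir / "truth_dphi.tif", truth_phi, photometric="minisblack")
    return outdir


def load_scan(indir, geom: SetupGeometry) -> ScanSimulation:
    """Read a scan directory back into frames keyed like the simulator's."""
    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    angles = np.array(manifest["angles"])
    sim = ScanSimulation(geom=geom, angles=angles)
    if manifest.get("dark"):
        sim.dark = tifffile.imread(indir / manifest["dark"]).astype(float)
    angle_index = {round(a, 12): i for i, a in enumerate(manifest["angles"])}
    for rec in manifest["frames"]:
        frame = BeamletFrame(
            intensity=tifffile.imread(indir / rec["path"]).astype(float),
            grid_origin=tuple(rec["grid_origin"]),
            grid_pitch=rec["grid_pitch"],
            grid_shape=tuple(rec["grid_shape"]),
            modulator_offset=tuple(rec["modulator_offset"]),
        )
        a, b = rec["raster"]
        if rec["type"] == "flat":
            sim.flats[(a, b)] = frame
        elif rec["type"] == "sample":
            ia = angle_index[round(rec["angle"], 12)]
            sim.frames[(ia, a, b)] = frame
    return sim


def save_projections(projections: list[StitchedProjection], outpath) -> Path:
    """Stitched projections as one TIFF (angle, channel, y, x) + JSON."""
    outpath = Path(outpath)
    stack = np.stack(
        [np.stack([p.t, p.alpha_x, p.alpha_y]) for p in projections]
    ).astype(np.float32)
    tifffile.imwrite(outpath, stack, photometric="minisblack")
    meta = {
        "angles": [float(p.angle) for p in projections],
        "pitch_m": float(projections[0].pitch),
        "channels": ["t", "alpha_x", "alpha_y"],
    }
    with open(outpath.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    return outpath


def load_projections(path) -> list[StitchedProjection]:
    path = Path(path)
    stack = tifffile.imread(path).astype(float)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return [
        StitchedProjection(
            t=stack[i, 0], alpha_x=stack[i, 1], alpha_y=stack[i, 2],
            angle=meta["angles"][i], pitch=meta["pitch_m"],
        )
        for i in range(stack.shape[0])
    ]


def save_phase_maps(maps: list[PhaseMap], outpath) -> Path:
    outpath = Path(outpath)
    tifffile.imwrite(outpath, np.stack([m.dphi for m in maps]).astype(np.float32), photometric="minisblack")
    meta = {"angles": [float(m.angle) for m in maps], "pitch_m": float(maps[0].pitch)}
    with open(outpath.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    return outpath


def load_phase_maps(path) -> list[PhaseMap]:
    path = Path(path)
    stack = tifffile.imread(path).astype(float)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return [
        PhaseMap(dphi=stack[i], pitch=meta["pitch_m"], angle=meta["angles"][i])
        for i in range(stack.shape[0])
    ]


def save_volume(vol: Volume, outpath) -> Path:
    outpath = Path(outpath)
    tifffile.imwrite(outpath, vol.voxels.astype(np.float32), photometric="minisblack")
    with open(outpath.with_suffix(".json"), "w") as fh:
        json.dump({"voxel_size_m": float(vol.voxel_size)}, fh)
    return outpath


def load_volume(path) -> Volume:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return Volume(voxels=tifffile.imread(path).astype(float), voxel_size=meta["voxel_size_m"])


def save_frc_curve(curve, outpath) -> Path:
    """FRC curve as CSV columns (freq_cyc_per_px, frc, threshold)."""
    outpath = Path(outpath)
    with open(outpath, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["freq_cyc_per_px", "frc", "threshold"])
        for f, c, t in zip(curve.freq, curve.frc, curve.threshold):
            w.writerow([f"{f:.6f}", f"{c:.6f}", f"{t:.6f}" if np.isfinite(t) else "inf"])
    return outpath
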