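"""File interchange: CSV + JSON sidecars for time series, TIFF for volumes."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from septodg.behavior import BehaviorTrack, ExplorationBout
from septodg.ephys import Sweep, SweepSet
from septodg.photometry import PhotometrySession
from septodg.tracing import LabeledVolume, RoiMask

__all__ = [
    "write_session",
    "read_session",
    "write_track",
    "read_track",
    "write_sweepset",
    "read_sweepset",
    "write_volume",
    "read_volume",
    "write_ground_truth",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_session(session: PhotometrySession, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {"time_s": session.time, "f_gcamp": session.f_gcamp, "f_mcherry": session.f_mcherry}
    ).to_csv(path, index=False, float_format="%.10g")
    meta = {
        "site": session.site,
        "animal_id": session.animal_id,
        "genotype": session.genotype,
        "context": session.context,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_session(path: str | Path) -> PhotometrySession:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    return PhotometrySession(
        time=df.time_s.to_numpy(),
        f_gcamp=df.f_gcamp.to_numpy(),
        f_mcherry=df.f_mcherry.to_numpy(),
        **meta,
    )


def write_track(track: BehaviorTrack, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {"time_s": track.time, "x_cm": track.x, "y_cm": track.y,
         "heading_deg": track.heading_deg}
    ).to_csv(path, index=False, float_format="%.10g")
    meta = {
        "objects": {k: list(v) for k, v in track.objects.items()},
        "arena_side_cm": track.arena_side_cm,
        "phase": track.phase,
        "corner_zone_cm": track.corner_zone_cm,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_track(path: str | Path) -> BehaviorTrack:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    return BehaviorTrack(
        time=df.time_s.to_numpy(),
        x=df.x_cm.to_numpy(),
        y=df.y_cm.to_numpy(),
        heading_deg=df.heading_deg.to_numpy(),
        objects={k: tuple(v) for k, v in meta["objects"].items()},
        arena_side_cm=meta["arena_side_cm"],
        phase=meta["phase"],
        corner_zone_cm=meta["corner_zone_cm"],
    )


def write_sweepset(sweeps: SweepSet, path: str | Path) -> None:
    path = Path(path)
    frames = []
    for i, s in enumerate(sweeps.sweeps):
        frames.append(
            pd.DataFrame({"sweep": i, "time_s": s.time, "signal": s.signal})
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")
    meta = {
        "mode": sweeps.mode,
        "holding_mv": sweeps.holding_mv,
        "light_epochs": [list(e) for e in sweeps.light_epochs],
        "access_resistance_mohm": sweeps.access_resistance_mohm,
        "cell_id": sweeps.cell_id,
        "genotype": sweeps.genotype,
        "sweep_meta": [
            {"injected_pa": s.injected_pa, "step_start_s": s.step_start_s,
             "step_duration_s": s.step_duration_s, "label": s.label}
            for s in sweeps.sweeps
        ],
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_sweepset(path: str | Path) -> SweepSet:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    sweeps = []
    for i, sm in enumerate(meta["sweep_meta"]):
        sub = df[df.sweep == i]
        sweeps.append(
            Sweep(time=sub.time_s.to_numpy(), signal=sub.signal.to_numpy(), **sm)
        )
    return SweepSet(
        sweeps=sweeps,
        mode=meta["mode"],
        holding_mv=meta["holding_mv"],
        light_epochs=[tuple(e) for e in meta["light_epochs"]],
        access_resistance_mohm=meta["access_resistance_mohm"],
        cell_id=meta["cell_id"],
        genotype=meta["genotype"],
    )


def write_volume(volume: LabeledVolume, rois: dict[str, RoiMask], path: str | Path) -> None:
    """Multi-channel TIFF (channel axis first) + per-ROI mask TIFFs + JSON."""
    path = Path(path)
    names = sorted(volume.channels)
    stack = np.stack([volume.channels[n].astype(np.float32) for n in names])
    tifffile.imwrite(path, stack)
    for name, roi in rois.items():
        tifffile.imwrite(
            path.with_name(f"{path.stem}_roi_{name}.tif"), roi.mask.astype(np.uint8)
        )
    meta = {
        "channels": names,
        "voxel_size_um": list(volume.voxel_size_um),
        "section_interval": volume.section_interval,
        "rois": sorted(rois),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_volume(path: str | Path) -> tuple[LabeledVolume, dict[str, RoiMask]]:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    stack = tifffile.imread(path)
    channels = {n: stack[i] for i, n in enumerate(meta["channels"])}
    volume = LabeledVolume(
        channels=channels,
        voxel_size_um=tuple(meta["voxel_size_um"]),
        section_interval=meta["section_interval"],
    )
    rois = {}
    for name in meta["rois"]:
        mask = tifffile.imread(path.with_name(f"{path.stem}_roi_{name}.tif"))
        rois[name] = RoiMask(name=name, mask=mask.astype(bool))
    return volume, rois


def write_ground_truth(truth, path: str | Path) -> None:
    d = asdict(truth)
    out = {}
    for k, v in d.items():
        if v is None:
            continue
        if isinstance(v, np.ndarray):
            out[k] = v.tolist()
        elif isinstance(v, list) and v and isinstance(v[0], ExplorationBout):
            out[k] = [asdict(b) for b in v]
        else:
            out[k] = v
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True, default=str))
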