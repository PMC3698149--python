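"""Readers and writers for the plain-text artifact formats.

Depth scans, HLUTs and PET frames travel as CSV; results, specs and
timelines as JSON; CT and activity volumes as a raw little-endian array
next to a JSON header (shape, spacing, dtype).  All numbers are serialized
at full precision — any rounding happens in human-readable report fields
only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .bragg import DepthScanCurve, WeplResult
from .hlut import CtVolume, Hlut, RoiSpec
from .pet import ActivityFrames, IrradiationTimeline, IsotopeFit

PathLike = Union[str, Path]


def write_depth_scan(curve: DepthScanCurve, path: PathLike) -> None:
    df = pd.DataFrame({"thickness_mm": curve.absorber_thickness,
                       "charge_ratio": curve.charge_ratio})
    df.to_csv(path, index=False)


def read_depth_scan(path: PathLike, step: float | None = None
                    ) -> DepthScanCurve:
    df = pd.read_csv(path)
    x = df["thickness_mm"].to_numpy()
    if step is None:
        step = float(np.median(np.diff(x))) if x.size > 1 else 0.1
    return DepthScanCurve(x, df["charge_ratio"].to_numpy(), step)


def write_wepl_result(result: WeplResult, path: PathLike) -> None:
    payload = {"wepl": result.wepl,
               "u_total_2sigma": result.u_total_2sigma,
               "components": dict(result.components)}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_wepl_result(path: PathLike) -> WeplResult:
    payload = json.loads(Path(path).read_text())
    return WeplResult(payload["wepl"], payload["u_total_2sigma"],
                      payload["components"])


def write_hlut(hlut: Hlut, path: PathLike) -> None:
    pd.DataFrame({"hu": hlut.hu, "wepl": hlut.wepl}).to_csv(path, index=False)


def read_hlut(path: PathLike) -> Hlut:
    df = pd.read_csv(path)
    return Hlut(tuple(zip(df["hu"], df["wepl"])))


def write_volume(volume: CtVolume, base: PathLike) -> tuple[Path, Path]:
    """Write a volume as ``<base>.json`` header plus ``<base>.raw`` data."""
    base = Path(base)
    raw_path = base.with_suffix(".raw")
    header_path = base.with_suffix(".json")
    arr = np.ascontiguousarray(volume.data)
    arr.tofile(raw_path)
    header = {"shape": list(arr.shape),
              "spacing": list(volume.spacing),
              "dtype": str(arr.dtype),
              "order": "C",
              "raw": raw_path.name}
    header_path.write_text(json.dumps(header, indent=2, sort_keys=True))
    return header_path, raw_path


def read_volume(header_path: PathLike) -> CtVolume:
    header_path = Path(header_path)
    header = json.loads(header_path.read_text())
    raw_path = header_path.parent / header["raw"]
    arr = np.fromfile(raw_path, dtype=np.dtype(header["dtype"]))
    arr = arr.reshape(header["shape"])
    return CtVolume(arr, tuple(header["spacing"]))


def write_roi(roi: RoiSpec, path: PathLike) -> None:
    payload = {"centre": list(roi.centre), "diameter": roi.diameter,
               "slices": list(roi.slices)}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_roi(path: PathLike) -> RoiSpec:
    payload = json.loads(Path(path).read_text())
    return RoiSpec(tuple(payload["centre"]), payload["diameter"],
                   tuple(payload["slices"]))


def write_timeline(timeline: IrradiationTimeline, path: PathLike) -> None:
    payload = {"beam_on": timeline.beam_on, "delay": timeline.delay,
               "acquisition": timeline.acquisition,
               "frame_boundaries": list(timeline.frame_boundaries)}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_timeline(path: PathLike) -> IrradiationTimeline:
    payload = json.loads(Path(path).read_text())
    return IrradiationTimeline(payload["beam_on"], payload["delay"],
                               payload["acquisition"],
                               tuple(payload["frame_boundaries"]))


def write_frames(frames: ActivityFrames, path: PathLike) -> None:
    rows = []
    for f, (t1, t2) in enumerate(frames.frame_bounds):
        for d, depth in enumerate(frames.depth):
            rows.append((t1, t2, depth, frames.values[f, d]))
    df = pd.DataFrame(rows, columns=["frame_start", "frame_end", "depth_mm",
                                     "value"])
    df["bin_width"] = frames.bin_width
    df["bin_volume_ml"] = frames.bin_volume_ml
    df["units"] = frames.units
    df.to_csv(path, index=False)


def read_frames(path: PathLike) -> ActivityFrames:
    df = pd.read_csv(path)
    bounds = sorted(set(zip(df["frame_start"], df["frame_end"])))
    depth = np.array(sorted(set(df["depth_mm"])))
    values = np.zeros((len(bounds), depth.size))
    index = {b: i for i, b in enumerate(bounds)}
    dindex = {d: i for i, d in enumerate(depth)}
    for _, row in df.iterrows():
        values[index[(row["frame_start"], row["frame_end"])],
               dindex[row["depth_mm"]]] = row["value"]
    return ActivityFrames(values=values, frame_bounds=tuple(bounds),
                          depth=depth,
                          bin_width=float(df["bin_width"].iloc[0]),
                          bin_volume_ml=float(df["bin_volume_ml"].iloc[0]),
                          units=str(df["units"].iloc[0]))


def write_fit(fit: IsotopeFit, path: PathLike) -> None:
    payload = {"isotopes": list(fit.isotopes),
               "a0": {k: list(map(float, v)) for k, v in fit.a0.items()},
               "residual_norm": list(map(float, fit.residual_norm)),
               "converged": fit.converged}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_fit(path: PathLike) -> IsotopeFit:
    payload = json.loads(Path(path).read_text())
    return IsotopeFit(a0={k: np.array(v) for k, v in payload["a0"].items()},
                      residual_norm=np.array(payload["residual_norm"]),
                      converged=payload["converged"],
                      isotopes=tuple(payload["isotopes"]))


def sha256_file(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
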