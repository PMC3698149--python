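"""Fixture presets and the staged analysis pipeline.

``make_*_fixtures`` write self-contained synthetic datasets (depth scans,
CT volume, PET frames) to disk; the pipeline stages read them back and run
the corresponding analysis, producing one artifact per stage plus a JSON
run report with the seed, package versions and artifact checksums.  Given
an identical configuration the outputs are byte-identical between runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from . import __version__, io
from .bragg import (SessionRecord, analyze_session, find_bragg_peak,
                    normalize_session)
from .datasets import CALCULATED_RANGES, MEASURED_GEL_WEPL, SAMPLE_LENGTH_MM
from .geometry import PetPhantomSpec, VialGeometry, spacer_gel, water
from .hlut import RoiSpec, default_hlut, hlut_lookup, roi_mean_hu
from .pet import IrradiationTimeline, fit_isotope_fractions
from .synthetic import (ScanSample, gen_activity_frames, gen_ct_phantom,
                        gen_depth_scan, gen_yield_profiles)


@dataclass(frozen=True)
class RunConfig:
    """Units are fixed package-wide: mm, mmH2O, s, Gy, Bq/ml."""

    seed: int
    out_dir: Path
    log_level: str = "info"

    def __post_init__(self) -> None:
        object.__setattr__(self, "out_dir", Path(self.out_dir))


# per-session alignment shifts emulating day-to-day beam/positioning drift;
# chosen to mirror the magnitudes seen in repeated qualification sessions.
_SESSION_SHIFTS = (0.0, 0.03, -0.69)
_SCAN_NOISE_SD = 0.01
_N_GEL_REPEATS = 3


def make_table2_fixtures(out_dir: Path, seed: int) -> list[Path]:
    """Write three sessions of synthetic depth scans plus geometry JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vial = VialGeometry()
    gel = spacer_gel(nominal_wepl=MEASURED_GEL_WEPL)
    samples = {
        "no_absorber": None,
        "empty_holder": None,
        "empty_vial": ScanSample(vial, None),
        "water_vial": ScanSample(vial, water()),
    }
    written: list[Path] = []
    for k, shift in enumerate(_SESSION_SHIFTS, start=1):
        sdir = out_dir / f"session{k}"
        sdir.mkdir(exist_ok=True)
        ref = CALCULATED_RANGES["no_absorber"] + shift
        for label, sample in samples.items():
            curve = gen_depth_scan(sample, ref, noise_sd=_SCAN_NOISE_SD,
                                   seed=seed * 100 + k * 10 + len(written))
            path = sdir / f"{label}.csv"
            io.write_depth_scan(curve, path)
            written.append(path)
        for rep in range(_N_GEL_REPEATS):
            curve = gen_depth_scan(ScanSample(vial, gel), ref,
                                   noise_sd=_SCAN_NOISE_SD,
                                   seed=seed * 100 + k * 10 + 5 + rep)
            path = sdir / f"gel_{rep + 1}.csv"
            io.write_depth_scan(curve, path)
            written.append(path)
    geom = out_dir / "geometry.json"
    geom.write_text(json.dumps({
        "inner_diameter": vial.inner_diameter,
        "inner_length_d": vial.inner_length_d,
        "cap_thickness": vial.cap_thickness,
        "pmma_wepl_factor": vial.pmma_wepl_factor,
    }, indent=2, sort_keys=True))
    written.append(geom)
    calc = out_dir / "calculated.json"
    calc.write_text(json.dumps(CALCULATED_RANGES, indent=2, sort_keys=True))
    written.append(calc)
    return written


def make_ct_fixtures(out_dir: Path, seed: int) -> list[Path]:
    """Write the vial-in-sphere CT volume (raw + JSON header) and an ROI."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    volume = gen_ct_phantom(seed=seed, air_bubble_fraction=0.01)
    header, raw = io.write_volume(volume, out_dir / "ct_volume")
    nz, ny, nx = volume.data.shape
    sz, sy, sx = volume.spacing
    # 15 mm ROI centred on the gel, on slices safely inside the 32 mm column
    centre = (ny * sy / 2.0, nx * sx / 2.0)
    half_slices = int(12.0 / sz)
    mid = nz // 2
    roi = RoiSpec(centre, 15.0,
                  tuple(range(mid - half_slices, mid + half_slices + 1)))
    roi_path = out_dir / "roi.json"
    io.write_roi(roi, roi_path)
    return [header, raw, roi_path]


def make_pet_fixtures(out_dir: Path, seed: int) -> list[Path]:
    """Write dynamic PET frames with timeline/phantom specs and ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    phantom = PetPhantomSpec()
    timeline = IrradiationTimeline()
    yields = gen_yield_profiles(phantom, beam_range=150.0, seed=seed)
    frames = gen_activity_frames(yields, timeline, seed=seed)
    frames_path = out_dir / "frames.csv"
    io.write_frames(frames, frames_path)
    timeline_path = out_dir / "timeline.json"
    io.write_timeline(timeline, timeline_path)
    phantom_path = out_dir / "phantom.json"
    phantom_path.write_text(json.dumps({
        "segments": [list(s) for s in phantom.segments],
        "gel_insert_mm": list(phantom.gel_insert_mm),
        "transverse_mm": phantom.transverse_mm,
        "beam_range_mm": 150.0,
    }, indent=2, sort_keys=True))
    return [frames_path, timeline_path, phantom_path]


def _read_session(sdir: Path) -> SessionRecord:
    refs = {}
    for label in ("no_absorber", "empty_holder", "empty_vial", "water_vial"):
        path = sdir / f"{label}.csv"
        if path.exists():
            refs[label] = find_bragg_peak(io.read_depth_scan(path))
    gels = tuple(find_bragg_peak(io.read_depth_scan(p))
                 for p in sorted(sdir.glob("gel_*.csv")))
    return SessionRecord(reference_measurements=refs, gel_measurements=gels,
                         calculated_reference=CALCULATED_RANGES["no_absorber"])


def _stage_table2_fixtures(config: RunConfig, ctx: dict) -> list[Path]:
    return make_table2_fixtures(config.out_dir / "fixtures", config.seed)


def _stage_table2_wepl(config: RunConfig, ctx: dict) -> list[Path]:
    fixture_dir = config.out_dir / "fixtures"
    artifacts: list[Path] = []
    results = {}
    for sdir in sorted(fixture_dir.glob("session*")):
        session = normalize_session(_read_session(sdir))
        result = analyze_session(session, SAMPLE_LENGTH_MM)
        path = config.out_dir / f"wepl_{sdir.name}.json"
        io.write_wepl_result(result, path)
        artifacts.append(path)
        results[sdir.name] = result.wepl
    ctx["wepl_results"] = results
    return artifacts


def _stage_ct_fixtures(config: RunConfig, ctx: dict) -> list[Path]:
    return make_ct_fixtures(config.out_dir / "fixtures_ct", config.seed)


def _stage_ct_hu(config: RunConfig, ctx: dict) -> list[Path]:
    fdir = config.out_dir / "fixtures_ct"
    volume = io.read_volume(fdir / "ct_volume.json")
    roi = io.read_roi(fdir / "roi.json")
    est = roi_mean_hu(volume, roi)
    predicted = hlut_lookup(default_hlut(), est.mean)
    path = config.out_dir / "hu.json"
    path.write_text(json.dumps({
        "mean_hu": est.mean,
        "sd_2sigma": est.sd_2sigma,
        "n_voxels": est.n_voxels,
        "hlut_predicted_wepl": predicted,
    }, indent=2, sort_keys=True))
    ctx["hu"] = est.mean
    return [path]


def _stage_pet_fixtures(config: RunConfig, ctx: dict) -> list[Path]:
    return make_pet_fixtures(config.out_dir / "fixtures_pet", config.seed)


def _stage_pet_fit(config: RunConfig, ctx: dict) -> list[Path]:
    frames = io.read_frames(config.out_dir / "fixtures_pet" / "frames.csv")
    fit = fit_isotope_fractions(frames, ["C11", "O15", "N13"])
    path = config.out_dir / "pet_fit.json"
    io.write_fit(fit, path)
    ctx["pet_fit_isotopes"] = fit.isotopes
    return [path]


STAGES: dict[str, Callable[[RunConfig, dict], list[Path]]] = {
    "table2_fixtures": _stage_table2_fixtures,
    "table2_wepl": _stage_table2_wepl,
    "ct_fixtures": _stage_ct_fixtures,
    "ct_hu": _stage_ct_hu,
    "pet_fixtures": _stage_pet_fixtures,
    "pet_fit": _stage_pet_fit,
}

PRESETS: dict[str, tuple[str, ...]] = {
    "table2": ("table2_fixtures", "table2_wepl"),
    "ct": ("ct_fixtures", "ct_hu"),
    "pet": ("pet_fixtures", "pet_fit"),
}


def run_pipeline(config: RunConfig, stages: list[str]) -> dict:
    """Execute stages in order; returns (and writes) the run report.

    Unknown stage names fail before anything executes.  The report records
    the seed, library versions and a checksum for every artifact, and is
    deterministic for a fixed configuration.
    """
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown pipeline stage(s): {unknown}")
    config.out_dir.mkdir(parents=True, exist_ok=True)
    ctx: dict = {}
    report_stages = []
    for name in stages:
        artifacts = STAGES[name](config, ctx)
        report_stages.append({
            "name": name,
            "artifacts": [{"path": str(p.relative_to(config.out_dir)),
                           "sha256": io.sha256_file(p)}
                          for p in artifacts],
        })
    report = {
        "seed": config.seed,
        "versions": {"gelrange": __version__, "numpy": np.__version__},
        "stages": report_stages,
        "results": {k: v for k, v in ctx.items()
                    if isinstance(v, (int, float, str, dict, list, tuple))},
    }
    report_path = config.out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True,
                                      default=str))
    return report
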