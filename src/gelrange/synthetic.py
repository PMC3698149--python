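"""Seeded generators emulating the measurement hardware.

Every pipeline input — water-column depth scans, the planning CT of the
vial-in-sphere phantom, and dynamic PET frames of the slab phantom — can be
generated here with the statistical structure the analysis assumes, so all
stages are testable end to end without instrument data.

Each generator is a bijection in its noiseless mode: the analysis stage
consuming its output recovers the configured ground truth exactly (peak
position, HU mean, per-isotope initial activities).  Randomness comes from
one seed per invocation; independent named substreams keep fixtures
decoupled from one another.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .bragg import DepthScanCurve
from .geometry import MaterialComposition, PetPhantomSpec, VialGeometry
from .hlut import CtVolume
from .pet import (ActivityFrames, IrradiationTimeline, activity_at_beam_end,
                  decay_over_delay, frame_average_factor, get_isotope)

AIR_HU = -1000.0
PMMA_HU = 120.0  # fixture convention; feeds only synthetic volumes


def substream_rng(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible RNG substream derived from one invocation seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                zlib.crc32(name.encode("utf-8"))]))


# ---------------------------------------------------------------------------
# depth-dose (Bragg) curve model
# ---------------------------------------------------------------------------

def _hermite(x: np.ndarray, x0: float, x1: float, y0: float, y1: float,
             m0: float, m1: float) -> np.ndarray:
    h = x1 - x0
    t = (x - x0) / h
    t2 = t * t
    t3 = t2 * t
    return (y0 * (2 * t3 - 3 * t2 + 1) + m0 * h * (t3 - 2 * t2 + t)
            + y1 * (-2 * t3 + 3 * t2) + m1 * h * (t3 - t2))


def bragg_curve(thickness, peak_position: float, *,
                plateau: float = 1.0,
                peak_amplitude: float = 3.5,
                parabola_halfwidth: float = 0.8,
                curvature: float = 0.35,
                rise_length: float = 8.0,
                falloff_length: float = 4.0,
                distal_tail: float = 0.03) -> np.ndarray:
    """Analytic unimodal charge-ratio model of a pristine Bragg curve.

    Piecewise construction in ``u = thickness - peak_position``: a constant
    entrance plateau for ``u <= -rise_length``, a monotone C1 Hermite rise,
    an exactly parabolic cap ``peak_amplitude - curvature * u**2`` for
    ``|u| <= parabola_halfwidth``, a monotone Hermite distal fall-off, and a
    constant fragmentation tail beyond ``falloff_length``.  The exactly
    quadratic cap makes the sub-step parabolic peak interpolation of the
    analysis bias-free regardless of the sampling phase, so the peak
    position parameter is recovered identically in noiseless scans.  Shape
    defaults mimic a 200 MeV/u carbon depth-dose curve (peak-to-plateau
    ratio 3.5, fall-off over a few mm).
    """
    if not 0 < parabola_halfwidth < min(rise_length, falloff_length):
        raise ValueError("parabola halfwidth must be smaller than the rise "
                         "and fall-off lengths")
    u = np.asarray(thickness, dtype=float) - peak_position
    w = parabola_halfwidth
    y_edge = peak_amplitude - curvature * w * w
    m_edge = 2.0 * curvature * w

    out = np.empty_like(u)
    out[u <= -rise_length] = plateau
    m = (u > -rise_length) & (u < -w)
    out[m] = _hermite(u[m], -rise_length, -w, plateau, y_edge, 0.0, m_edge)
    m = np.abs(u) <= w
    out[m] = peak_amplitude - curvature * u[m] ** 2
    m = (u > w) & (u < falloff_length)
    out[m] = _hermite(u[m], w, falloff_length, y_edge, distal_tail,
                      -m_edge, 0.0)
    out[u >= falloff_length] = distal_tail
    return out


@dataclass(frozen=True)
class ScanSample:
    """What sits in the beam during a depth scan: a vial and its content.

    ``vial=None`` models the bare beam (or the empty holder); ``content=None``
    an empty (air-filled) vial whose caps alone shift the peak.
    """

    vial: Optional[VialGeometry] = None
    content: Optional[MaterialComposition] = None

    def total_wepl(self) -> float:
        """Water-equivalent thickness the sample adds to the beam path."""
        if self.vial is None:
            return 0.0
        wepl = self.vial.caps_wepl
        if self.content is not None:
            wepl += self.content.nominal_wepl * self.vial.inner_length_d
        return wepl


def gen_depth_scan(sample: Optional[ScanSample], reference_range: float, *,
                   noise_sd: float = 0.0, step: float = 0.1,
                   window: Optional[tuple[float, float]] = None,
                   seed: int = 0,
                   model_params: Optional[Mapping[str, float]] = None
                   ) -> DepthScanCurve:
    """Simulate a water-column depth scan for a sample in the beam.

    The Bragg peak appears at ``reference_range - sample.total_wepl()`` on
    the water-column axis; optional additive Gaussian noise (``noise_sd``,
    charge-ratio units) is applied per point.  ``window`` gives absolute
    scan limits in mmH2O; by default the scan brackets the expected peak by
    20 mm proximally and 8 mm distally.  A window that does not bracket the
    peak (2 mm margin on both sides) raises ``ValueError``.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    peak = reference_range - (sample.total_wepl() if sample else 0.0)
    if window is None:
        window = (peak - 20.0, peak + 8.0)
    lo, hi = window
    if not (lo + 2.0 <= peak <= hi - 2.0):
        raise ValueError(
            f"scan window [{lo}, {hi}] does not bracket the Bragg peak "
            f"at {peak:.2f} mmH2O")
    grid = np.arange(lo, hi + step / 2.0, step)
    y = bragg_curve(grid, peak, **(dict(model_params) if model_params else {}))
    if noise_sd > 0:
        rng = substream_rng(seed, "depth_scan")
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return DepthScanCurve(grid, y, step)


# ---------------------------------------------------------------------------
# planning-CT phantom
# ---------------------------------------------------------------------------

def gen_ct_phantom(vial: Optional[VialGeometry] = None, *,
                   gel_hu_mean: float = 28.9,
                   hu_noise_sd: float = 3.05,
                   air_bubble_fraction: float = 0.0,
                   voxel_spacing: tuple[float, float, float] = (3.0, 0.6055,
                                                                0.6055),
                   phantom_diameter: float = 160.0,
                   pmma_hu: float = PMMA_HU,
                   margin: float = 6.0,
                   seed: int = 0) -> CtVolume:
    """Synthesise the CT of a gel-filled vial centred in a PMMA sphere.

    The gel cylinder (vial inner dimensions, axis along the slice
    direction) receives Gaussian voxel noise around ``gel_hu_mean``;
    ``air_bubble_fraction`` of its voxels are independently replaced by air
    (-1000 HU), emulating imperfect polymerisation.  The surrounding sphere
    is uniform PMMA, the background air.  The default noise level matches
    the 2-sigma HU spread observed on a clinical body protocol.
    """
    if vial is None:
        vial = VialGeometry()
    if any(s <= 0 for s in voxel_spacing):
        raise ValueError("voxel spacing must be > 0")
    if not 0.0 <= air_bubble_fraction < 0.5:
        raise ValueError("air_bubble_fraction must be in [0, 0.5)")
    radius = phantom_diameter / 2.0
    cyl_r = vial.inner_diameter / 2.0
    cyl_hl = vial.inner_length_d / 2.0
    if math.hypot(cyl_r, cyl_hl) > radius:
        raise ValueError("vial does not fit inside the spherical phantom")

    sz, sy, sx = voxel_spacing
    extent = phantom_diameter + 2.0 * margin
    nz = int(math.ceil(extent / sz))
    ny = int(math.ceil(extent / sy))
    nx = int(math.ceil(extent / sx))
    zz = (np.arange(nz) + 0.5) * sz - nz * sz / 2.0
    yy = (np.arange(ny) + 0.5) * sy - ny * sy / 2.0
    xx = (np.arange(nx) + 0.5) * sx - nx * sx / 2.0

    r2_inplane = (yy ** 2)[:, None] + (xx ** 2)[None, :]
    sphere = (zz ** 2)[:, None, None] + r2_inplane[None, :, :] <= radius ** 2
    cylinder = ((np.abs(zz) <= cyl_hl)[:, None, None]
                & (r2_inplane <= cyl_r ** 2)[None, :, :])

    vol = np.full((nz, ny, nx), AIR_HU, dtype=np.float32)
    vol[sphere] = pmma_hu
    n_gel = int(cylinder.sum())
    rng = substream_rng(seed, "ct_phantom")
    gel_vals = np.full(n_gel, gel_hu_mean, dtype=np.float64)
    if hu_noise_sd > 0:
        gel_vals += rng.normal(0.0, hu_noise_sd, size=n_gel)
    if air_bubble_fraction > 0:
        bubbles = rng.random(n_gel) < air_bubble_fraction
        gel_vals[bubbles] = AIR_HU
    vol[cylinder] = gel_vals.astype(np.float32)
    return CtVolume(vol, voxel_spacing)


# ---------------------------------------------------------------------------
# PET activation model
# ---------------------------------------------------------------------------

#: Fraction of the produced beta+ emitters per isotope, by material.
#: Carbon-rich PMMA is 11C-dominated; the water-dominated hydrogel and
#: gelatin produce mostly 15O from 16O(p,pn)15O.  No phantom material
#: contains potassium, so 38K is never produced.
ISOTOPE_MIX: dict[str, dict[str, float]] = {
    "pmma": {"C11": 0.75, "O15": 0.20, "N13": 0.05, "K38": 0.0},
    "gel": {"C11": 0.25, "O15": 0.65, "N13": 0.10, "K38": 0.0},
    "gelatin": {"C11": 0.30, "O15": 0.60, "N13": 0.10, "K38": 0.0},
}

#: Total beta+ emitters produced per primary per mm of path, by material.
YIELD_PER_PRIMARY_PER_MM: dict[str, float] = {
    "pmma": 4.0e-4,
    "gel": 3.2e-4,
    "gelatin": 3.4e-4,
}


@dataclass(frozen=True)
class YieldProfiles:
    """Per-isotope positron-emitter production along the beam axis.

    ``yields`` maps isotope name to the total number of nuclei produced per
    depth bin over the whole delivery (decay during irradiation is handled
    downstream); ``materials`` names the phantom material of each bin.
    """

    depth: np.ndarray
    bin_width: float
    materials: tuple[str, ...]
    yields: Mapping[str, np.ndarray]
    primaries: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "depth", np.asarray(self.depth, dtype=float))
        object.__setattr__(self, "yields",
                           {k: np.asarray(v, dtype=float)
                            for k, v in self.yields.items()})


def _depth_shape(z: np.ndarray, beam_range: float,
                 falloff_width: float) -> np.ndarray:
    """Plateau with a mild rise and a smooth distal fall-off.

    Exactly zero beyond ``beam_range + falloff_width``; the fall-off is a
    cubic smoothstep over ``[beam_range - falloff_width,
    beam_range + falloff_width]``.
    """
    base = 1.0 + 0.3 * z / beam_range
    t = np.clip((z - (beam_range - falloff_width)) / (2.0 * falloff_width),
                0.0, 1.0)
    fall = 1.0 - (3.0 * t ** 2 - 2.0 * t ** 3)
    return base * fall


def gen_yield_profiles(phantom: PetPhantomSpec, beam_range: float,
                       isotopes: Sequence[str] = ("C11", "O15", "N13"), *,
                       primaries: float = 2.24e11,
                       bin_width: float = 1.0,
                       falloff_width: float = 4.0,
                       seed: int = 0) -> YieldProfiles:
    """Parametric per-material, per-isotope production-yield depth profiles.

    Stands in for a Monte-Carlo transport calculation: each material
    produces emitters at a fixed rate per primary per mm, split between
    isotopes by :data:`ISOTOPE_MIX`, modulated by a plateau-plus-fall-off
    depth shape ending at ``beam_range``.  Deterministic and exactly linear
    in ``primaries``; the seed is accepted for interface symmetry with the
    stochastic generators.
    """
    del seed  # deterministic parametric model
    total = phantom.total_thickness
    if not 0.0 < beam_range < total:
        raise ValueError("beam range must lie inside the phantom")
    for iso in isotopes:
        if iso not in ISOTOPE_MIX["pmma"]:
            raise ValueError(f"unknown isotope label {iso!r}")
    z = np.arange(bin_width / 2.0, total, bin_width)
    materials = tuple(phantom.material_at(float(d)) for d in z)
    for mat in set(materials):
        if mat not in YIELD_PER_PRIMARY_PER_MM:
            raise ValueError(f"no yield model for material {mat!r}")
    shape = _depth_shape(z, beam_range, falloff_width)
    density = np.array([YIELD_PER_PRIMARY_PER_MM[m] for m in materials])
    yields = {}
    for iso in isotopes:
        mix = np.array([ISOTOPE_MIX[m][iso] for m in materials])
        yields[iso] = primaries * density * mix * shape * bin_width
    return YieldProfiles(depth=z, bin_width=bin_width, materials=materials,
                         yields=yields, primaries=primaries)


def expected_initial_activity(yields: YieldProfiles,
                              timeline: IrradiationTimeline,
                              bin_volume_ml: float = 10.0
                              ) -> dict[str, np.ndarray]:
    """Ground-truth A_0 concentration (Bq/ml) per isotope per depth bin.

    Applies the build-up and transport-delay closed forms to the production
    profiles; this is exactly what a perfect decomposition of noiseless
    frames recovers.
    """
    if bin_volume_ml <= 0:
        raise ValueError("bin volume must be > 0")
    out = {}
    for name, produced in yields.yields.items():
        iso = get_isotope(name)
        rate = produced / timeline.beam_on
        a_end = activity_at_beam_end(rate, iso, timeline.beam_on)
        out[name] = decay_over_delay(a_end, iso,
                                     timeline.delay) / bin_volume_ml
    return out


def gen_activity_frames(yields: YieldProfiles,
                        timeline: IrradiationTimeline, *,
                        bin_volume_ml: float = 10.0,
                        noiseless: bool = False,
                        seed: int = 0) -> ActivityFrames:
    """Dynamic PET frames from yield profiles and the irradiation timeline.

    Expected decays per bin per frame follow the build-up / delay / frame
    closed forms summed over isotopes; unless ``noiseless``, each expected
    count is Poisson-sampled and converted back to a frame-averaged
    concentration (Bq/ml) by frame length and bin volume.
    """
    a0 = expected_initial_activity(yields, timeline, bin_volume_ml)
    bounds = timeline.frames
    n_bins = yields.depth.size
    expected = np.zeros((len(bounds), n_bins))
    for f, (t1, t2) in enumerate(bounds):
        for name, conc in a0.items():
            expected[f] += conc * frame_average_factor(name, t1, t2)
    if noiseless:
        values = expected
    else:
        rng = substream_rng(seed, "activity_frames")
        values = np.empty_like(expected)
        for f, (t1, t2) in enumerate(bounds):
            dt = t2 - t1
            lam_counts = expected[f] * dt * bin_volume_ml
            counts = rng.poisson(lam_counts)
            values[f] = counts / (dt * bin_volume_ml)
    return ActivityFrames(values=values, frame_bounds=bounds,
                          depth=yields.depth, bin_width=yields.bin_width,
                          bin_volume_ml=bin_volume_ml, units="Bq/ml")
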