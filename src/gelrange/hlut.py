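"""CT number statistics, HU-to-WEPL lookup and range-shift arithmetic.

Ion treatment planning predicts particle range from the planning CT through
an empirical piecewise-linear Hounsfield look-up table (HLUT) mapping each
CT number to a water-equivalent path length per mm.  This module estimates
the mean HU of a region of interest, evaluates an HLUT, and turns a WEPL
discrepancy into the distal range shift and planning-margin extension it
implies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


class HlutDomainError(ValueError):
    """Requested HU value lies outside the table domain (no clamping)."""


@dataclass(frozen=True)
class Hlut:
    """Piecewise-linear HU -> WEPL table.

    Breakpoints are ``(hu, wepl)`` pairs with strictly increasing HU and
    non-decreasing WEPL, covering at least [-1000, 1500] HU.
    """

    breakpoints: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        bp = tuple((float(h), float(w)) for h, w in self.breakpoints)
        object.__setattr__(self, "breakpoints", bp)
        if len(bp) < 2:
            raise ValueError("HLUT needs at least two breakpoints")
        hu = np.array([h for h, _ in bp])
        wepl = np.array([w for _, w in bp])
        if not np.all(np.diff(hu) > 0):
            raise ValueError("HLUT HU values must be strictly increasing")
        if not np.all(np.diff(wepl) >= 0):
            raise ValueError("HLUT WEPL values must be non-decreasing")
        if hu[0] > -1000 or hu[-1] < 1500:
            raise ValueError("HLUT must cover at least [-1000, 1500] HU")

    @property
    def hu(self) -> np.ndarray:
        return np.array([h for h, _ in self.breakpoints])

    @property
    def wepl(self) -> np.ndarray:
        return np.array([w for _, w in self.breakpoints])


def default_hlut() -> Hlut:
    """Default clinical-style HLUT.

    Anchored at air (-1000 HU -> 0.001) and water (0 HU -> 1.000); the
    soft-tissue segment is calibrated so that the measured hydrogel CT
    number of 28.9 HU maps to a WEPL of 1.027, matching the planning-system
    pair used clinically for this material.  The bone-side breakpoints are
    generic conventions.
    """
    soft_tissue_100 = 1.0 + 0.027 * (100.0 / 28.9)
    return Hlut((
        (-1000.0, 0.001),
        (0.0, 1.000),
        (100.0, soft_tissue_100),
        (1500.0, 1.800),
        (3071.0, 2.500),
    ))


def hlut_lookup(hlut: Hlut, hu: float) -> float:
    """Linearly interpolate the table at ``hu``; exact at breakpoints.

    Raises :class:`HlutDomainError` outside the table domain rather than
    clamping, so fixture errors surface instead of saturating silently.
    """
    grid = hlut.hu
    if hu < grid[0] or hu > grid[-1]:
        raise HlutDomainError(
            f"HU {hu} outside HLUT domain [{grid[0]}, {grid[-1]}]")
    return float(np.interp(hu, grid, hlut.wepl))


@dataclass(frozen=True)
class CtVolume:
    """CT voxel array with isotropic-in-plane spacing.

    Axis order is (slice, row, column); ``spacing`` is (slice, row, column)
    in mm.  Voxel indices are 0-based; the physical position of voxel ``i``
    along an axis is ``(i + 0.5) * spacing`` (voxel-centre convention,
    half-open extents).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "spacing", tuple(float(s)
                                                  for s in self.spacing))
        if arr.ndim != 3:
            raise ValueError("CT volume must be 3-D (slice, row, column)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be > 0")
        if arr.size and (arr.min() < -1024 or arr.max() > 3071):
            raise ValueError("HU values must lie within [-1024, 3071]")


@dataclass(frozen=True)
class RoiSpec:
    """Circular in-slice region of interest repeated over several slices.

    ``centre`` is the (row_mm, col_mm) physical in-slice centre, ``diameter``
    in mm, ``slices`` the 0-based slice indices included.
    """

    centre: tuple[float, float]
    diameter: float
    slices: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("ROI diameter must be > 0")
        object.__setattr__(self, "slices", tuple(int(s) for s in self.slices))
        if not self.slices:
            raise ValueError("ROI must list at least one slice")


@dataclass(frozen=True)
class HuEstimate:
    mean: float
    sd_2sigma: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.n_voxels <= 0:
            raise ValueError("n_voxels must be > 0")


def roi_mean_hu(volume: CtVolume, roi: RoiSpec) -> HuEstimate:
    """Mean and 2-sigma standard deviation of HU inside a circular ROI.

    A voxel belongs to the ROI when its in-slice centre lies within the
    circle (voxel-centre inclusion), evaluated on every listed slice.  The
    result is invariant to the order of the slice list and to translating
    ROI and content together.
    """
    nz, ny, nx = volume.data.shape
    _, sy, sx = volume.spacing
    cy, cx = roi.centre
    yy = (np.arange(ny) + 0.5) * sy
    xx = (np.arange(nx) + 0.5) * sx
    dist2 = ((yy - cy) ** 2)[:, None] + ((xx - cx) ** 2)[None, :]
    mask = dist2 <= (roi.diameter / 2.0) ** 2
    vals: list[np.ndarray] = []
    for s in roi.slices:
        if not 0 <= s < nz:
            raise ValueError(f"slice index {s} outside volume")
        vals.append(volume.data[s][mask])
    flat = np.concatenate(vals) if vals else np.array([])
    if flat.size == 0:
        raise ValueError("ROI contains no voxel centres")
    mean = float(flat.mean())
    sd = float(flat.std(ddof=1)) if flat.size > 1 else 0.0
    return HuEstimate(mean=mean, sd_2sigma=2.0 * sd, n_voxels=int(flat.size))


def wepl_discrepancy(predicted: float, measured: float) -> float:
    """CT/HLUT-predicted WEPL minus directly measured WEPL."""
    if predicted <= 0 or measured <= 0:
        raise ValueError("WEPL values must be > 0")
    return predicted - measured


def range_shift(delta_wepl: float, path_length: float) -> float:
    """Distal range shift (mm) from a WEPL error over a path length in the
    material: ``delta_wepl * path_length``."""
    if path_length < 0:
        raise ValueError("path length must be >= 0")
    return delta_wepl * path_length


def margin_extension(base_margin: float, gel_shift: float) -> float:
    """PTV margin growth when an independent random shift joins the budget.

    Independent contributions combine in quadrature, so the extension is
    ``sqrt(base^2 + shift^2) - base``; it never exceeds the shift itself.
    """
    if base_margin < 0 or gel_shift < 0:
        raise ValueError("margins and shifts must be >= 0")
    return math.hypot(base_margin, gel_shift) - base_margin
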