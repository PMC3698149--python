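"""Bragg-peak localisation and water-equivalent path length (WEPL) analysis.

A range measurement records the ratio of the charge collected in two
parallel-plane ionisation chambers while a water column of variable
thickness sits between them.  Plotting charge ratio against water-column
setting traces the depth-dose curve; the Bragg peak position on that axis is
the residual range of the beam behind the sample, in mmH2O.

Placing a sample of physical length ``d`` (mm) in the beam shifts the peak
to shallower water-column settings by the sample's water-equivalent
thickness.  Comparing a vial filled with water against the same vial filled
with gel cancels every common term (caps, holder, beam energy), leaving

    WEPL_gel = 1 + (vial_w - vial_g) / d

where ``vial_w`` and ``vial_g`` are the peak positions measured with the
water-filled and gel-filled vial.  A water-equivalent sample gives exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

#: Labels of the per-session reference measurements, in acquisition order.
REFERENCE_LABELS = ("no_absorber", "empty_holder", "empty_vial", "water_vial")


class PeakNotBracketedError(ValueError):
    """The charge-ratio maximum lies at (or beyond) the scan window edge."""


@dataclass(frozen=True)
class DepthScanCurve:
    """Charge ratio versus water-column thickness for one depth scan.

    ``absorber_thickness`` is the water-column setting in mmH2O, strictly
    increasing; ``step`` is the nominal scan step in mm.
    """

    absorber_thickness: np.ndarray
    charge_ratio: np.ndarray
    step: float

    def __post_init__(self) -> None:
        x = np.asarray(self.absorber_thickness, dtype=float)
        y = np.asarray(self.charge_ratio, dtype=float)
        object.__setattr__(self, "absorber_thickness", x)
        object.__setattr__(self, "charge_ratio", y)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("thickness and charge ratio must be 1-D and "
                             "equally long")
        if x.size >= 2 and not np.all(np.diff(x) > 0):
            raise ValueError("absorber thickness must be strictly increasing")
        if self.step <= 0:
            raise ValueError("step must be > 0")

    def __len__(self) -> int:
        return int(self.absorber_thickness.size)


@dataclass(frozen=True)
class BraggPeakEstimate:
    """Sub-step Bragg-peak position with its fit standard uncertainty.

    ``position`` is the peak location on the water-column axis (mmH2O);
    ``u_fit`` is the 1-sigma standard error of the parabola vertex.
    """

    position: float
    u_fit: float = 0.0
    n_points_used: int = 0

    def __post_init__(self) -> None:
        if self.u_fit < 0:
            raise ValueError("u_fit must be >= 0")


def find_bragg_peak(curve: DepthScanCurve,
                    window_halfwidth: int = 3) -> BraggPeakEstimate:
    """Locate the Bragg peak by a local parabolic fit around the maximum.

    A parabola is fitted to up to ``2 * window_halfwidth + 1`` points centred
    on the sampled maximum (5 to 9 points for the default and permitted
    values); the vertex gives the sub-step peak position.  The vertex
    standard error is propagated from the fit residuals by the delta method.

    Raises
    ------
    ValueError
        If the curve has fewer than five points.
    PeakNotBracketedError
        If the maximum sits at the scan edge or the window holds no concave
        maximum, i.e. the peak is not bracketed by the scan.
    """
    if not 2 <= window_halfwidth <= 4:
        raise ValueError("window_halfwidth must be 2, 3 or 4")
    x = curve.absorber_thickness
    y = curve.charge_ratio
    n = len(curve)
    if n < 5:
        raise ValueError("need at least 5 scan points to bracket a peak")
    i = int(np.argmax(y))
    if i < 2 or i > n - 3:
        raise PeakNotBracketedError(
            "charge-ratio maximum at the scan window edge")
    half = min(window_halfwidth, i, n - 1 - i)
    sl = slice(i - half, i + half + 1)
    dx = x[sl] - x[i]
    yy = y[sl]
    design = np.vander(dx, 3, increasing=True)  # columns 1, dx, dx^2
    coef, *_ = np.linalg.lstsq(design, yy, rcond=None)
    c0, c1, c2 = coef
    if c2 >= 0:
        raise PeakNotBracketedError("no concave maximum inside the fit window")
    vertex = float(x[i] - c1 / (2.0 * c2))
    if not (x[0] < vertex < x[-1]):
        raise PeakNotBracketedError("fitted vertex outside the scan window")

    m = yy.size
    u_fit = 0.0
    dof = m - 3
    if dof > 0:
        resid = yy - design @ coef
        s2 = float(resid @ resid) / dof
        if s2 > 0.0:
            cov = s2 * np.linalg.inv(design.T @ design)
            grad = np.array([0.0, -1.0 / (2.0 * c2), c1 / (2.0 * c2 ** 2)])
            var_v = float(grad @ cov @ grad)
            u_fit = math.sqrt(max(var_v, 0.0))
    return BraggPeakEstimate(position=vertex, u_fit=u_fit, n_points_used=m)


@dataclass(frozen=True)
class SessionRecord:
    """One measurement session: reference scans plus repeated gel scans.

    ``reference_measurements`` maps the labels in :data:`REFERENCE_LABELS`
    to peak estimates; ``gel_measurements`` holds the repeated gel-vial
    acquisitions (vial rotated between repeats).  ``calculated_reference``
    is the beam-model range without any absorber; ``offset`` accumulates the
    additive normalisation already applied to this record.
    """

    reference_measurements: Mapping[str, BraggPeakEstimate]
    gel_measurements: tuple[BraggPeakEstimate, ...]
    calculated_reference: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference_measurements",
                           dict(self.reference_measurements))
        object.__setattr__(self, "gel_measurements",
                           tuple(self.gel_measurements))


def normalize_session(session: SessionRecord) -> SessionRecord:
    """Apply the per-session additive offset fixed by the no-absorber scan.

    The offset is ``calculated_reference - measured no-absorber position``
    and is added uniformly to every measurement of the session, so all
    pairwise differences (and hence any WEPL derived from them) are
    unchanged.  Applying the normalisation twice is a no-op.
    """
    ref = session.reference_measurements.get("no_absorber")
    if ref is None:
        raise ValueError("session lacks the no-absorber reference scan")
    off = session.calculated_reference - ref.position

    def shift(est: BraggPeakEstimate) -> BraggPeakEstimate:
        return replace(est, position=est.position + off)

    return replace(
        session,
        reference_measurements={k: shift(v) for k, v in
                                session.reference_measurements.items()},
        gel_measurements=tuple(shift(e) for e in session.gel_measurements),
        offset=session.offset + off,
    )


def wepl_from_shift(vial_w: float, vial_g: float, d: float) -> float:
    """WEPL of the sample from the water-vial/gel-vial peak shift.

    Parameters are the two peak positions in mmH2O and the sample column
    length ``d`` in mm (caps excluded).
    """
    if d <= 0:
        raise ValueError("sample length d must be > 0")
    return 1.0 + (vial_w - vial_g) / d


def pmma_wepl(thickness: float, factor: float = 1.165) -> float:
    """Water-equivalent thickness of a PMMA slab of given physical thickness."""
    if thickness < 0:
        raise ValueError("thickness must be >= 0")
    if factor <= 0:
        raise ValueError("WEPL factor must be > 0")
    return thickness * factor


def combine_uncertainty(components: Mapping[str, float],
                        n_repeats: int = 1) -> float:
    """Quadrature combination of the range-measurement uncertainty budget.

    ``components`` holds the individual contributions in mmH2O.  The keys
    ``u_step`` (water-column stepping), ``u_fit`` (peak interpolation) and
    ``u_vial`` (vial manufacture, already converted to mmH2O) are treated as
    2-sigma-level bounds and summed in quadrature unchanged.  The optional
    key ``u_sample`` is the 1-sigma standard deviation over the repeated,
    rotated gel acquisitions and enters as the 2-sigma standard error of
    their mean, ``2 * u_sample / sqrt(n_repeats)``.

    Returns the combined 2-sigma uncertainty in mmH2O.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    q = 0.0
    for key, val in components.items():
        if val < 0:
            raise ValueError(f"uncertainty component {key!r} must be >= 0")
        if key == "u_sample":
            q += (2.0 * val / math.sqrt(n_repeats)) ** 2
        else:
            q += val ** 2
    return math.sqrt(q)


def air_fraction_effect(air_fraction: float, d: float,
                        wepl_material: float) -> tuple[float, float]:
    """Systematic effect of trapped air replacing part of the sample column.

    If a fraction of the vial volume is air (WEPL ~ 0) instead of material
    with water-equivalence ``wepl_material``, the Bragg peak moves deeper by
    ``air_fraction * d * wepl_material`` mmH2O and the apparent WEPL of the
    sample drops by that shift divided by ``d``.

    Returns ``(peak_shift_mmH2O, wepl_change)``.
    """
    if not 0.0 <= air_fraction < 1.0:
        raise ValueError("air_fraction must be in [0, 1)")
    if d <= 0:
        raise ValueError("sample length d must be > 0")
    shift = air_fraction * d * wepl_material
    return shift, shift / d


@dataclass(frozen=True)
class WeplResult:
    """Sample WEPL with its 2-sigma uncertainty budget.

    ``components`` reports each contribution on the WEPL (dimensionless)
    scale; the total is their quadrature sum and therefore bounds each one.
    """

    wepl: float
    u_total_2sigma: float
    components: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.wepl <= 0:
            raise ValueError("wepl must be > 0")
        object.__setattr__(self, "components", dict(self.components))


def analyze_session(session: SessionRecord, d: float, *,
                    u_step: float = 0.1,
                    u_vial_mm: float = 0.05,
                    pmma_factor: float = 1.165) -> WeplResult:
    """Compute the gel WEPL and its uncertainty budget for one session.

    Uses the water-vial reference peak and the mean of the repeated gel
    peaks.  Position-level components (step, fit, vial) affect both peak
    positions independently and therefore enter the WEPL uncertainty as
    ``sqrt(2) * component / d``; the sample-scatter term affects only the
    gel mean and enters as ``(2 * sd / sqrt(n)) / d``.
    """
    water = session.reference_measurements.get("water_vial")
    if water is None:
        raise ValueError("session lacks the water-vial reference scan")
    if not session.gel_measurements:
        raise ValueError("session holds no gel measurements")
    gels = np.array([e.position for e in session.gel_measurements])
    wepl = wepl_from_shift(water.position, float(gels.mean()), d)

    fits = [water.u_fit] + [e.u_fit for e in session.gel_measurements]
    u_fit = 2.0 * float(np.mean(fits))  # 1-sigma SE -> 2-sigma bound
    u_vial = pmma_wepl(u_vial_mm, pmma_factor)
    sd = float(gels.std(ddof=1)) if gels.size > 1 else 0.0
    n = gels.size

    comps = {
        "u_step": math.sqrt(2.0) * u_step / d,
        "u_fit": math.sqrt(2.0) * u_fit / d,
        "u_vial": math.sqrt(2.0) * u_vial / d,
        "u_sample": (2.0 * sd / math.sqrt(n)) / d,
    }
    total = math.sqrt(sum(v ** 2 for v in comps.values()))
    return WeplResult(wepl=wepl, u_total_2sigma=total, components=comps)
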