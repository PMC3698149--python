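"""Bundled reference measurements from the hydrogel qualification study.

Carbon-ion (200 MeV/u) range measurements of the clinical hydrogel spacer
performed in three sessions over ten weeks with a water-column absorber,
plus the planning-CT characterisation scalars.  Raw values are as acquired
(before per-session normalisation); spreads are quoted at 2 sigma over the
listed number of rotated-vial repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .bragg import BraggPeakEstimate, SessionRecord

#: Sample column length inside the vial, mm (caps excluded).
SAMPLE_LENGTH_MM = 32.0

#: Beam-model (calculated) ranges for the reference configurations, mmH2O.
CALCULATED_RANGES = {
    "no_absorber": 86.65,
    "empty_holder": 86.65,
    "empty_vial": 70.69,
    "water_vial": 38.51,
}


@dataclass(frozen=True)
class GelSeries:
    """Mean peak position over repeated, rotated gel-vial scans."""

    mean: float
    two_sigma: float
    n: int


@dataclass(frozen=True)
class RangeSession:
    """Raw (un-normalised) peak positions of one measurement session."""

    label: str
    no_absorber: float
    empty_holder: float
    empty_vial: float
    water_vial: float
    gel: GelSeries
    gel_after_high_dose: Optional[GelSeries] = None


RANGE_SESSIONS: tuple[RangeSession, ...] = (
    RangeSession("session1", 86.65, 86.61, 70.80, 38.71,
                 GelSeries(38.31, 0.30, 3)),
    RangeSession("session2", 86.68, 86.69, 70.80, 38.72,
                 GelSeries(38.27, 0.29, 5)),
    RangeSession("session3", 85.96, 85.97, 70.00, 38.02,
                 GelSeries(37.63, 0.29, 3),
                 gel_after_high_dose=GelSeries(37.68, 0.51, 3)),
)

#: Directly measured hydrogel water-equivalence (2 sigma) pooled over the
#: three sessions, and the pooled mean gel-vial peak position in mmH2O.
MEASURED_GEL_WEPL = 1.011
MEASURED_GEL_WEPL_2SIGMA = 0.011
POOLED_GEL_RANGE = 38.31
POOLED_GEL_RANGE_2SIGMA = 0.28

#: Planning-CT characterisation of the gel (body protocol, 15 mm ROI).
MEASURED_GEL_HU = 28.9
MEASURED_GEL_HU_2SIGMA = 6.1

#: Typical beam penetration depth through homogeneous gel used for
#: range-shift estimates, and the pelvic PTV safety margins in use.
TYPICAL_GEL_PATH_MM = 40.0
PTV_MARGIN_RANGE_MM = (5.0, 7.0)


def session_record(session: RangeSession,
                   use_after_high_dose: bool = False) -> SessionRecord:
    """Convert a bundled session into an analysable :class:`SessionRecord`.

    Only peak positions are carried over; per-scan fit uncertainties were
    not reported and are set to zero.  With ``use_after_high_dose`` the
    post-irradiation gel series (where present) replaces the regular one.
    """
    series = session.gel_after_high_dose if use_after_high_dose else session.gel
    if series is None:
        raise ValueError(f"{session.label} has no post-irradiation series")
    refs = {
        "no_absorber": BraggPeakEstimate(session.no_absorber),
        "empty_holder": BraggPeakEstimate(session.empty_holder),
        "empty_vial": BraggPeakEstimate(session.empty_vial),
        "water_vial": BraggPeakEstimate(session.water_vial),
    }
    return SessionRecord(
        reference_measurements=refs,
        gel_measurements=(BraggPeakEstimate(series.mean),),
        calculated_reference=CALCULATED_RANGES["no_absorber"],
    )
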