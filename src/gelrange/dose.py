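"""RBE-weighted to absorbed dose conversion and high-dose plan specs.

The prescription in ion therapy is an RBE-weighted dose D_ion (Gy (RBE));
with a constant relative biological effectiveness the absorbed (physical)
dose follows from RBE = D_gamma / D_ion at iso-effect, i.e. absorbed dose =
prescribed dose / RBE.  Constant RBE values of 3 (carbon ions) and 1.1
(protons) are the conservative planning assumptions for the pelvic target.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PlanSpec:
    """Irradiation plan parameters for the high-dose stability test."""

    species: str
    prescribed_rbe_weighted_dose: float  # Gy (RBE)
    rbe: float
    field_dimensions: tuple[float, float, float]  # mm (X, Y, Z)
    spot_fwhm: float  # mm

    def __post_init__(self) -> None:
        if self.species not in ("carbon", "proton"):
            raise ValueError("species must be 'carbon' or 'proton'")
        if self.rbe <= 0:
            raise ValueError("rbe must be > 0")
        if self.prescribed_rbe_weighted_dose < 0:
            raise ValueError("prescribed dose must be >= 0")

    @property
    def absorbed_dose(self) -> float:
        return absorbed_from_rbe_weighted(self.prescribed_rbe_weighted_dose,
                                          self.rbe)


#: 100 Gy (RBE) single-delivery plans used for the gel stability test.
CARBON_PLAN = PlanSpec("carbon", 100.0, 3.0, (32.0, 55.0, 40.0), 6.0)
PROTON_PLAN = PlanSpec("proton", 100.0, 1.1, (25.0, 65.0, 25.0), 12.0)


def absorbed_from_rbe_weighted(d_rbe: float, rbe: float) -> float:
    """Absorbed dose (Gy) from an RBE-weighted dose (Gy (RBE)).

    Returns the exact quotient; integer-Gy rounding is a presentation rule
    applied only by :func:`report_integer_gy`.
    """
    if rbe <= 0:
        raise ValueError("rbe must be > 0")
    if d_rbe < 0:
        raise ValueError("dose must be >= 0")
    return d_rbe / rbe


def report_integer_gy(dose: float) -> int:
    """Round a dose to the integer Gy used in human-readable plan tables."""
    return int(round(dose))
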