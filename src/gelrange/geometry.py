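"""Sample and phantom geometry.

The measurement vial is a watertight PMMA cylinder closed by two caps; the
beam traverses both caps and the enclosed sample column, so the caps enter
every range measurement as a fixed water-equivalent offset.  The PET phantom
is a PMMA box holding a stack of PMMA slabs, a rectangular hydrogel insert
and a gelatin backfill along the beam axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping


@dataclass(frozen=True)
class VialGeometry:
    """Cylindrical PMMA sample vial used for water-column range measurements.

    Lengths in mm.  ``pmma_wepl_factor`` converts a physical mm of PMMA into
    mm of water-equivalent path (mmH2O per mm).
    """

    inner_diameter: float = 20.0
    inner_length_d: float = 32.0
    cap_thickness: float = 6.85
    pmma_wepl_factor: float = 1.165

    def __post_init__(self) -> None:
        for name in ("inner_diameter", "inner_length_d", "cap_thickness",
                     "pmma_wepl_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def caps_wepl(self) -> float:
        """Water-equivalent thickness of the two caps, mmH2O."""
        return 2.0 * self.cap_thickness * self.pmma_wepl_factor

    @property
    def volume_ml(self) -> float:
        """Inner (sample) volume in millilitres."""
        r = self.inner_diameter / 2.0
        return math.pi * r * r * self.inner_length_d / 1000.0


@dataclass(frozen=True)
class MaterialComposition:
    """A material with elemental mass fractions and nominal imaging properties.

    ``fractions`` maps element symbols to mass fractions summing to one.
    ``nominal_wepl`` is the water-equivalent path length per physical mm
    (dimensionless), ``nominal_hu`` the expected CT number.
    """

    name: str
    fractions: Mapping[str, float]
    nominal_wepl: float
    nominal_hu: float

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"mass fractions of {self.name!r} sum to {total}, expected 1")
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("mass fractions must be non-negative")


def _mix(parts: Mapping[str, float],
         components: Mapping[str, Mapping[str, float]]) -> dict[str, float]:
    out: dict[str, float] = {}
    for comp, w in parts.items():
        for el, f in components[comp].items():
            out[el] = out.get(el, 0.0) + w * f
    total = sum(out.values())
    return {el: f / total for el, f in out.items()}


# Elemental mass fractions of the building blocks.
_WATER_EL = {"H": 0.111894, "O": 0.888106}
# polyethylene glycol repeat unit C2H6O2 (M = 62.068 g/mol)
_PEG_EL = {"C": 0.386991, "H": 0.097436, "O": 0.515573}
_PMMA_EL = {"C": 0.599848, "H": 0.080538, "O": 0.319614}
# gelatin phantom fill: predominantly water with a small protein fraction
_GELATIN_EL = {"H": 0.1066, "C": 0.0266, "N": 0.0091, "O": 0.8577}


def water() -> MaterialComposition:
    return MaterialComposition("water", _WATER_EL, nominal_wepl=1.0,
                               nominal_hu=0.0)


def spacer_gel(nominal_wepl: float = 1.011,
               nominal_hu: float = 28.9) -> MaterialComposition:
    """Hydrogel spacer: 90 % water, 10 % polyethylene glycol by mass.

    The default water-equivalence and CT number are the measured values of
    the qualified clinical hydrogel; both are overridable for simulation
    studies.
    """
    fractions = _mix({"water": 0.9, "peg": 0.1},
                     {"water": _WATER_EL, "peg": _PEG_EL})
    return MaterialComposition("gel", fractions, nominal_wepl, nominal_hu)


def pmma(nominal_hu: float = 120.0) -> MaterialComposition:
    return MaterialComposition("pmma", _PMMA_EL, nominal_wepl=1.165,
                               nominal_hu=nominal_hu)


def gelatin() -> MaterialComposition:
    return MaterialComposition("gelatin", _GELATIN_EL, nominal_wepl=1.02,
                               nominal_hu=20.0)


@dataclass(frozen=True)
class PetPhantomSpec:
    """Layered slab phantom for the offline-PET activation study.

    ``segments`` lists ``(material_name, thickness_mm)`` along the beam axis,
    entrance first.  The hydrogel insert sits between PMMA slabs and gelatin
    backfill; its dimensions are (beam-axis, height, width) in mm.
    """

    segments: tuple[tuple[str, float], ...] = (
        ("pmma", 100.0), ("gel", 20.0), ("gelatin", 230.0))
    gel_insert_mm: tuple[float, float, float] = (20.0, 40.0, 100.0)
    transverse_mm: float = 100.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("phantom needs at least one segment")
        for name, thick in self.segments:
            if thick <= 0:
                raise ValueError(f"segment {name!r} thickness must be > 0")
        gel_segments = [t for n, t in self.segments if n == "gel"]
        depth, height, width = self.gel_insert_mm
        if gel_segments and depth > max(gel_segments) + 1e-9:
            raise ValueError("gel insert thicker than its slot")
        if height > self.transverse_mm or width > self.transverse_mm:
            raise ValueError("gel insert exceeds transverse phantom extent")

    @property
    def total_thickness(self) -> float:
        return sum(t for _, t in self.segments)

    def material_at(self, depth_mm: float) -> str:
        """Material name at a beam-axis depth (mm from the entrance face)."""
        if depth_mm < 0 or depth_mm > self.total_thickness:
            raise ValueError("depth outside phantom")
        z = 0.0
        for name, thick in self.segments:
            z += thick
            if depth_mm <= z:
                return name
        return self.segments[-1][0]
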