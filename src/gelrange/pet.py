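"""Time evolution and decomposition of beam-induced positron-emitter activity.

Inelastic nuclear reactions during irradiation produce beta+ emitters whose
activity builds up while the beam is on, decays during the transport delay
to the PET scanner, and is then integrated over reconstruction frames of
the acquisition.  With a constant production rate R (nuclei/s) per depth
bin, the chain per isotope (decay constant lambda = ln 2 / T_half) is

    build-up       A(T_beam)   = R * (1 - exp(-lambda * T_beam))
    transport      A_0         = A(T_beam) * exp(-lambda * delta)
    frame average  <A>(t1, t2) = A_0 * (exp(-lambda t1) - exp(-lambda t2))
                                     / (lambda * (t2 - t1))

with frame times relative to the acquisition start.  Because the half-lives
of the candidate isotopes are known and fixed, a dynamic acquisition is a
linear model in the per-isotope initial activities A_0, which are recovered
per depth bin by non-negative least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
from scipy.optimize import nnls

LN2 = math.log(2.0)


@dataclass(frozen=True)
class IsotopeSpec:
    """A beta+ emitter with a fixed, known half-life (seconds)."""

    name: str
    half_life: float

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError("half-life must be > 0")

    @property
    def lam(self) -> float:
        """Decay constant ln(2) / T_half, 1/s."""
        return LN2 / self.half_life


#: Candidate emitters for proton/carbon activation of tissue-like media.
#: 38K occurs only in potassium-bearing tissue, never in PMMA, hydrogel or
#: gelatin phantom materials.
DEFAULT_ISOTOPES: dict[str, IsotopeSpec] = {
    "C11": IsotopeSpec("C11", 1222.0),
    "O15": IsotopeSpec("O15", 120.0),
    "N13": IsotopeSpec("N13", 598.0),
    "K38": IsotopeSpec("K38", 458.0),
}


def get_isotope(isotope: Union[str, IsotopeSpec]) -> IsotopeSpec:
    if isinstance(isotope, IsotopeSpec):
        return isotope
    try:
        return DEFAULT_ISOTOPES[isotope]
    except KeyError:
        raise ValueError(f"unknown isotope label {isotope!r}") from None


@dataclass(frozen=True)
class IrradiationTimeline:
    """Beam-on, transport-delay and acquisition time structure (seconds).

    ``frame_boundaries`` are contiguous times within the acquisition,
    starting at 0 and ending at ``acquisition``.  The default framing splits
    the acquisition into ten 180 s frames: short enough that the first
    frames still resolve 15O (T_half 120 s), long enough that late frames
    accumulate 11C statistics.
    """

    beam_on: float = 215.0
    delay: float = 176.0
    acquisition: float = 1800.0
    frame_boundaries: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.beam_on <= 0 or self.acquisition <= 0:
            raise ValueError("beam_on and acquisition must be > 0")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        fb = tuple(float(t) for t in self.frame_boundaries)
        if not fb:
            fb = tuple(np.linspace(0.0, self.acquisition, 11))
        if fb[0] != 0.0 or abs(fb[-1] - self.acquisition) > 1e-9:
            raise ValueError("frames must start at 0 and cover the "
                             "acquisition")
        if any(b - a <= 0 for a, b in zip(fb, fb[1:])):
            raise ValueError("frame boundaries must be strictly increasing")
        object.__setattr__(self, "frame_boundaries", fb)

    @property
    def frames(self) -> tuple[tuple[float, float], ...]:
        fb = self.frame_boundaries
        return tuple(zip(fb, fb[1:]))


@dataclass(frozen=True)
class ActivityFrames:
    """Frame-averaged activity per depth bin, shape (n_frames, n_bins).

    ``values`` are frame-averaged activity concentrations (Bq/ml by
    default) or, for count data, decays per frame; ``depth`` holds the bin
    centres in mm.
    """

    values: np.ndarray
    frame_bounds: tuple[tuple[float, float], ...]
    depth: np.ndarray
    bin_width: float
    bin_volume_ml: float = 1.0
    units: str = "Bq/ml"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "depth", np.asarray(self.depth, dtype=float))
        object.__setattr__(self, "frame_bounds",
                           tuple((float(a), float(b))
                                 for a, b in self.frame_bounds))
        if vals.ndim != 2:
            raise ValueError("values must be 2-D (frame, depth)")
        if vals.shape[0] != len(self.frame_bounds):
            raise ValueError("frame count mismatch")
        if vals.shape[1] != self.depth.size:
            raise ValueError("depth bin count mismatch")
        if np.any(vals < 0):
            raise ValueError("activity values must be non-negative")
        if self.bin_width <= 0 or self.bin_volume_ml <= 0:
            raise ValueError("bin width and volume must be > 0")


class RankDeficientBasisError(ValueError):
    """Frame design cannot separate the requested isotopes."""


def activity_at_beam_end(production_rate, isotope: Union[str, IsotopeSpec],
                         beam_on: float):
    """Activity after constant production over the beam-on time.

    ``production_rate`` is the production rate R in nuclei/s (scalar or
    per-bin array).  Saturates at R for long irradiations and reduces to
    R * lambda * T in the short-irradiation limit.
    """
    iso = get_isotope(isotope)
    if beam_on < 0:
        raise ValueError("beam_on must be >= 0")
    rate = np.asarray(production_rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("production rate must be >= 0")
    out = rate * (-np.expm1(-iso.lam * beam_on))
    return float(out) if np.isscalar(production_rate) else out


def decay_over_delay(a_end, isotope: Union[str, IsotopeSpec], delay: float):
    """Exponential decay of the beam-end activity over the transport delay."""
    iso = get_isotope(isotope)
    if delay < 0:
        raise ValueError("delay must be >= 0")
    a = np.asarray(a_end, dtype=float)
    out = a * math.exp(-iso.lam * delay)
    return float(out) if np.isscalar(a_end) else out


def frame_average_factor(isotope: Union[str, IsotopeSpec],
                         t1: float, t2: float) -> float:
    """Mean of exp(-lambda t) over [t1, t2]: the <A>/A_0 ratio of a frame."""
    iso = get_isotope(isotope)
    if not (t2 > t1 >= 0):
        raise ValueError("frame must satisfy t2 > t1 >= 0")
    lam = iso.lam
    dt = t2 - t1
    # exp(-lam t1) - exp(-lam t2) via expm1: stable for short frames
    return float(math.exp(-lam * t1) * (-math.expm1(-lam * dt)) / (lam * dt))


def frame_average(a_start, isotope: Union[str, IsotopeSpec],
                  frame: tuple[float, float]):
    """Frame-averaged activity <A> given the activity at acquisition start."""
    t1, t2 = frame
    factor = frame_average_factor(isotope, t1, t2)
    a = np.asarray(a_start, dtype=float)
    out = a * factor
    return float(out) if np.isscalar(a_start) else out


def laterally_integrate(activity_volume) -> np.ndarray:
    """Sum a 3-D activity array over both transverse axes.

    Axis 0 is depth (beam axis); the result is a depth profile preserving
    the array total, which maximises counting statistics before fitting.
    """
    vol = np.asarray(activity_volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("activity volume must be 3-D")
    if np.any(vol < 0):
        raise ValueError("activity must be non-negative")
    return vol.sum(axis=(1, 2))


def area_normalize(profile, bin_width: float) -> np.ndarray:
    """Scale a depth profile so that sum(value * bin_width) equals one."""
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    p = np.asarray(profile, dtype=float)
    if np.any(p < 0):
        raise ValueError("profile must be non-negative")
    total = p.sum() * bin_width
    if total <= 0:
        raise ValueError("cannot area-normalise an all-zero profile")
    return p / total


@dataclass(frozen=True)
class IsotopeFit:
    """Per-isotope initial-activity depth profiles recovered from frames.

    ``a0`` maps isotope name to the A_0 profile at acquisition start in the
    units of the fitted frames; profiles are non-negative by construction.
    """

    a0: Mapping[str, np.ndarray]
    residual_norm: np.ndarray
    converged: bool
    isotopes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "a0",
                           {k: np.asarray(v, dtype=float)
                            for k, v in self.a0.items()})
        object.__setattr__(self, "residual_norm",
                           np.asarray(self.residual_norm, dtype=float))


def fit_isotope_fractions(frames: ActivityFrames,
                          isotopes: Sequence[Union[str, IsotopeSpec]],
                          cond_limit: float = 1e8) -> IsotopeFit:
    """Decompose dynamic frames into fixed-half-life isotope contributions.

    Per depth bin, solves the non-negative linear least-squares problem
    ``min || M a - y ||, a >= 0`` where column i of M holds the
    frame-average factors of isotope i.  Half-lives are fixed and known;
    only the initial activities A_0 are free.  The basis must be well
    conditioned: indistinguishable half-lives raise
    :class:`RankDeficientBasisError` instead of returning an arbitrary
    split.
    """
    isos = [get_isotope(i) for i in isotopes]
    if len(isos) == 0:
        raise ValueError("need at least one isotope")
    half_lives = [i.half_life for i in isos]
    if len(set(half_lives)) != len(half_lives):
        raise RankDeficientBasisError("isotope half-lives must be pairwise "
                                      "distinct")
    n_frames = len(frames.frame_bounds)
    if n_frames < 2:
        raise ValueError("need at least two frames to fit")
    if n_frames < len(isos):
        raise ValueError("need at least as many frames as isotopes")

    design = np.array([[frame_average_factor(iso, t1, t2) for iso in isos]
                       for t1, t2 in frames.frame_bounds])
    cond = float(np.linalg.cond(design))
    if cond > cond_limit:
        raise RankDeficientBasisError(
            f"frame design cannot separate the isotopes "
            f"(condition number {cond:.3g})")

    n_bins = frames.values.shape[1]
    a0 = np.zeros((len(isos), n_bins))
    rnorm = np.zeros(n_bins)
    for d in range(n_bins):
        a0[:, d], rnorm[d] = nnls(design, frames.values[:, d])
    return IsotopeFit(
        a0={iso.name: a0[i] for i, iso in enumerate(isos)},
        residual_norm=rnorm,
        converged=True,
        isotopes=tuple(iso.name for iso in isos),
    )


def sum_fitted_contributions(fit: IsotopeFit,
                             timeline: IrradiationTimeline) -> np.ndarray:
    """Frame-averaged total profile implied by a fit over the acquisition.

    Sums, over isotopes, A_0 times the full-acquisition frame-average
    factor; on noiseless data this reproduces the profile of a single
    static reconstruction covering the whole acquisition.
    """
    out: np.ndarray | None = None
    for name in fit.isotopes:
        factor = frame_average_factor(name, 0.0, timeline.acquisition)
        term = fit.a0[name] * factor
        out = term if out is None else out + term
    assert out is not None
    return out


def washout_apply(a0_profile, isotope: Union[str, IsotopeSpec],
                  medium: str, rate: float):
    """Physiological washout as an extra clearance constant.

    In perfused media the measurable signal decays with the effective
    constant ``lambda + rate``; in a confined medium (the hydrogel implant)
    isotopes stay at the production spot and the physical decay is
    unchanged.  Returns ``(a0_profile, effective_isotope)``; the profile at
    t = 0 is unaffected, only the decay kinetics change.
    """
    if medium not in ("perfused", "confined"):
        raise ValueError("medium must be 'perfused' or 'confined'")
    if rate < 0:
        raise ValueError("washout rate must be >= 0")
    iso = get_isotope(isotope)
    if medium == "confined" or rate == 0.0:
        return a0_profile, iso
    effective = IsotopeSpec(f"{iso.name}+washout",
                            half_life=LN2 / (iso.lam + rate))
    return a0_profile, effective
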