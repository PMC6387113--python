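"""Power spectra, transmissivity ratios, vapor masking, absorption curves.

The measurement model: a frequency-swept THz beam crosses a microfluidic
channel array (alternating liquid channels and silicon ridges).  Three power
spectra are recorded on the same grid — blank chip P_B, buffer reference
P_R, sample P_S.  Transmissivities T = P/P_B are formed pointwise; windows
around atmospheric water-vapor lines are masked; the absorption coefficient
follows from the Lambert–Beer law with the liquid fill factor f and channel
depth d:

    α(ν) = −ln T(ν) / (f·d),      d in cm, α in cm⁻¹.

The printed relation omits the minus sign; the positive-absorption
convention is used throughout so that T < 1 gives α > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import UM_TO_CM

__all__ = [
    "PowerSpectrum",
    "TransmissivityCurve",
    "AbsorptionCurve",
    "ChipGeometry",
    "WATER_VAPOR_LINES_GHZ",
    "DEFAULT_VAPOR_HALF_WIDTH_GHZ",
    "fill_factor",
    "compute_transmissivity",
    "vapor_mask",
    "absorption_coefficient",
]

logger = logging.getLogger(__name__)

#: Atmospheric water-vapor absorption lines contaminating ratio spectra.
WATER_VAPOR_LINES_GHZ = (556.0, 752.0, 990.0)
#: Exclusion half-width: undulations within ±20 GHz of a line are disturbances.
DEFAULT_VAPOR_HALF_WIDTH_GHZ = 20.0


@dataclass(frozen=True)
class ChipGeometry:
    """Microfluidic channel-array geometry (all lengths in μm)."""

    width_um: float = 2.4
    pitch_um: float = 1.6
    depth_um: float = 2.4

    def __post_init__(self):
        if self.width_um <= 0 or self.pitch_um < 0 or self.depth_um <= 0:
            raise ValueError("chip geometry must be strictly positive "
                             "(pitch may be zero for a continuous film)")

    @property
    def fill_factor(self) -> float:
        return fill_factor(self)

    @property
    def depth_cm(self) -> float:
        return self.depth_um * UM_TO_CM


def fill_factor(geom: ChipGeometry) -> float:
    """Liquid fill factor f = width/(width+pitch), in (0, 1]."""
    return geom.width_um / (geom.width_um + geom.pitch_um)


@dataclass(frozen=True)
class PowerSpectrum:
    """A single frequency sweep: strictly increasing GHz grid, power ≥ 0.

    ``role`` labels the run: "blank" (P_B), "reference" (P_R) or
    "sample" (P_S).
    """

    frequencies_ghz: np.ndarray
    power: np.ndarray
    role: str = "sample"

    def __post_init__(self):
        f = np.asarray(self.frequencies_ghz, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.ndim != 1 or f.shape != p.shape:
            raise ValueError("frequency and power arrays must be equal-length 1-D")
        if f.size == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("power must be non-negative")
        object.__setattr__(self, "frequencies_ghz", f)
        object.__setattr__(self, "power", p)

    def __len__(self) -> int:
        return self.frequencies_ghz.size


@dataclass(frozen=True)
class TransmissivityCurve:
    """Pointwise power ratio with a validity mask (True = usable point).

    Masked points are flagged, never deleted, so curves stay on the full
    instrument grid.
    """

    frequencies_ghz: np.ndarray
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequencies_ghz, dtype=float)
        t = np.asarray(self.values, dtype=float)
        m = np.asarray(self.valid, dtype=bool)
        if not (f.shape == t.shape == m.shape):
            raise ValueError("frequencies, values and mask must share a shape")
        object.__setattr__(self, "frequencies_ghz", f)
        object.__setattr__(self, "values", t)
        object.__setattr__(self, "valid", m)

    def mask_vapor(self, lines=WATER_VAPOR_LINES_GHZ,
                   half_width: float = DEFAULT_VAPOR_HALF_WIDTH_GHZ
                   ) -> "TransmissivityCurve":
        """Return a copy with water-vapor windows additionally invalidated."""
        excluded = vapor_mask(self.frequencies_ghz, lines, half_width)
        return TransmissivityCurve(self.frequencies_ghz, self.values,
                                   self.valid & ~excluded)


@dataclass(frozen=True)
class AbsorptionCurve:
    """Absorption coefficient α (cm⁻¹) with geometry provenance and mask."""

    frequencies_ghz: np.ndarray
    alpha_invcm: np.ndarray
    valid: np.ndarray
    geometry: ChipGeometry = field(default_factory=ChipGeometry)

    def __post_init__(self):
        f = np.asarray(self.frequencies_ghz, dtype=float)
        a = np.asarray(self.alpha_invcm, dtype=float)
        m = np.asarray(self.valid, dtype=bool)
        if not (f.shape == a.shape == m.shape):
            raise ValueError("frequencies, alpha and mask must share a shape")
        if not np.all(np.isfinite(a[m])):
            raise ValueError("alpha must be finite at valid points")
        object.__setattr__(self, "frequencies_ghz", f)
        object.__setattr__(self, "alpha_invcm", a)
        object.__setattr__(self, "valid", m)


def compute_transmissivity(numerator: PowerSpectrum,
                           denominator: PowerSpectrum) -> TransmissivityCurve:
    """Pointwise ratio of two power spectra on an identical grid.

    Grids must match exactly — resampling is refused because ratio spectra
    amplify interpolation artifacts.  Points where the denominator power is
    not strictly positive are masked invalid.
    """
    fn, fd = numerator.frequencies_ghz, denominator.frequencies_ghz
    if fn.shape != fd.shape or not np.array_equal(fn, fd):
        if fn.shape != fd.shape:
            raise ValueError(
                f"frequency grids differ in length ({fn.size} vs {fd.size})")
        i = int(np.nonzero(fn != fd)[0][0])
        raise ValueError(
            f"frequency grids differ first at index {i}: "
            f"{fn[i]:.6g} GHz vs {fd[i]:.6g} GHz (no resampling is applied)")
    valid = denominator.power > 0
    values = np.full_like(numerator.power, np.nan)
    np.divide(numerator.power, denominator.power, out=values, where=valid)
    return TransmissivityCurve(fn, values, valid)


def vapor_mask(frequencies_ghz, lines=WATER_VAPOR_LINES_GHZ,
               half_width: float = DEFAULT_VAPOR_HALF_WIDTH_GHZ) -> np.ndarray:
    """Boolean mask, True where a point falls inside a vapor window.

    A point is excluded iff |ν − line| ≤ half_width for some line (closed
    interval: boundary points are excluded, erring toward exclusion).
    """
    if half_width < 0:
        raise ValueError("half_width must be ≥ 0")
    f = np.asarray(frequencies_ghz, dtype=float)
    excluded = np.zeros(f.shape, dtype=bool)
    for line in lines:
        excluded |= np.abs(f - line) <= half_width
    return excluded


def absorption_coefficient(curve: TransmissivityCurve,
                           geom: ChipGeometry) -> AbsorptionCurve:
    """Lambert–Beer absorption coefficient α = −ln T/(f·d) in cm⁻¹.

    Valid points with T ≤ 0 are masked and logged rather than raising;
    the validity mask of the transmissivity curve propagates.
    """
    f = fill_factor(geom)
    d_cm = geom.depth_cm
    valid = curve.valid.copy()
    nonpos = valid & ~(curve.values > 0)
    if np.any(nonpos):
        logger.warning("masking %d point(s) with non-positive transmissivity",
                       int(nonpos.sum()))
        valid &= ~nonpos
    alpha = np.full_like(curve.values, np.nan)
    np.negative(np.log(curve.values, out=alpha, where=valid), out=alpha,
                where=valid)
    alpha[valid] /= f * d_cm
    return AbsorptionCurve(curve.frequencies_ghz, alpha, valid, geom)
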