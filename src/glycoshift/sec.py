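"""Deterministic model of analytical size-exclusion chromatography (SEC).

Glycopeptides are separated by hydrodynamic size on a Superdex-30-class
column, collected in equal-volume fractions over a fixed elution window.
Within a column's linear separation range, elution volume is well described
as a linear function of log10(molecular mass) — the standard SEC
calibration form — with negative slope (larger species elute earlier).

The model intentionally ignores peak width, hydrophobicity and charge:
SEC separates by size, and only mass drives fraction assignment.  Average
masses (not monoisotopic) should be fed in, since hydrodynamic behaviour
tracks total mass.

The default calibration spans 1500–4000 Da over the 10–20 mL collection
window (20 fractions x 0.5 mL).  That span is resolution-matched to the
analytical task: it makes a glycan change of two monosaccharides
(>= ~324 Da) move a glycopeptide by at least two fractions anywhere in the
simulator's observable mass window, while a one-monosaccharide change does
so only sometimes.  The nominal separation span quoted for the column
(100–7000 Da) is available as :meth:`SECCalibration.column_nominal`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

__all__ = [
    "SECCalibration",
    "FractionRangeError",
    "mass_to_volume",
    "volume_to_fraction",
    "fraction_for_mass",
    "min_detectable_change",
]

logger = logging.getLogger(__name__)


class FractionRangeError(ValueError):
    """An elution volume or mass fell outside the calibrated window."""


@dataclass(frozen=True)
class SECCalibration:
    """Log-linear mass -> elution-volume calibration with fraction binning.

    The calibration is anchored so that ``mass_high`` elutes at ``v_start``
    (begin collecting) and ``mass_low`` at ``v_end`` (stop collecting);
    fractions of ``fraction_width`` mL are numbered 1..``n_fractions``
    across the window.
    """

    v_start: float = 10.0
    v_end: float = 20.0
    fraction_width: float = 0.5
    n_fractions: int = 20
    mass_low: float = 1500.0
    mass_high: float = 4000.0

    def __post_init__(self) -> None:
        if not (self.v_start < self.v_end):
            raise ValueError("v_start must be below v_end")
        if abs(self.n_fractions * self.fraction_width - (self.v_end - self.v_start)) > 1e-9:
            raise ValueError(
                "n_fractions x fraction_width must equal the collection window "
                f"({self.n_fractions} x {self.fraction_width} != {self.v_end - self.v_start})"
            )
        if not (0 < self.mass_low < self.mass_high):
            raise ValueError("need 0 < mass_low < mass_high")

    @property
    def slope(self) -> float:
        """mL per decade of mass; negative (bigger elutes earlier)."""
        return (self.v_end - self.v_start) / (
            math.log10(self.mass_low) - math.log10(self.mass_high)
        )

    @property
    def intercept(self) -> float:
        return self.v_start - self.slope * math.log10(self.mass_high)

    @classmethod
    def from_mass_range(cls, mass_low: float, mass_high: float, **kwargs) -> "SECCalibration":
        return cls(mass_low=mass_low, mass_high=mass_high, **kwargs)

    @classmethod
    def column_nominal(cls) -> "SECCalibration":
        """Calibration anchored at the column's nominal 100–7000 Da span."""
        return cls.from_mass_range(100.0, 7000.0)

    def to_dict(self) -> dict:
        return {
            "v_start": self.v_start,
            "v_end": self.v_end,
            "fraction_width": self.fraction_width,
            "n_fractions": self.n_fractions,
            "mass_low": self.mass_low,
            "mass_high": self.mass_high,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SECCalibration":
        return cls(**d)


def mass_to_volume(mass: float, calib: SECCalibration, clamp: bool = True) -> float:
    """Elution volume (mL) of a species of the given mass (Da).

    Masses outside the calibrated range clamp to the window edges (a very
    large glycopeptide elutes in the void, at the start of the window);
    pass ``clamp=False`` to get an error instead.
    """
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    if not (calib.mass_low <= mass <= calib.mass_high):
        if not clamp:
            raise FractionRangeError(
                f"mass {mass} Da outside calibrated range "
                f"[{calib.mass_low}, {calib.mass_high}]"
            )
        logger.warning(
            "mass %.1f Da outside calibrated range [%g, %g]; clamping",
            mass, calib.mass_low, calib.mass_high,
        )
        mass = min(max(mass, calib.mass_low), calib.mass_high)
    return calib.intercept + calib.slope * math.log10(mass)


def volume_to_fraction(v: float, calib: SECCalibration) -> int:
    """Fraction number (1..n) for an elution volume, half-open binning.

    Fraction k collects volumes in ``[v_start+(k-1)w, v_start+kw)``.
    Volumes outside ``[v_start, v_end)`` raise :class:`FractionRangeError`.
    """
    if not (calib.v_start <= v < calib.v_end):
        raise FractionRangeError(
            f"elution volume {v} mL outside collection window "
            f"[{calib.v_start}, {calib.v_end})"
        )
    k = int(math.floor((v - calib.v_start) / calib.fraction_width)) + 1
    return min(k, calib.n_fractions)  # guard float edge at the last bin


def fraction_for_mass(mass: float, calib: SECCalibration) -> int:
    """Fraction in which a species of the given mass is collected.

    The lower mass anchor elutes exactly at ``v_end``, the closed edge of
    the last fraction's bin in practice: it is assigned fraction n.
    """
    v = mass_to_volume(mass, calib)
    if v >= calib.v_end:
        return calib.n_fractions
    return volume_to_fraction(v, calib)


def min_detectable_change(
    calib: SECCalibration,
    base_mass: float,
    shift_threshold: int = 2,
    tol: float = 1e-6,
) -> float:
    """Smallest mass gain (Da) at ``base_mass`` that moves the elution by
    at least ``shift_threshold`` fractions under the deterministic model.

    Returns ``math.inf`` when no gain within the calibrated range achieves
    the shift (the base species already elutes too close to the void).
    """
    if not (calib.mass_low <= base_mass <= calib.mass_high):
        raise FractionRangeError(
            f"base mass {base_mass} Da outside calibrated range "
            f"[{calib.mass_low}, {calib.mass_high}]"
        )
    if shift_threshold <= 0:
        return 0.0
    base_fraction = fraction_for_mass(base_mass, calib)

    def shift(delta: float) -> int:
        return base_fraction - fraction_for_mass(base_mass + delta, calib)

    hi = calib.mass_high - base_mass
    if shift(hi) < shift_threshold:
        return math.inf
    lo = 0.0
    # binned shift is monotone non-decreasing in the mass gain: bisect
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if shift(mid) >= shift_threshold:
            hi = mid
        else:
            lo = mid
    return hi
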