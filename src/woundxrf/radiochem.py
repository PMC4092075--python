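"""Dose, amount-of-substance and radioactivity conversions.

These conversions tie the stable-lead model measurement to the plutonium
application:

* *dose from time*: the maximal equivalent dose to the wound is proportional
  to the accumulation (live) time; the default rate, 3.3 mSv/s, maps 5 s to
  16.5 mSv (the device manual's upper bound treated as the working value,
  hence "maximal").
* *concentration to amount*: a mass-fraction concentration over the measured
  volume (beam footprint x wound depth x matrix density) gives moles of
  contaminant atoms.  XRF responds to the number of atoms, which is what
  makes the technique sensitive for long-lived nuclides: atoms per Bq grow
  linearly with half-life.
* *amount to activity*: A = lambda * N with lambda = ln 2 / T_half.

Because the phantom calibration is performed with stable lead as the model
contaminant, concentrations are on the lead mass scale; mapping a lead MDL
onto a radionuclide therefore goes through the *number of atoms* (lead molar
mass in the first step), then converts that same amount of the nuclide to
activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.constants import Avogadro

__all__ = [
    "NuclideSpec",
    "MeasurementGeometry",
    "NUCLIDES",
    "JULIAN_YEAR_S",
    "dose_from_time",
    "concentration_to_amount",
    "amount_to_activity",
    "activity_to_amount",
    "mdl_to_activity",
]

#: Julian year in seconds (365.25 d), the standard year in nuclear data.
JULIAN_YEAR_S = 3.15576e7


@dataclass(frozen=True)
class NuclideSpec:
    """Element/isotope constants. ``half_life_s`` is None for stable species."""

    symbol: str
    molar_mass: float            # g/mol
    half_life_s: float | None = None

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError("molar mass must be > 0")
        if self.half_life_s is not None and self.half_life_s <= 0:
            raise ValueError("half-life must be > 0 when present")

    @property
    def decay_constant_per_s(self) -> float:
        if self.half_life_s is None:
            raise ValueError(f"{self.symbol}: stable nuclide has no decay constant")
        return math.log(2.0) / self.half_life_s


#: Built-in constants (standard physical data; source: ENSDF / IUPAC tables).
NUCLIDES: dict[str, NuclideSpec] = {
    "Pb": NuclideSpec("Pb", molar_mass=207.2, half_life_s=None),
    "Pu-239": NuclideSpec("Pu-239", molar_mass=239.0522, half_life_s=24110.0 * JULIAN_YEAR_S),
    "Pu-240": NuclideSpec("Pu-240", molar_mass=240.0538, half_life_s=6561.0 * JULIAN_YEAR_S),
    "Pu-241": NuclideSpec("Pu-241", molar_mass=241.0569, half_life_s=14.329 * JULIAN_YEAR_S),
    "Am-241": NuclideSpec("Am-241", molar_mass=241.0568, half_life_s=432.6 * JULIAN_YEAR_S),
}


@dataclass(frozen=True)
class MeasurementGeometry:
    """Geometry of the interrogated wound volume.

    Defaults: 8-mm beam footprint over a 10-mm-deep wound phantom of density
    1.06 g/cm^3 (epoxy resin, soft-tissue-like).  The uniform-depth
    convention is deliberately conservative: real contamination sits near the
    wound surface where attenuation is lower, so a calibration against the
    uniform phantom over-reads, never under-reads.
    """

    beam_diameter_mm: float = 8.0
    phantom_depth_mm: float = 10.0
    density_g_cm3: float = 1.06

    def __post_init__(self) -> None:
        if min(self.beam_diameter_mm, self.phantom_depth_mm, self.density_g_cm3) <= 0:
            raise ValueError("geometry parameters must be > 0")

    @property
    def volume_cm3(self) -> float:
        r_cm = self.beam_diameter_mm / 20.0
        return math.pi * r_cm * r_cm * (self.phantom_depth_mm / 10.0)

    @property
    def mass_g(self) -> float:
        return self.volume_cm3 * self.density_g_cm3


def dose_from_time(
    accumulation_s: float, dose_rate_mSv_per_s: float = 3.3
) -> float:
    """Maximal equivalent dose (mSv) for a given accumulation time.

    Default rate maps 5/10/15/20 s to 16.5/33.0/49.5/66.0 mSv.
    """
    if accumulation_s < 0:
        raise ValueError("accumulation time must be >= 0")
    if dose_rate_mSv_per_s <= 0:
        raise ValueError("dose rate must be > 0")
    return accumulation_s * dose_rate_mSv_per_s


def concentration_to_amount(
    c_ppm: float,
    geometry: MeasurementGeometry | None = None,
    molar_mass: float = NUCLIDES["Pb"].molar_mass,
) -> float:
    """Amount of contaminant (nmol) in the measured volume at ``c_ppm``.

    ppm is a mass fraction (ug analyte per g matrix); the measured volume is
    the beam footprint through the full phantom depth.
    """
    if c_ppm < 0:
        raise ValueError("concentration must be >= 0")
    if molar_mass <= 0:
        raise ValueError("molar mass must be > 0")
    geometry = geometry or MeasurementGeometry()
    analyte_g = c_ppm * 1e-6 * geometry.mass_g
    return analyte_g / molar_mass * 1e9


def amount_to_activity(nmol: float, nuclide: NuclideSpec) -> float:
    """Radioactivity (Bq) of ``nmol`` of a radionuclide: A = lambda * N."""
    if nmol < 0:
        raise ValueError("amount must be >= 0")
    return nuclide.decay_constant_per_s * nmol * 1e-9 * Avogadro


def activity_to_amount(activity_Bq: float, nuclide: NuclideSpec) -> float:
    """Inverse of :func:`amount_to_activity` (Bq -> nmol)."""
    if activity_Bq < 0:
        raise ValueError("activity must be >= 0")
    return activity_Bq / (nuclide.decay_constant_per_s * Avogadro) * 1e9


def mdl_to_activity(
    mdl_ppm: float,
    geometry: MeasurementGeometry | None = None,
    nuclide: NuclideSpec = NUCLIDES["Pu-239"],
    analyte_molar_mass: float = NUCLIDES["Pb"].molar_mass,
) -> float:
    """Radioactivity (Bq) equivalent of a lead-scale detection limit.

    Two-step composition: the mass-fraction MDL (on the model-contaminant
    lead scale) converts to an amount of atoms via ``analyte_molar_mass``,
    and that same amount of the target radionuclide converts to activity.
    1.2 ppm with the default geometry maps to ~3.1 nmol and ~1.7 kBq of
    Pu-239.
    """
    nmol = concentration_to_amount(mdl_ppm, geometry, analyte_molar_mass)
    return amount_to_activity(nmol, nuclide)
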