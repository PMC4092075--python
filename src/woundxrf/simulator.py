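"""Synthetic portable-XRF spectra for the bleeding-wound phantom design.

The simulator produces spectra with the statistical structure the analysis
chain assumes, so every downstream stage (intensity extraction, calibration,
thickness estimation, concentration inversion, detection limits) can be
exercised end to end without a physical device:

* a smooth exponential continuum plus narrow Gaussian device lines
  (Ni K, Mo K, Ag K) and broad Compton-scatter humps below the Mo lines --
  all scaling linearly with the delivered dose ``d`` and independent of the
  overlying blood thickness ``t`` (the device background originates upstream
  of the wound);
* analyte lines (Pb La at 10.55 keV, Pb Lb at 12.61 keV) whose
  window-integrated emission scales as ``I1 * exp(-mu * t) * d * c`` -- the
  Lambert attenuation law with one *effective* coefficient per line, lumping
  incident-beam and fluorescence-path attenuation into a single exponential;
* independent Poisson counting noise per energy bin.

The broad Mo Ka Compton hump reproduces the key background asymmetry of the
real device: the continuum under the Pb Lb window exceeds that under the
Pb La window, which is why the La line is the quantification line.

Analyte line amplitudes are normalised *within the line's integration
window*, so the window integral of the expectation equals the configured
emission rate exactly; what calibration recovers is therefore directly
comparable to the configured truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .spectra import EnergyWindow, Spectrum, default_windows

__all__ = [
    "GaussianLine",
    "AnalyteLine",
    "SimConfig",
    "PhantomMeasurement",
    "expected_spectrum",
    "simulate_spectrum",
    "simulate_design",
    "phantom_concentration",
    "STUDY_C_PPM",
    "STUDY_T_MM",
    "STUDY_D_MSV",
    "STUDY_N_REPLICATES",
]

#: The phantom study grid: 6 lead concentrations x 5 blood thicknesses x
#: 4 maximal equivalent doses, n = 4 replicates -> 120 cases, 480 spectra.
STUDY_C_PPM = (0.0, 2.0, 5.0, 10.0, 15.0, 20.0)
STUDY_T_MM = (0.0, 0.5, 1.0, 1.5, 2.0)
STUDY_D_MSV = (16.5, 33.0, 49.5, 66.0)
STUDY_N_REPLICATES = 4


@dataclass(frozen=True)
class GaussianLine:
    """A device-derived spectral feature: Gaussian with total counts per mSv."""

    label: str
    center_keV: float
    sigma_keV: float
    counts_per_mSv: float

    def __post_init__(self) -> None:
        if self.sigma_keV <= 0 or self.counts_per_mSv <= 0:
            raise ValueError(f"{self.label}: width and amplitude must be > 0")


@dataclass(frozen=True)
class AnalyteLine:
    """A contaminant emission line with Lambert-law attenuation.

    ``counts_per_mSv_per_ppm`` is the *window-integrated* net emission rate at
    zero overlayer thickness; ``mu_per_mm`` is the effective linear
    attenuation coefficient of the overlying blood at this line's energy.
    """

    label: str
    center_keV: float
    sigma_keV: float
    counts_per_mSv_per_ppm: float
    mu_per_mm: float
    window: EnergyWindow

    def __post_init__(self) -> None:
        if self.sigma_keV <= 0 or self.counts_per_mSv_per_ppm <= 0:
            raise ValueError(f"{self.label}: width and emission rate must be > 0")
        if self.mu_per_mm <= 0:
            raise ValueError(f"{self.label}: attenuation coefficient must be > 0")


def _default_device_lines() -> tuple[GaussianLine, ...]:
    return (
        GaussianLine("Ni Ka", 7.48, 0.12, 300.0),
        GaussianLine("Ni Kb", 8.26, 0.12, 60.0),
        GaussianLine("Mo Ka", 17.48, 0.12, 1500.0),
        GaussianLine("Mo Ka Compton", 16.5, 1.8, 800.0),
        GaussianLine("Mo Kb", 19.61, 0.12, 300.0),
        GaussianLine("Mo Kb Compton", 18.7, 1.8, 160.0),
        GaussianLine("Ag Ka", 22.16, 0.14, 600.0),
        GaussianLine("Ag Kb", 24.94, 0.14, 120.0),
    )


def _default_analyte_lines() -> tuple[AnalyteLine, ...]:
    w = default_windows()
    return (
        AnalyteLine("Pb La", 10.55, 0.15, 6.0, 0.45, w["PbLa"]),
        AnalyteLine("Pb Lb", 12.61, 0.15, 4.0, 0.27, w["PbLb"]),
    )


@dataclass
class SimConfig:
    """Full description of the synthetic measurement system.

    Continuum: ``amplitude * exp(-E / scale)`` counts per keV per mSv.
    Default amplitudes put the background under the Pb La window near
    60 counts/mSv, which together with the default La emission rate places
    the detection limit at (t = 0.5 mm, d = 16.5 mSv) near 1.2 ppm.
    The attenuation coefficients (0.45 and 0.27 per mm) are water-like
    effective values at 10.6 and 12.6 keV.  The dose rate, 3.3 mSv/s, maps a
    5 s accumulation to a 16.5 mSv maximal equivalent dose to the wound.
    """

    continuum_amplitude: float = 246.0  # counts / keV / mSv at E = 0
    continuum_scale_keV: float = 10.0
    device_lines: tuple[GaussianLine, ...] = field(default_factory=_default_device_lines)
    analyte_lines: tuple[AnalyteLine, ...] = field(default_factory=_default_analyte_lines)
    dose_rate_mSv_per_s: float = 3.3
    energy_min_keV: float = 0.0
    energy_max_keV: float = 40.0
    energy_step_keV: float = 0.02

    def __post_init__(self) -> None:
        if self.continuum_amplitude <= 0 or self.continuum_scale_keV <= 0:
            raise ValueError("continuum parameters must be > 0")
        if self.dose_rate_mSv_per_s <= 0:
            raise ValueError("dose rate must be > 0")
        if self.energy_step_keV <= 0 or self.energy_max_keV <= self.energy_min_keV:
            raise ValueError("invalid energy grid")
        mus = {line.label: line.mu_per_mm for line in self.analyte_lines}
        if len(self.analyte_lines) >= 2:
            la, lb = self.analyte_lines[0], self.analyte_lines[1]
            if not la.mu_per_mm > lb.mu_per_mm:
                raise ValueError(
                    f"attenuation must decrease with line energy: "
                    f"mu({la.label})={la.mu_per_mm} must exceed mu({lb.label})={lb.mu_per_mm}"
                )

    # -- grid and cached per-bin shapes ------------------------------------

    def energy_grid(self) -> np.ndarray:
        """Bin centers: [min + step/2, max) in steps of ``energy_step_keV``."""
        n = int(round((self.energy_max_keV - self.energy_min_keV) / self.energy_step_keV))
        return self.energy_min_keV + (np.arange(n) + 0.5) * self.energy_step_keV

    def _gaussian_profile(self, center: float, sigma: float, grid: np.ndarray) -> np.ndarray:
        z = (grid - center) / sigma
        return np.exp(-0.5 * z * z) / (sigma * math.sqrt(2.0 * math.pi)) * self.energy_step_keV

    def background_per_mSv(self, grid: np.ndarray | None = None) -> np.ndarray:
        """Per-bin expected background counts per mSv (continuum + device lines)."""
        if grid is None:
            grid = self.energy_grid()
        out = (
            self.continuum_amplitude
            * np.exp(-grid / self.continuum_scale_keV)
            * self.energy_step_keV
        )
        for line in self.device_lines:
            out = out + line.counts_per_mSv * self._gaussian_profile(
                line.center_keV, line.sigma_keV, grid
            )
        return out

    def analyte_profile(self, line: AnalyteLine, grid: np.ndarray | None = None) -> np.ndarray:
        """Per-bin line shape normalised to unit integral *within the line window*."""
        if grid is None:
            grid = self.energy_grid()
        prof = self._gaussian_profile(line.center_keV, line.sigma_keV, grid)
        in_window = prof[line.window.mask(grid)].sum()
        if in_window <= 0:
            raise ValueError(f"{line.label}: window does not capture the line")
        return prof / in_window

    def background_rate(self, window: EnergyWindow) -> float:
        """Background counts per mSv integrated over ``window`` (the true I0 analog)."""
        grid = self.energy_grid()
        return float(self.background_per_mSv(grid)[window.mask(grid)].sum())

    def true_params(self) -> dict[str, float]:
        """Ground-truth constants of the intensity model implied by this config.

        Keys mirror the calibration parameter set so parameter-recovery tests
        can compare fitted values against configured truth.
        """
        la, lb = self.analyte_lines[0], self.analyte_lines[1]
        return {
            "I0": self.background_rate(la.window),
            "I0_Lb": self.background_rate(lb.window),
            "I1_La": la.counts_per_mSv_per_ppm,
            "I1_Lb": lb.counts_per_mSv_per_ppm,
            "mu_La": la.mu_per_mm,
            "mu_Lb": lb.mu_per_mm,
            "R0": la.counts_per_mSv_per_ppm / lb.counts_per_mSv_per_ppm,
            "delta_mu": la.mu_per_mm - lb.mu_per_mm,
        }

    # -- (de)serialisation --------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        for i, line in enumerate(payload["analyte_lines"]):
            w = self.analyte_lines[i].window
            line["window"] = {"lo_keV": w.lo_keV, "hi_keV": w.hi_keV, "label": w.label}
        with Path(path).open("w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        with Path(path).open() as fh:
            payload = json.load(fh)
        payload["device_lines"] = tuple(
            GaussianLine(**d) for d in payload["device_lines"]
        )
        payload["analyte_lines"] = tuple(
            AnalyteLine(**{**d, "window": EnergyWindow(**d["window"])})
            for d in payload["analyte_lines"]
        )
        return cls(**payload)


@dataclass
class PhantomMeasurement:
    """A simulated (or recorded) spectrum tagged with its ground-truth condition."""

    spectrum: Spectrum
    c_ppm: float
    t_mm: float
    d_mSv: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.c_ppm < 0 or self.t_mm < 0:
            raise ValueError("concentration and thickness must be non-negative")
        if self.d_mSv <= 0:
            raise ValueError("dose must be positive")


# ---------------------------------------------------------------------------
# Forward model and sampling
# ---------------------------------------------------------------------------

def expected_spectrum(
    config: SimConfig, c_ppm: float, t_mm: float, d_mSv: float
) -> np.ndarray:
    """Per-bin expected counts for condition (c, t, d).

    The background (continuum + device lines) scales with d only; each
    analyte line contributes ``I1 * exp(-mu * t) * d * c`` counts inside its
    integration window, distributed over the line profile.
    """
    if c_ppm < 0 or t_mm < 0:
        raise ValueError("c_ppm and t_mm must be non-negative")
    if d_mSv <= 0:
        raise ValueError("d_mSv must be positive")
    grid = config.energy_grid()
    mean = config.background_per_mSv(grid) * d_mSv
    if c_ppm > 0:
        for line in config.analyte_lines:
            rate = (
                line.counts_per_mSv_per_ppm
                * math.exp(-line.mu_per_mm * t_mm)
                * d_mSv
                * c_ppm
            )
            mean = mean + rate * config.analyte_profile(line, grid)
    return mean


def simulate_spectrum(
    config: SimConfig,
    c_ppm: float,
    t_mm: float,
    d_mSv: float,
    seed: int | np.random.Generator | None = None,
) -> Spectrum:
    """Draw one spectrum: independent Poisson counts around the expectation.

    ``accumulation_time_s`` is derived from the dose and the configured dose
    rate (dose is proportional to live time).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean = expected_spectrum(config, c_ppm, t_mm, d_mSv)
    counts = rng.poisson(mean)
    return Spectrum(
        energies_keV=config.energy_grid(),
        counts=counts,
        accumulation_time_s=d_mSv / config.dose_rate_mSv_per_s,
        metadata={"c_ppm": c_ppm, "t_mm": t_mm, "d_mSv": d_mSv},
    )


def simulate_design(
    config: SimConfig,
    c_list: "list[float] | tuple" = STUDY_C_PPM,
    t_list: "list[float] | tuple" = STUDY_T_MM,
    d_list: "list[float] | tuple" = STUDY_D_MSV,
    n_replicates: int = STUDY_N_REPLICATES,
    seed: int = 0,
) -> list[PhantomMeasurement]:
    """Simulate a full factorial phantom design.

    Defaults reproduce the study grid: 6 concentrations x 5 thicknesses x
    4 doses with 4 replicates each (480 spectra over 120 cases).  Each
    measurement gets its own child seed derived from (master seed, case
    index, replicate), so enlarging ``n_replicates`` leaves earlier draws
    untouched.
    """
    if not (len(c_list) and len(t_list) and len(d_list)):
        raise ValueError("design lists must be non-empty")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    out: list[PhantomMeasurement] = []
    case = 0
    for c in c_list:
        for t in t_list:
            for d in d_list:
                for rep in range(n_replicates):
                    rng = np.random.default_rng([int(seed), case, rep])
                    spec = simulate_spectrum(config, c, t, d, rng)
                    spec.metadata["replicate"] = rep
                    out.append(PhantomMeasurement(spec, c, t, d, rep))
                case += 1
    return out


def phantom_concentration(
    solution_ppm: float, solution_parts: float = 1.0, matrix_parts: float = 99.0
) -> float:
    """Final analyte concentration after mixing a doped solution into the matrix.

    A paint solution at ``solution_ppm`` mixed at ratio solution:matrix =
    1:99 yields solution_ppm / 100 in the cured phantom (mass-fraction
    dilution): 2000 ppm stock -> 20 ppm phantom.
    """
    if solution_ppm < 0 or solution_parts <= 0 or matrix_parts < 0:
        raise ValueError("invalid mixing parameters")
    return solution_ppm * solution_parts / (solution_parts + matrix_parts)
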