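"""Energy-dispersive XRF spectra and region-of-interest intensity extraction.

A measurement is an energy-calibrated counts histogram.  Peak intensities are
obtained by integrating counts over a fixed energy window (region of interest)
rather than by peak fitting: the Pb L lines are clusters of unresolved
subcomponents (La1/La2, Lb1-Lb4) with asymmetric composite shapes, so window
integration is both simpler and more robust than a Gaussian model.

Three intensities are distinguished for each line:

* *gross*      -- window-integrated counts of the sample spectrum,
* *background* -- the same window integrated in a blank (analyte-free) spectrum
                  acquired under matching conditions,
* *net*        -- gross minus background.

Counting noise can drive the raw net difference negative at low analyte
concentration; the raw signed value is preserved in :class:`IntensityTriple`
while the reported net is clamped at zero with a flag, since a negative
intensity has no physical reading and detectability is judged by the
detection-limit machinery, not by the sign of the net.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Spectrum",
    "EnergyWindow",
    "IntensityTriple",
    "SpectrumParseError",
    "gross_intensity",
    "background_intensity",
    "net_intensity",
    "read_spectrum",
    "write_spectrum",
    "default_windows",
    "load_windows",
    "dump_windows",
    "PB_LA_KEV",
    "PB_LB_KEV",
]

#: Pb L-line centroids (keV).
PB_LA_KEV = 10.55
PB_LB_KEV = 12.61


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed into a valid Spectrum."""


@dataclass(frozen=True)
class EnergyWindow:
    """Half-open integration window [lo_keV, hi_keV) on bin centers.

    Half-open membership makes window integrals exactly additive:
    splitting [a, c) into [a, b) and [b, c) never double-counts a bin.
    """

    lo_keV: float
    hi_keV: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.lo_keV < self.hi_keV:
            raise ValueError(
                f"window bounds must satisfy lo < hi, got [{self.lo_keV}, {self.hi_keV})"
            )

    @property
    def width_keV(self) -> float:
        return self.hi_keV - self.lo_keV

    def mask(self, energies_keV: np.ndarray) -> np.ndarray:
        return (energies_keV >= self.lo_keV) & (energies_keV < self.hi_keV)


@dataclass
class Spectrum:
    """An energy-calibrated counts histogram with acquisition metadata.

    Parameters
    ----------
    energies_keV
        Strictly increasing bin centers in keV.
    counts
        Non-negative integer counts per bin, same length as ``energies_keV``.
    accumulation_time_s
        Live acquisition time in seconds (> 0).
    metadata
        Free-form string labels (phantom condition, device, operator ...).
    """

    energies_keV: np.ndarray
    counts: np.ndarray
    accumulation_time_s: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.energies_keV = np.asarray(self.energies_keV, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.energies_keV.ndim != 1:
            raise ValueError("energies_keV must be one-dimensional")
        if self.counts.shape != self.energies_keV.shape:
            raise ValueError(
                f"counts length {self.counts.shape} does not match energies "
                f"{self.energies_keV.shape}"
            )
        if self.energies_keV.size < 1:
            raise ValueError("spectrum must contain at least one bin")
        if np.any(np.diff(self.energies_keV) <= 0):
            raise ValueError("energies_keV must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        counts_int = np.asarray(self.counts, dtype=np.int64)
        if not np.array_equal(counts_int, self.counts):
            raise ValueError("counts must be integers")
        self.counts = counts_int
        if not self.accumulation_time_s > 0:
            raise ValueError(
                f"accumulation_time_s must be > 0, got {self.accumulation_time_s}"
            )

    @property
    def n_bins(self) -> int:
        return self.energies_keV.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            np.array_equal(self.energies_keV, other.energies_keV)
            and np.array_equal(self.counts, other.counts)
            and self.accumulation_time_s == other.accumulation_time_s
            and self.metadata == other.metadata
        )


@dataclass(frozen=True)
class IntensityTriple:
    """Gross, background and net window-integrated counts for one line.

    ``net`` is the reported (clamped, non-negative) value; ``net_raw`` keeps
    the signed difference so that downstream statistics are not biased by the
    clamping.  ``clamped`` flags the case where the raw difference was
    negative.
    """

    gross: int
    background: float
    net: float
    net_raw: float
    clamped: bool

    @classmethod
    def from_gross_background(cls, gross: int | float, background: float) -> "IntensityTriple":
        raw = float(gross) - float(background)
        return cls(
            gross=int(round(gross)),
            background=float(background),
            net=max(raw, 0.0),
            net_raw=raw,
            clamped=raw < 0.0,
        )


def gross_intensity(spectrum: Spectrum, window: EnergyWindow) -> int:
    """Integrated counts of ``spectrum`` in ``window`` (sum over bin centers in [lo, hi)).

    Raises
    ------
    ValueError
        If the window lies entirely outside the spectrum's energy range.
    """
    e = spectrum.energies_keV
    if window.hi_keV <= e[0] or window.lo_keV > e[-1]:
        raise ValueError(
            f"window {window.label or ''} [{window.lo_keV}, {window.hi_keV}) keV "
            f"does not overlap spectrum range [{e[0]}, {e[-1]}] keV"
        )
    return int(spectrum.counts[window.mask(e)].sum())


def background_intensity(background_spectrum: Spectrum, window: EnergyWindow) -> int:
    """Gross intensity of a blank (analyte-free) spectrum in the same window.

    The blank should be acquired at the same dose as the sample; matching the
    overlying-layer thickness is optional because the device-derived
    background is not attenuated by the layer (it originates upstream of it).
    """
    return gross_intensity(background_spectrum, window)


def net_intensity(gross: int | float, background: int | float) -> IntensityTriple:
    """Background-subtracted intensity with non-negativity clamping.

    Both inputs must be non-negative counts.
    """
    if gross < 0 or background < 0:
        raise ValueError("gross and background intensities must be non-negative")
    return IntensityTriple.from_gross_background(gross, background)


# ---------------------------------------------------------------------------
# File I/O: two-column CSV with '# key=value' header comments.
# ---------------------------------------------------------------------------

_REQUIRED_META = "accumulation_time_s"


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as CSV: comment header with metadata, then energy,counts rows."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {_REQUIRED_META}={spectrum.accumulation_time_s!r}\n")
        for key, value in spectrum.metadata.items():
            fh.write(f"# {key}={value}\n")
        fh.write("energy_keV,counts\n")
        for e, n in zip(spectrum.energies_keV, spectrum.counts):
            fh.write(f"{float(e)!r},{int(n)}\n")


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a spectrum CSV written by :func:`write_spectrum`.

    Raises :class:`SpectrumParseError` (with the offending line number) for
    malformed rows, non-monotone energies, negative counts, or a missing
    ``accumulation_time_s`` field.
    """
    path = Path(path)
    meta: dict = {}
    energies: list[float] = []
    counts: list[int] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            if line.startswith("energy"):
                continue  # column header
            parts = line.split(",")
            if len(parts) != 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                e = float(parts[0])
                n = int(parts[1])
            except ValueError as exc:
                raise SpectrumParseError(f"{path}:{lineno}: {exc}") from exc
            if n < 0:
                raise SpectrumParseError(f"{path}:{lineno}: negative count {n}")
            if energies and e <= energies[-1]:
                raise SpectrumParseError(
                    f"{path}:{lineno}: energies not strictly increasing ({e} after {energies[-1]})"
                )
            energies.append(e)
            counts.append(n)
    if _REQUIRED_META not in meta:
        raise SpectrumParseError(f"{path}: missing required header field '{_REQUIRED_META}'")
    try:
        acc = float(meta.pop(_REQUIRED_META))
    except ValueError as exc:
        raise SpectrumParseError(f"{path}: invalid {_REQUIRED_META}: {exc}") from exc
    try:
        return Spectrum(
            energies_keV=np.array(energies),
            counts=np.array(counts),
            accumulation_time_s=acc,
            metadata=meta,
        )
    except ValueError as exc:
        raise SpectrumParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Line windows
# ---------------------------------------------------------------------------

def default_windows() -> dict[str, EnergyWindow]:
    """Default integration windows for the Pb L lines.

    Roughly +/-0.35 keV around the centroids, wide enough to capture the
    unresolved subcomponent structure of each composite line while staying
    clear of the neighbouring device features.
    """
    return {
        "PbLa": EnergyWindow(10.2, 10.9, "Pb La"),
        "PbLb": EnergyWindow(12.2, 13.0, "Pb Lb"),
    }


def load_windows(path: str | Path) -> dict[str, EnergyWindow]:
    """Load line windows from JSON: {"lines": {name: {"window": [lo, hi]}}}."""
    import json

    with Path(path).open() as fh:
        cfg = json.load(fh)
    out = {}
    for name, spec in cfg["lines"].items():
        lo, hi = spec["window"]
        out[name] = EnergyWindow(float(lo), float(hi), name)
    return out


def dump_windows(windows: dict[str, EnergyWindow], path: str | Path) -> None:
    import json

    cfg = {
        "lines": {
            name: {"window": [w.lo_keV, w.hi_keV]} for name, w in windows.items()
        }
    }
    with Path(path).open("w") as fh:
        json.dump(cfg, fh, indent=2)
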