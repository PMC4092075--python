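"""Calibration of the wound-XRF intensity model from labelled phantom spectra.

The gross intensity of an analyte line over a bleeding wound follows

    I(c, t, d) = I1 * exp(-mu * t) * d * c  +  I0 * d

where ``c`` is the contaminant concentration (ppm), ``t`` the thickness of
blood over the wound (mm), ``d`` the maximal equivalent dose delivered by the
acquisition (mSv, proportional to live time), ``I1`` the net emission rate of
the line per mSv per ppm at t = 0, ``I0`` the background rate per mSv in the
line's window, and ``mu`` the effective linear attenuation coefficient of
blood at the line energy.

Three least-squares fits recover the constants from a factorial phantom
design:

1. *Dry model* (t = 0): for each dose level, regress gross intensity on
   concentration; the per-dose slopes and intercepts are then regressed on
   dose through the origin, giving I1 and I0.  Through-origin because both
   the net signal and the background are strictly proportional to live time,
   hence to dose.
2. *Attenuation*: net intensities relative to the dry case, aggregated by
   geometric mean over (c, d) cells, fitted log-linearly against thickness
   through the origin -- one Lambert-law coefficient per line.
3. *Ratio model*: the La/Lb net ratio R(t) = R0 * exp(-delta_mu * t), fitted
   as a straight line in semi-log coordinates.  The ratio is dose- and
   concentration-free, so it later yields the blood thickness from a single
   field spectrum.

A consistency diagnostic compares the directly fitted ``delta_mu`` with
``mu_La - mu_Lb`` from the per-line attenuation fits.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .spectra import EnergyWindow, default_windows, gross_intensity
from .simulator import PhantomMeasurement

__all__ = [
    "CalibrationParams",
    "CalibrationError",
    "fit_dry_model",
    "fit_attenuation",
    "fit_ratio_model",
    "build_calibration",
]


class CalibrationError(ValueError):
    """Raised when the measurement set cannot support a requested fit."""


@dataclass
class CalibrationParams:
    """Fitted constants of the intensity model, with fit diagnostics.

    Units are embedded in the JSON field names on serialisation
    (counts/mSv, counts/mSv/ppm, 1/mm).
    """

    I0: float                 # background counts per mSv, La window
    I1_La: float              # net counts per mSv per ppm at t = 0, La line
    I1_Lb: float              # same for the Lb line
    mu_La: float              # effective attenuation, La energy (1/mm)
    mu_Lb: float              # effective attenuation, Lb energy (1/mm)
    R0: float                 # La/Lb net ratio at t = 0
    delta_mu: float           # ratio decay constant (1/mm)
    I0_Lb: float = 0.0        # background counts per mSv, Lb window
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("I0", "I1_La", "I1_Lb", "R0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not (self.mu_La > 0 and self.mu_Lb > 0):
            raise ValueError("attenuation coefficients must be > 0")
        if not self.delta_mu > 0:
            raise ValueError("delta_mu must be > 0")
        if not self.mu_La > self.mu_Lb:
            warnings.warn(
                "fitted mu_La does not exceed mu_Lb; attenuation ordering is "
                "inverted relative to the physical expectation",
                stacklevel=2,
            )

    def delta_mu_consistency(self) -> dict:
        """Compare fitted delta_mu against mu_La - mu_Lb.

        Returns the discrepancy, its combined standard error (if per-fit
        standard errors are available) and a boolean verdict at 3 sigma.
        """
        diff = self.delta_mu - (self.mu_La - self.mu_Lb)
        se = math.sqrt(
            self.diagnostics.get("se_delta_mu", 0.0) ** 2
            + self.diagnostics.get("se_mu_La", 0.0) ** 2
            + self.diagnostics.get("se_mu_Lb", 0.0) ** 2
        )
        return {
            "discrepancy_per_mm": diff,
            "combined_se_per_mm": se,
            "consistent_3se": abs(diff) <= 3.0 * se if se > 0 else None,
        }

    # -- JSON round trip ----------------------------------------------------

    _JSON_KEYS = {
        "I0": "I0_counts_per_mSv",
        "I0_Lb": "I0_Lb_counts_per_mSv",
        "I1_La": "I1_La_counts_per_mSv_per_ppm",
        "I1_Lb": "I1_Lb_counts_per_mSv_per_ppm",
        "mu_La": "mu_La_per_mm",
        "mu_Lb": "mu_Lb_per_mm",
        "R0": "R0",
        "delta_mu": "delta_mu_per_mm",
    }

    def to_json(self, path: str | Path) -> None:
        payload = {jk: getattr(self, k) for k, jk in self._JSON_KEYS.items()}
        payload["diagnostics"] = self.diagnostics
        with Path(path).open("w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationParams":
        with Path(path).open() as fh:
            payload = json.load(fh)
        kwargs = {k: payload[jk] for k, jk in cls._JSON_KEYS.items()}
        kwargs["diagnostics"] = payload.get("diagnostics", {})
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Intensity bookkeeping
# ---------------------------------------------------------------------------

def _gross_by_condition(
    measurements: Iterable[PhantomMeasurement], window: EnergyWindow
) -> dict[tuple[float, float, float], list[int]]:
    out: dict[tuple[float, float, float], list[int]] = {}
    for m in measurements:
        out.setdefault((m.c_ppm, m.t_mm, m.d_mSv), []).append(
            gross_intensity(m.spectrum, window)
        )
    return out


def _background_by_dose(
    gross: dict[tuple[float, float, float], list[int]],
    t_matched: bool = False,
) -> dict:
    """Mean blank (c = 0) gross intensity per dose (pooled over thickness).

    The device background is not attenuated by the blood layer, so blanks at
    all thicknesses are interchangeable at a given dose; ``t_matched=True``
    restricts to same-thickness blanks instead.
    """
    pooled: dict = {}
    for (c, t, d), vals in gross.items():
        if c != 0.0:
            continue
        key = (t, d) if t_matched else d
        pooled.setdefault(key, []).extend(vals)
    if not pooled:
        raise CalibrationError(
            "no c = 0 (blank) measurements present: background condition missing"
        )
    return {k: float(np.mean(v)) for k, v in pooled.items()}


def _net_cell_means(
    measurements: Sequence[PhantomMeasurement],
    window: EnergyWindow,
    t_matched_background: bool = False,
) -> dict[tuple[float, float, float], float]:
    """Replicate-averaged net intensity per (c, t, d) cell (c > 0 only)."""
    gross = _gross_by_condition(measurements, window)
    bg = _background_by_dose(gross, t_matched=t_matched_background)
    out = {}
    for (c, t, d), vals in gross.items():
        if c == 0.0:
            continue
        b = bg[(t, d)] if t_matched_background else bg[d]
        out[(c, t, d)] = float(np.mean(vals)) - b
    return out


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------

def _through_origin(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of y = b*x and its standard error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise CalibrationError("degenerate through-origin fit: all x are zero")
    b = float(np.sum(x * y)) / sxx
    dof = x.size - 1
    if dof > 0:
        s2 = float(np.sum((y - b * x) ** 2)) / dof
        se = math.sqrt(s2 / sxx)
    else:
        se = 0.0
    return b, se


def fit_dry_model(
    measurements: Sequence[PhantomMeasurement],
    windows: dict[str, EnergyWindow] | None = None,
    weighted: bool = False,
) -> dict:
    """Fit I1 (per line) and I0 from dry-wound (t = 0) measurements.

    Two-stage least squares: (i) per dose level, ordinary regression of gross
    intensity on concentration gives a slope ``I1*d`` and intercept ``I0*d``;
    (ii) slopes and intercepts are regressed on dose through the origin.
    ``weighted=True`` applies inverse-variance (Poisson, variance ~ gross)
    weights at stage (i).

    Returns a dict with I1_La, I1_Lb, I0 (La window), I0_Lb, per-stage
    residual diagnostics.
    """
    windows = windows or default_windows()
    dry = [m for m in measurements if m.t_mm == 0.0]
    if not dry:
        raise CalibrationError("no t = 0 (dry) measurements available")
    c_levels = sorted({m.c_ppm for m in dry})
    d_levels = sorted({m.d_mSv for m in dry})
    if len(c_levels) < 2:
        raise CalibrationError(f"need >= 2 concentration levels, got {c_levels}")
    if 0.0 not in c_levels:
        raise CalibrationError("dry calibration requires c = 0 blanks")
    if len(d_levels) < 2:
        raise CalibrationError(f"need >= 2 dose levels, got {d_levels}")

    out: dict = {"d_levels": d_levels, "c_levels": c_levels}
    for line_key, out_slope, out_icept in (
        ("PbLa", "I1_La", "I0"),
        ("PbLb", "I1_Lb", "I0_Lb"),
    ):
        window = windows[line_key]
        gross = _gross_by_condition(dry, window)
        slopes, intercepts = [], []
        for d in d_levels:
            xs, ys, ws = [], [], []
            for c in c_levels:
                for v in gross.get((c, 0.0, d), []):
                    xs.append(c)
                    ys.append(v)
                    ws.append(1.0 / max(v, 1.0))
            x = np.asarray(xs, dtype=float)
            y = np.asarray(ys, dtype=float)
            if weighted:
                w = np.asarray(ws, dtype=float)
                W = np.diag(w)
                A = np.column_stack([x, np.ones_like(x)])
                beta = np.linalg.solve(A.T @ W @ A, A.T @ W @ y)
                slope, intercept = float(beta[0]), float(beta[1])
            else:
                res = stats.linregress(x, y)
                slope, intercept = float(res.slope), float(res.intercept)
            slopes.append(slope)
            intercepts.append(intercept)
        i1, se_i1 = _through_origin(np.asarray(d_levels), np.asarray(slopes))
        i0, se_i0 = _through_origin(np.asarray(d_levels), np.asarray(intercepts))
        if i1 <= 0 or i0 <= 0:
            raise CalibrationError(
                f"degenerate dry fit for {line_key}: I1={i1:.4g}, I0={i0:.4g} "
                "(expected both positive)"
            )
        out[out_slope] = i1
        out[out_icept] = i0
        out[f"se_{out_slope}"] = se_i1
        out[f"se_{out_icept}"] = se_i0
    return out


def fit_attenuation(
    measurements: Sequence[PhantomMeasurement],
    windows: dict[str, EnergyWindow] | None = None,
    t_matched_background: bool = False,
) -> dict:
    """Fit the effective Lambert-law coefficient of each line.

    For each line: net intensities relative to the t = 0 cell within each
    (c, d) stratum, aggregated across strata by geometric mean at each
    thickness, then a through-origin fit of log(relative intensity) on t.
    Cells whose net intensity is non-positive carry no log-scale information
    and are excluded with a warning.
    """
    windows = windows or default_windows()
    t_levels = sorted({m.t_mm for m in measurements})
    if 0.0 not in t_levels:
        raise CalibrationError("attenuation fit requires t = 0 reference measurements")
    if len(t_levels) < 2:
        raise CalibrationError(f"need >= 2 thickness levels, got {t_levels}")

    out: dict = {"t_levels": t_levels}
    for line_key, mu_key in (("PbLa", "mu_La"), ("PbLb", "mu_Lb")):
        nets = _net_cell_means(measurements, windows[line_key], t_matched_background)
        if not nets:
            raise CalibrationError("no c > 0 cells available for attenuation fit")
        # relative intensity per (c, d) stratum
        log_rel_by_t: dict[float, list[float]] = {t: [] for t in t_levels if t > 0}
        n_excluded = 0
        for (c, t, d), net in nets.items():
            if t == 0.0:
                continue
            ref = nets.get((c, 0.0, d))
            if ref is None or ref <= 0 or net <= 0:
                n_excluded += 1
                continue
            log_rel_by_t[t].append(math.log(net / ref))
        if n_excluded:
            warnings.warn(
                f"{line_key}: excluded {n_excluded} non-positive net cells from "
                "the attenuation fit",
                stacklevel=2,
            )
        ts, ys = [], []
        for t, vals in log_rel_by_t.items():
            if vals:
                ts.append(t)
                ys.append(float(np.mean(vals)))  # geometric mean in log space
        if not ts:
            raise CalibrationError(
                f"{line_key}: all cells excluded; attenuation not estimable"
            )
        slope, se = _through_origin(np.asarray(ts), np.asarray(ys))
        out[mu_key] = -slope
        out[f"se_{mu_key}"] = se
        out[f"n_excluded_{mu_key}"] = n_excluded
    return out


def fit_ratio_model(
    measurements: Sequence[PhantomMeasurement],
    windows: dict[str, EnergyWindow] | None = None,
    t_matched_background: bool = False,
) -> dict:
    """Fit the La/Lb net-ratio thickness model R(t) = R0 * exp(-delta_mu * t).

    Weighted least squares of log(net_La / net_Lb) on thickness over the
    replicate-averaged (c, t, d) cells with positive net intensity in both
    windows.  Averaging before the log keeps low-count cells from biasing the
    log-linear fit; inverse-variance weights from Poisson counting statistics
    (var[log ratio] ~ gross_La/net_La^2 + gross_Lb/net_Lb^2 per replicate)
    keep them from dominating its variance.  Cells where either averaged net
    is non-positive are excluded.
    """
    windows = windows or default_windows()
    t_levels = sorted({m.t_mm for m in measurements})
    if len(t_levels) < 2:
        raise CalibrationError(f"ratio fit needs >= 2 thickness levels, got {t_levels}")
    gross_la = _gross_by_condition(measurements, windows["PbLa"])
    gross_lb = _gross_by_condition(measurements, windows["PbLb"])
    bg_la = _background_by_dose(gross_la, t_matched=t_matched_background)
    bg_lb = _background_by_dose(gross_lb, t_matched=t_matched_background)

    ts, ys, ws = [], [], []
    n_excluded = 0
    for (c, t, d), vals_la in gross_la.items():
        if c == 0.0:
            continue
        key = (t, d) if t_matched_background else d
        ga = float(np.mean(vals_la))
        gb = float(np.mean(gross_lb[(c, t, d)]))
        na, nb = ga - bg_la[key], gb - bg_lb[key]
        if na <= 0 or nb <= 0:
            n_excluded += 1
            continue
        n_rep = len(vals_la)
        var = (ga / na**2 + gb / nb**2) / n_rep
        ts.append(t)
        ys.append(math.log(na / nb))
        ws.append(1.0 / var if var > 0 else 0.0)
    if not ts:
        raise CalibrationError("all measurements excluded; ratio model not estimable")
    if len(set(ts)) < 2:
        raise CalibrationError(
            "ratio fit needs usable measurements at >= 2 thickness levels"
        )
    t_arr, y_arr, w_arr = map(np.asarray, (ts, ys, ws))
    if not np.any(w_arr > 0):
        w_arr = np.ones_like(w_arr)
    A = np.column_stack([t_arr, np.ones_like(t_arr)])
    Aw = A * np.sqrt(w_arr)[:, None]
    yw = y_arr * np.sqrt(w_arr)
    beta, _, _, _ = np.linalg.lstsq(Aw, yw, rcond=None)
    slope, intercept = float(beta[0]), float(beta[1])
    # parameter covariance under the working weights, scaled by the
    # weighted residual variance (robust to mild weight misspecification)
    dof = t_arr.size - 2
    resid = y_arr - (slope * t_arr + intercept)
    s2 = float(np.sum(w_arr * resid**2)) / dof if dof > 0 else 1.0
    cov = s2 * np.linalg.inv(Aw.T @ Aw)
    return {
        "R0": math.exp(intercept),
        "delta_mu": -slope,
        "se_delta_mu": math.sqrt(cov[0, 0]),
        "se_log_R0": math.sqrt(cov[1, 1]),
        "n_used": len(ts),
        "n_excluded_ratio": n_excluded,
    }


def build_calibration(
    measurements: Sequence[PhantomMeasurement],
    windows: dict[str, EnergyWindow] | None = None,
    weighted: bool = False,
    t_matched_background: bool = False,
) -> CalibrationParams:
    """Run all three fits on a labelled measurement set and assemble the result.

    The measurement set must span >= 2 concentration levels including c = 0,
    >= 2 dose levels, and >= 2 thickness levels including t = 0.
    """
    windows = windows or default_windows()
    dry = fit_dry_model(measurements, windows, weighted=weighted)
    att = fit_attenuation(measurements, windows, t_matched_background)
    ratio = fit_ratio_model(measurements, windows, t_matched_background)
    diagnostics = {
        "se_I1_La": dry["se_I1_La"],
        "se_I0": dry["se_I0"],
        "se_mu_La": att["se_mu_La"],
        "se_mu_Lb": att["se_mu_Lb"],
        "se_delta_mu": ratio["se_delta_mu"],
        "ratio_n_used": ratio["n_used"],
    }
    params = CalibrationParams(
        I0=dry["I0"],
        I0_Lb=dry["I0_Lb"],
        I1_La=dry["I1_La"],
        I1_Lb=dry["I1_Lb"],
        mu_La=att["mu_La"],
        mu_Lb=att["mu_Lb"],
        R0=ratio["R0"],
        delta_mu=ratio["delta_mu"],
        diagnostics=diagnostics,
    )
    params.diagnostics["delta_mu_consistency"] = params.delta_mu_consistency()
    return params
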