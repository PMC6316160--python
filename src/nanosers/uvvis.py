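"""UV-Vis quantification of gold colloids.

The localized surface plasmon resonance (LSPR) of ~20 nm gold spheres
appears as an absorbance band near 526 nm.  Its height scales linearly
through the origin with the gold concentration (Beer-Lambert), which
turns a dilution series into a calibration line and any later spectrum
into a concentration estimate.  Colloid ageing is monitored through the
concentration-normalized LSPR height, and aggregation — which red-shifts
the band and grows a long-wavelength shoulder — through a simple
absorbance ratio.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import UVVisSpectrum

__all__ = [
    "UVVisSpectrum",
    "LSPRPeak",
    "BeerLambertFit",
    "StabilitySeries",
    "DegenerateStandardsError",
    "NonPositiveSlopeError",
    "CoverageError",
    "find_lspr_peak",
    "fit_beer_lambert",
    "estimate_concentration",
    "stability_series",
    "aggregation_index",
    "read_uvvis",
    "write_uvvis",
]


class DegenerateStandardsError(ValueError):
    """Raised when a calibration series carries no concentration variation."""


class NonPositiveSlopeError(ValueError):
    """Raised when inverting a calibration with a non-positive slope."""


class CoverageError(ValueError):
    """Raised when a spectrum does not cover a required wavelength."""


@dataclass(frozen=True)
class LSPRPeak:
    wavelength_nm: float
    absorbance: float
    on_window_edge: bool   # peak may be truncated by the search window


@dataclass(frozen=True)
class BeerLambertFit:
    """Least-squares line through the origin: A = slope x c."""

    slope: float           # AU per (mol/L)
    r_squared: float
    n_points: int


def find_lspr_peak(
    spectrum: UVVisSpectrum, search_window: tuple[float, float] = (400.0, 700.0)
) -> LSPRPeak:
    """Locate the LSPR maximum inside the window.

    The discrete maximum is refined by a 3-point parabola through the
    neighbouring samples, recovering sub-sample peak positions.  When the
    maximum sits on the window edge the peak may extend beyond it; the
    result is flagged rather than rejected.
    """
    lo, hi = search_window
    wl, a = spectrum.wavelength_nm, spectrum.absorbance
    if lo < wl[0] or hi > wl[-1]:
        raise CoverageError(
            f"window [{lo:g}, {hi:g}] nm outside axis [{wl[0]:g}, {wl[-1]:g}] nm"
        )
    sel = (wl >= lo) & (wl <= hi)
    idx = np.flatnonzero(sel)
    k = idx[int(np.argmax(a[idx]))]
    on_edge = k == idx[0] or k == idx[-1]
    lam, amax = float(wl[k]), float(a[k])
    if 0 < k < wl.size - 1 and not on_edge:
        y0, y1, y2 = a[k - 1], a[k], a[k + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            lam = float(wl[k] + delta * (wl[k + 1] - wl[k]))
            amax = float(y1 - 0.25 * (y0 - y2) * delta)
    return LSPRPeak(lam, amax, on_edge)


def fit_beer_lambert(
    concentrations: Sequence[float], peak_absorbances: Sequence[float]
) -> BeerLambertFit:
    """Fit A = slope x c by least squares constrained through the origin.

    R^2 is computed against the through-origin model (uncentered total sum
    of squares), matching the constraint.
    """
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(peak_absorbances, dtype=float)
    if c.size != a.size or c.size < 2:
        raise ValueError("need at least 2 matched (concentration, absorbance) points")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    if np.unique(c).size < 2:
        raise DegenerateStandardsError(
            "calibration requires at least two distinct concentrations"
        )
    slope = float((c * a).sum() / (c * c).sum())
    resid = a - slope * c
    ss_tot = float((a * a).sum())
    r2 = 1.0 - float((resid * resid).sum()) / ss_tot if ss_tot > 0 else 1.0
    return BeerLambertFit(slope=slope, r_squared=max(0.0, min(1.0, r2)), n_points=c.size)


def estimate_concentration(a_max: float, fit: BeerLambertFit) -> float:
    """Invert the calibration: c = A_max / slope (mol/L)."""
    if not fit.slope > 0:
        raise NonPositiveSlopeError(f"calibration slope must be > 0, got {fit.slope}")
    return a_max / fit.slope


@dataclass(frozen=True)
class StabilitySeries:
    times_days: np.ndarray
    normalized_absorbance: np.ndarray   # LSPR height / concentration
    stable: bool
    max_relative_drop: float


def stability_series(
    spectra: Sequence[UVVisSpectrum],
    reference_concentration: float,
    search_window: tuple[float, float] = (400.0, 700.0),
    drop_threshold: float = 0.10,
) -> StabilitySeries:
    """Ageing series of concentration-normalized LSPR heights.

    The colloid is called stable when the relative drop from the first
    point never exceeds ``drop_threshold`` (default 10%).
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    if not reference_concentration > 0:
        raise ValueError("reference concentration must be > 0")
    times, heights = [], []
    for s in spectra:
        times.append(0.0 if s.age_days is None else float(s.age_days))
        heights.append(find_lspr_peak(s, search_window).absorbance)
    order = np.argsort(times)
    t = np.asarray(times)[order]
    h = np.asarray(heights)[order] / reference_concentration
    drops = (h[0] - h) / h[0] if h[0] > 0 else np.zeros_like(h)
    max_drop = float(drops.max()) if drops.size else 0.0
    return StabilitySeries(t, h, stable=max_drop <= drop_threshold, max_relative_drop=max_drop)


def aggregation_index(
    spectrum: UVVisSpectrum,
    shoulder_wavelength: float = 650.0,
    search_window: tuple[float, float] = (400.0, 700.0),
) -> float:
    """A(650 nm) / A(lambda_LSPR): ~0 for a monomeric colloid, growing as an
    aggregate shoulder develops at long wavelengths."""
    wl = spectrum.wavelength_nm
    if shoulder_wavelength < wl[0] or shoulder_wavelength > wl[-1]:
        raise CoverageError(
            f"spectrum does not cover {shoulder_wavelength:g} nm"
        )
    peak = find_lspr_peak(spectrum, search_window)
    if peak.absorbance <= 0:
        raise CoverageError("LSPR peak absorbance is not positive")
    a_shoulder = float(np.interp(shoulder_wavelength, wl, spectrum.absorbance))
    return a_shoulder / peak.absorbance


def write_uvvis(spectrum: UVVisSpectrum, path: str | Path) -> None:
    df = pd.DataFrame(
        {"wavelength_nm": spectrum.wavelength_nm, "absorbance": spectrum.absorbance}
    )
    df.to_csv(path, index=False)


def read_uvvis(path: str | Path, age_days: float | None = None) -> UVVisSpectrum:
    df = pd.read_csv(path, comment="#")
    return UVVisSpectrum(
        df["wavelength_nm"].to_numpy(), df["absorbance"].to_numpy(), age_days=age_days
    )
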