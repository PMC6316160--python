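"""Point-spectrum and hyperspectral Raman map processing.

The central quantity is the single-cell uptake statistic I1078: the
baseline-corrected, exposure-normalized intensity of the 1078 cm^-1
C-C anti-symmetric stretching band of gold-bound thiophenol, measured
on the *sum-spectrum* of all pixels inside the cell body.  Because each
bound reporter molecule contributes the same band, I1078 is proportional
to the number of internalized nanoparticles as long as acquisition
parameters are held constant.

Containers
----------
``Spectrum``           one wavenumber-indexed trace with exposure metadata
``HyperspectralMap``   an (ny, nx) grid of spectra sharing one axis
``CellMask``           boolean cell-body mask on the same grid

File formats are plain text: spectra as two-column CSV, maps as
long-format TSV (x_um, y_um, wavenumber_cm1, intensity) with
``# exposure_s:`` / ``# step_um:`` header lines, masks as 0/1 CSV grids.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "HyperspectralMap",
    "CellMask",
    "UptakeResult",
    "GroupStats",
    "UptakeSummary",
    "BandShift",
    "MapFormatError",
    "SpectralAxisError",
    "MaskError",
    "WindowError",
    "MissingReferenceGroupError",
    "read_spectrum",
    "write_spectrum",
    "read_map",
    "write_map",
    "read_mask",
    "write_mask",
    "band_intensity",
    "reconstruct_image",
    "sum_spectrum",
    "compute_i1078",
    "summarize_uptake",
    "band_shift_table",
    "average_point_spectra",
]

DEFAULT_BAND_CENTER = 1078.0  # cm^-1, C-C anti-symmetric stretching of bound TP
DEFAULT_HALF_WINDOW = 20.0    # cm^-1


class MapFormatError(ValueError):
    """Raised when a map file is ragged, incomplete or missing metadata."""


class SpectralAxisError(ValueError):
    """Raised for invalid or mismatched wavenumber axes."""


class MaskError(ValueError):
    """Raised for masks that do not match the grid or select no pixel."""


class WindowError(ValueError):
    """Raised when a band window falls outside the spectral axis."""


class MissingReferenceGroupError(ValueError):
    """Raised when a cell-line contrast lacks its reference group."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Spectrum:
    """A wavenumber-indexed intensity trace.

    Parameters
    ----------
    wavenumber : array, cm^-1, strictly increasing
    intensity : array, detector counts, same length
    exposure_s : acquisition exposure time in seconds (> 0)
    """

    wavenumber: np.ndarray
    intensity: np.ndarray
    exposure_s: float = 3.0

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumber, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if wn.ndim != 1 or y.shape != wn.shape:
            raise SpectralAxisError(
                f"axis and intensity must be 1-D and equal length, got {wn.shape} vs {y.shape}"
            )
        if wn.size >= 2 and not np.all(np.diff(wn) > 0):
            raise SpectralAxisError("wavenumber axis must be strictly increasing")
        if not self.exposure_s > 0:
            raise SpectralAxisError(f"exposure must be > 0 s, got {self.exposure_s}")
        object.__setattr__(self, "wavenumber", wn)
        object.__setattr__(self, "intensity", y)

    def __len__(self) -> int:
        return self.wavenumber.size


@dataclass
class HyperspectralMap:
    """A complete (ny, nx) grid of spectra sharing one axis and exposure.

    ``intensity`` has shape (ny, nx, k) with k the axis length; ``step_um``
    is the stage step between neighbouring pixels.
    """

    wavenumber: np.ndarray
    intensity: np.ndarray
    step_um: float = 2.0
    exposure_s: float = 3.0

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumber.ndim != 1 or not np.all(np.diff(self.wavenumber) > 0):
            raise SpectralAxisError("map axis must be 1-D and strictly increasing")
        if self.intensity.ndim != 3 or self.intensity.shape[2] != self.wavenumber.size:
            raise SpectralAxisError(
                f"intensity must have shape (ny, nx, {self.wavenumber.size})"
            )
        if not self.step_um > 0:
            raise ValueError(f"step must be > 0 um, got {self.step_um}")
        if not self.exposure_s > 0:
            raise ValueError(f"exposure must be > 0 s, got {self.exposure_s}")

    @property
    def ny(self) -> int:
        return self.intensity.shape[0]

    @property
    def nx(self) -> int:
        return self.intensity.shape[1]

    def spectrum_at(self, ix: int, iy: int) -> Spectrum:
        """Spectrum of the pixel at grid column ix, row iy."""
        return Spectrum(self.wavenumber, self.intensity[iy, ix], self.exposure_s)


@dataclass
class CellMask:
    """Boolean cell-body mask on the map grid."""

    grid: np.ndarray
    provenance: str = "user-supplied"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise MaskError("mask grid must be 2-D")

    @classmethod
    def full(cls, ny: int, nx: int) -> "CellMask":
        """Mask selecting every pixel (used when no cell outline is supplied)."""
        return cls(np.ones((ny, nx), dtype=bool), provenance="full-map")

    @property
    def n_pixels(self) -> int:
        return int(self.grid.sum())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a two-column CSV (wavenumber_cm1, intensity) with an exposure header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# exposure_s: {spectrum.exposure_s:g}\n")
        fh.write("wavenumber_cm1,intensity\n")
        for w, y in zip(spectrum.wavenumber, spectrum.intensity):
            fh.write(f"{w:.6g},{y:.8g}\n")


def read_spectrum(path: str | Path) -> Spectrum:
    path = Path(path)
    exposure = _parse_header(path).get("exposure_s")
    if exposure is None:
        raise MapFormatError(f"{path}: missing '# exposure_s:' header")
    df = pd.read_csv(path, comment="#")
    return Spectrum(df["wavenumber_cm1"].to_numpy(), df["intensity"].to_numpy(), exposure)


def _parse_header(path: Path) -> dict[str, float]:
    meta: dict[str, float] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                try:
                    meta[key.strip()] = float(val)
                except ValueError:
                    pass
    return meta


def write_map(hmap: HyperspectralMap, path: str | Path) -> None:
    """Write a map as long-format TSV with x_um, y_um, wavenumber_cm1, intensity."""
    path = Path(path)
    ny, nx, k = hmap.intensity.shape
    xs = np.arange(nx) * hmap.step_um
    ys = np.arange(ny) * hmap.step_um
    with path.open("w") as fh:
        fh.write(f"# exposure_s: {hmap.exposure_s:g}\n")
        fh.write(f"# step_um: {hmap.step_um:g}\n")
        fh.write("x_um\ty_um\twavenumber_cm1\tintensity\n")
        for iy in range(ny):
            for ix in range(nx):
                col = hmap.intensity[iy, ix]
                for w, v in zip(hmap.wavenumber, col):
                    fh.write(f"{xs[ix]:.6g}\t{ys[iy]:.6g}\t{w:.6g}\t{v:.8g}\n")


def read_map(path: str | Path) -> HyperspectralMap:
    """Read a long-format TSV map, validating grid completeness and the axis."""
    path = Path(path)
    meta = _parse_header(path)
    if "exposure_s" not in meta:
        raise MapFormatError(f"{path}: missing '# exposure_s:' header")
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"x_um", "y_um", "wavenumber_cm1", "intensity"}
    if not required.issubset(df.columns):
        raise MapFormatError(f"{path}: expected columns {sorted(required)}")
    xs = np.unique(df["x_um"].to_numpy())
    ys = np.unique(df["y_um"].to_numpy())
    wn = np.unique(df["wavenumber_cm1"].to_numpy())
    if wn.size >= 2 and not np.all(np.diff(wn) > 0):  # np.unique sorts; guard NaN
        raise SpectralAxisError(f"{path}: wavenumber axis is not strictly increasing")
    cube = np.full((ys.size, xs.size, wn.size), np.nan)
    ixi = np.searchsorted(xs, df["x_um"].to_numpy())
    iyi = np.searchsorted(ys, df["y_um"].to_numpy())
    iwi = np.searchsorted(wn, df["wavenumber_cm1"].to_numpy())
    cube[iyi, ixi, iwi] = df["intensity"].to_numpy()
    missing = np.isnan(cube)
    if missing.any():
        iy, ix, iw = np.argwhere(missing)[0]
        raise MapFormatError(
            f"{path}: incomplete grid — missing value at x={xs[ix]:g} um, "
            f"y={ys[iy]:g} um, wavenumber={wn[iw]:g} cm^-1"
        )
    step = meta.get("step_um", float(np.diff(xs).mean()) if xs.size > 1 else 2.0)
    return HyperspectralMap(wn, cube, step_um=step, exposure_s=meta["exposure_s"])


def write_mask(mask: CellMask, path: str | Path) -> None:
    np.savetxt(path, mask.grid.astype(int), fmt="%d", delimiter=",")


def read_mask(path: str | Path) -> CellMask:
    grid = np.loadtxt(path, delimiter=",", dtype=int, ndmin=2)
    return CellMask(grid.astype(bool), provenance="user-supplied")


# ---------------------------------------------------------------------------
# band extraction
# ---------------------------------------------------------------------------

def _window_slice(axis: np.ndarray, center: float, half_window: float) -> slice:
    lo, hi = center - half_window, center + half_window
    if lo < axis[0] or hi > axis[-1]:
        raise WindowError(
            f"band window [{lo:g}, {hi:g}] cm^-1 falls outside axis "
            f"[{axis[0]:g}, {axis[-1]:g}] cm^-1"
        )
    i0 = int(np.searchsorted(axis, lo, side="left"))
    i1 = int(np.searchsorted(axis, hi, side="right"))
    if i1 - i0 < 3:
        raise WindowError("band window must contain at least 3 samples")
    return slice(i0, i1)


def _corrected_window(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Subtract the linear baseline through the window's endpoint samples.

    Works on the last axis so the same code serves single spectra and
    whole-map stacks.
    """
    y0 = y[..., :1]
    y1 = y[..., -1:]
    frac = (x - x[0]) / (x[-1] - x[0])
    return y - (y0 + (y1 - y0) * frac)


def band_intensity(
    spectrum: Spectrum,
    center: float = DEFAULT_BAND_CENTER,
    half_window: float = DEFAULT_HALF_WINDOW,
    mode: str = "height",
) -> float:
    """Baseline-corrected band intensity in counts per second.

    A straight baseline through the two window endpoints is subtracted;
    ``mode='height'`` returns the maximum corrected value, ``mode='area'``
    the trapezoidal integral (counts.cm^-1).  The result is divided by the
    exposure time, making intensities comparable across acquisitions.
    """
    if mode not in ("height", "area"):
        raise ValueError(f"mode must be 'height' or 'area', got {mode!r}")
    sl = _window_slice(spectrum.wavenumber, center, half_window)
    x = spectrum.wavenumber[sl]
    corr = _corrected_window(spectrum.intensity[sl], x)
    if mode == "height":
        value = float(corr.max())
    else:
        value = float(np.trapezoid(corr, x))
    return value / spectrum.exposure_s


def reconstruct_image(
    hmap: HyperspectralMap,
    center: float = DEFAULT_BAND_CENTER,
    half_window: float = DEFAULT_HALF_WINDOW,
    mode: str = "height",
) -> np.ndarray:
    """Per-pixel band intensity image, shape (ny, nx), counts/s.

    This is the colour-map reconstruction used for uptake imaging: each
    pixel shows the local 1078 cm^-1 band strength.
    """
    if mode not in ("height", "area"):
        raise ValueError(f"mode must be 'height' or 'area', got {mode!r}")
    sl = _window_slice(hmap.wavenumber, center, half_window)
    x = hmap.wavenumber[sl]
    corr = _corrected_window(hmap.intensity[..., sl], x)
    if mode == "height":
        img = corr.max(axis=-1)
    else:
        img = np.trapezoid(corr, x, axis=-1)
    return img / hmap.exposure_s


def sum_spectrum(hmap: HyperspectralMap, mask: CellMask) -> Spectrum:
    """Pointwise sum of the spectra of all mask pixels (the cell sum-spectrum)."""
    if mask.grid.shape != (hmap.ny, hmap.nx):
        raise MaskError(
            f"mask shape {mask.grid.shape} does not match grid ({hmap.ny}, {hmap.nx})"
        )
    if not mask.grid.any():
        raise MaskError("mask selects no pixel")
    total = hmap.intensity[mask.grid].sum(axis=0)
    return Spectrum(hmap.wavenumber, total, hmap.exposure_s)


# ---------------------------------------------------------------------------
# uptake statistic
# ---------------------------------------------------------------------------

@dataclass
class UptakeResult:
    """Per-cell I1078 value (counts/s)."""

    cell_id: str
    cell_line: str
    time_h: float
    i1078: float
    clipped: bool = False  # True when the raw corrected value was negative


def compute_i1078(
    hmap: HyperspectralMap,
    mask: CellMask | None = None,
    cell_id: str = "",
    cell_line: str = "",
    time_h: float = float("nan"),
    center: float = DEFAULT_BAND_CENTER,
    half_window: float = DEFAULT_HALF_WINDOW,
    mode: str = "height",
) -> UptakeResult:
    """I1078 of one cell: band intensity of the masked sum-spectrum.

    Negative baseline-corrected values (possible on blank maps) are floored
    at zero and flagged, keeping the statistic a valid abundance proxy.
    """
    if mask is None:
        mask = CellMask.full(hmap.ny, hmap.nx)
    spec = sum_spectrum(hmap, mask)
    raw = band_intensity(spec, center=center, half_window=half_window, mode=mode)
    clipped = raw < 0
    return UptakeResult(cell_id, cell_line, float(time_h), max(raw, 0.0), clipped)


@dataclass
class GroupStats:
    mean: float
    sd: float
    sem: float
    n_cells: int


@dataclass
class UptakeSummary:
    """Per (cell line, time) statistics and tumor-vs-normal contrasts.

    ``percent_excess[t]`` is (mean_A - mean_B) / mean_B x 100 for the
    contrast lines at matched incubation time t.
    """

    groups: dict[tuple[str, float], GroupStats]
    percent_excess: dict[float, float]
    contrast: tuple[str, str] = ("PC3", "PNT2")


def summarize_uptake(
    results: Iterable[UptakeResult],
    contrast: tuple[str, str] = ("PC3", "PNT2"),
) -> UptakeSummary:
    """Group I1078 values by (line, time) and compute the percent-excess contrast."""
    results = list(results)
    if not results:
        raise ValueError("no uptake results supplied")
    grouped: dict[tuple[str, float], list[float]] = {}
    for r in results:
        grouped.setdefault((r.cell_line, r.time_h), []).append(r.i1078)
    groups = {}
    for key, vals in grouped.items():
        arr = np.asarray(vals, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        groups[key] = GroupStats(float(arr.mean()), sd, sd / math.sqrt(arr.size), arr.size)
    line_a, line_b = contrast
    excess: dict[float, float] = {}
    for (line, t) in list(groups):
        if line != line_a:
            continue
        ref = groups.get((line_b, t))
        if ref is None:
            raise MissingReferenceGroupError(
                f"no {line_b} group at t={t:g} h to contrast {line_a} against"
            )
        if not ref.mean > 0:
            raise MissingReferenceGroupError(
                f"{line_b} mean at t={t:g} h is not positive; contrast undefined"
            )
        excess[t] = (groups[(line_a, t)].mean - ref.mean) / ref.mean * 100.0
    return UptakeSummary(groups=groups, percent_excess=excess, contrast=contrast)


# ---------------------------------------------------------------------------
# band-shift table and spectrum averaging
# ---------------------------------------------------------------------------

@dataclass
class BandShift:
    label: str
    raman_nominal: float | None
    sers_nominal: float | None
    raman_detected: float | None
    sers_detected: float | None
    shift: float | None          # SERS - Raman, cm^-1
    sers_absent: bool


def _detect_peak(
    spectrum: Spectrum,
    lo: float,
    hi: float,
    noise_factor: float,
    floor: float,
) -> float | None:
    """Detected peak position in [lo, hi], or None when no credible peak.

    A peak is credible when its baseline-corrected height exceeds both
    ``noise_factor`` times the robust local noise (1.4826 x MAD) and an
    absolute ``floor``; the floor guards against far tails of neighbouring
    bands registering as peaks in noise-free traces.
    """
    center = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    sl = _window_slice(spectrum.wavenumber, center, half)
    x = spectrum.wavenumber[sl]
    corr = _corrected_window(spectrum.intensity[sl], x)
    noise = 1.4826 * float(np.median(np.abs(corr - np.median(corr))))
    imax = int(np.argmax(corr))
    height = float(corr[imax])
    if height < max(noise_factor * noise, floor):
        return None
    if 0 < imax < corr.size - 1:  # 3-point parabolic refinement
        y0, y1, y2 = corr[imax - 1], corr[imax], corr[imax + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            return float(x[imax] + delta * (x[imax + 1] - x[imax]))
    return float(x[imax])


def band_shift_table(
    raman_spectrum: Spectrum,
    sers_spectrum: Spectrum,
    band_table,
    window: float = 15.0,
    noise_factor: float = 3.0,
    rel_floor: float = 0.05,
) -> list[BandShift]:
    """Detect each reference band in both traces and report SERS - Raman shifts.

    The Raman side is searched within +/-window of the nominal Raman
    position; the SERS side within a window spanning both nominal positions
    (so an unshifted band is still found).  Bands whose SERS counterpart is
    never detected — notably the 920 cm^-1 S-H bend, which vanishes upon
    chemisorption — are reported absent rather than erroring.
    """
    def strongest(spec: Spectrum) -> float:
        best = 0.0
        for band in band_table.entries:
            pos = band.raman_cm1 if band.raman_cm1 is not None else band.sers_cm1
            try:
                sl = _window_slice(spec.wavenumber, pos, window)
            except WindowError:
                continue
            x = spec.wavenumber[sl]
            best = max(best, float(_corrected_window(spec.intensity[sl], x).max()))
        return best

    floor_r = rel_floor * strongest(raman_spectrum)
    floor_s = rel_floor * strongest(sers_spectrum)
    rows: list[BandShift] = []
    for band in band_table.entries:
        r_nom, s_nom = band.raman_cm1, band.sers_cm1
        r_det = None
        if r_nom is not None:
            r_det = _detect_peak(
                raman_spectrum, r_nom - window, r_nom + window, noise_factor, floor_r
            )
        anchor = [p for p in (r_nom, s_nom) if p is not None]
        s_det = _detect_peak(
            sers_spectrum, min(anchor) - window, max(anchor) + window,
            noise_factor, floor_s,
        )
        shift = None
        if r_det is not None and s_det is not None:
            shift = s_det - r_det
        rows.append(
            BandShift(
                label=band.label,
                raman_nominal=r_nom,
                sers_nominal=s_nom,
                raman_detected=r_det,
                sers_detected=s_det,
                shift=shift,
                sers_absent=s_det is None,
            )
        )
    return rows


def average_point_spectra(spectra: Sequence[Spectrum]) -> tuple[Spectrum, Spectrum]:
    """Pointwise mean and sample standard deviation of replicate point spectra."""
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra to average")
    axis = spectra[0].wavenumber
    for s in spectra[1:]:
        if s.wavenumber.shape != axis.shape or not np.allclose(s.wavenumber, axis):
            raise SpectralAxisError("replicate spectra must share one wavenumber axis")
    stack = np.stack([s.intensity for s in spectra])
    mean = Spectrum(axis, stack.mean(axis=0), spectra[0].exposure_s)
    sd = Spectrum(axis, stack.std(axis=0, ddof=1), spectra[0].exposure_s)
    return mean, sd
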