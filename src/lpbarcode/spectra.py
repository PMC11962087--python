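"""Barcode extraction from emission spectra.

Laser particles emit sub-nanometer lines; a spectrometer returns, per flow
event or per image pixel, an intensity trace on an ascending photon-energy
grid (meV).  Extraction is: detect candidate peaks (prominence against a
robust noise estimate), refine each line center with a local Gaussian fit,
and — in imaging mode — merge spatially adjacent pixel peaks of similar
energy into one emission line per LP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .simulator import Barcode

__all__ = [
    "Spectrum",
    "PeakFit",
    "PixelPeak",
    "LPCluster",
    "ExtractionParams",
    "detect_peaks",
    "refine_peak",
    "barcode_from_event",
    "cluster_pixel_peaks",
    "convert_units",
    "nm_to_mev",
    "mev_to_nm",
]

# hc in eV*nm; E(meV) = 1e3 * HC_EV_NM / lambda(nm)
HC_EV_NM = 1239.84198

# MAD -> sigma for Gaussian noise; the prominence gate is expressed in
# robust-sigma units so that a factor of 8 sits far above noise maxima.
_MAD_TO_SIGMA = 1.4826


@dataclass
class Spectrum:
    """One emission spectrum on a strictly ascending energy grid (meV)."""

    energy: np.ndarray
    intensity: np.ndarray
    origin: object = None  # event id (flow) or (x, y) pixel coordinate

    def __post_init__(self) -> None:
        self.energy = np.asarray(self.energy, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.energy.ndim != 1 or self.energy.shape != self.intensity.shape:
            raise ValueError("energy and intensity must be equal-length 1-D")
        if np.any(np.diff(self.energy) <= 0):
            raise ValueError("energy grid must be strictly ascending")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    @property
    def step(self) -> float:
        return float(np.median(np.diff(self.energy)))


@dataclass
class PeakFit:
    """A refined emission line: Gaussian center/width/amplitude and fit RMSE."""

    center: float
    width: float
    amplitude: float
    fit_rmse: float
    method: str = "gaussian"  # "parabolic" marks the fallback path


@dataclass(frozen=True)
class PixelPeak:
    """A peak observed at one image pixel (0-based integer coordinates)."""

    x: int
    y: int
    center: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("pixel coordinates must be non-negative")


@dataclass
class LPCluster:
    """A group of pixel peaks attributed to one LP; energy is their mean."""

    energy: float
    members: tuple[int, ...]

    @property
    def n_pixels(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ExtractionParams:
    """Extraction thresholds (all exposed; defaults are engineering choices)."""

    min_prominence_mads: float = 8.0
    min_separation: float = 1.0  # meV
    fit_window: int = 5  # grid points each side


# ---------------------------------------------------------------------------
# Peak detection and refinement
# ---------------------------------------------------------------------------


def detect_peaks(spec: Spectrum, min_prominence_mads: float = 8.0,
                 min_separation: float = 1.0) -> np.ndarray:
    """Indices of local maxima that clear the robust prominence gate.

    The gate is ``min_prominence_mads`` times the robust noise scale
    (``1.4826 * MAD`` of the intensity trace); detections must additionally
    be separated by at least ``min_separation`` meV.  Deterministic; a flat
    spectrum yields an empty result.
    """
    if spec.energy.size < 8:
        raise ValueError("need at least 8 grid points")
    intensity = spec.intensity
    mad = float(np.median(np.abs(intensity - np.median(intensity))))
    threshold = min_prominence_mads * _MAD_TO_SIGMA * mad
    distance = max(1, int(math.ceil(min_separation / spec.step)))
    peaks, _ = signal.find_peaks(intensity, prominence=threshold,
                                 distance=distance)
    return peaks


def _parabolic_vertex(spec: Spectrum, idx: int) -> PeakFit:
    i = spec.intensity
    e = spec.energy
    n = e.size
    if idx == 0 or idx == n - 1:
        return PeakFit(center=float(e[idx]), width=spec.step,
                       amplitude=float(i[idx]), fit_rmse=float("nan"),
                       method="parabolic")
    denom = i[idx - 1] - 2.0 * i[idx] + i[idx + 1]
    shift = 0.0 if denom == 0 else 0.5 * (i[idx - 1] - i[idx + 1]) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    return PeakFit(center=float(e[idx] + shift * spec.step), width=spec.step,
                   amplitude=float(i[idx]), fit_rmse=float("nan"),
                   method="parabolic")


def refine_peak(spec: Spectrum, peak_index: int, fit_window: int = 5) -> PeakFit:
    """Refine a detected peak with a local Gaussian-plus-constant fit.

    Fits ``A exp(-(E-c)^2 / (2 w^2)) + b`` on ``+/- fit_window`` grid points
    around the peak, yielding a sub-grid-resolution center.  When the window
    is clipped by the grid edge or the fit is singular, the parabolic vertex
    through the three points around the maximum is used instead and flagged
    via ``method="parabolic"``.
    """
    n = spec.energy.size
    if not 0 <= peak_index < n:
        raise ValueError("peak index outside grid")
    lo, hi = peak_index - fit_window, peak_index + fit_window + 1
    if lo < 0 or hi > n:
        return _parabolic_vertex(spec, peak_index)
    e = spec.energy[lo:hi]
    y = spec.intensity[lo:hi]

    def model(x, amp, center, width, base):
        return amp * np.exp(-0.5 * ((x - center) / width) ** 2) + base

    base0 = float(y.min())
    amp0 = float(y[fit_window] - base0)
    p0 = [max(amp0, 1e-12), float(e[fit_window]), max(spec.step, 1e-9), base0]
    try:
        popt, _ = optimize.curve_fit(
            model, e, y, p0=p0,
            bounds=([0.0, e[0], 1e-6 * spec.step, -np.inf],
                    [np.inf, e[-1], e[-1] - e[0], np.inf]),
            maxfev=2000)
    except (RuntimeError, ValueError):
        return _parabolic_vertex(spec, peak_index)
    resid = y - model(e, *popt)
    return PeakFit(center=float(popt[1]), width=float(abs(popt[2])),
                   amplitude=float(popt[0]),
                   fit_rmse=float(np.sqrt(np.mean(resid ** 2))),
                   method="gaussian")


def barcode_from_event(spec: Spectrum, params: ExtractionParams | None = None,
                       cell_id: str | None = None) -> Barcode:
    """Detect, refine and sort the lines of one flow event into a barcode.

    An empty or featureless spectrum yields a multiplicity-0 barcode (an
    untagged record).  Lines closer than ``min_separation`` merge into a
    single detection — a documented limitation of threshold-based peak
    finding.
    """
    params = params or ExtractionParams()
    peaks = detect_peaks(spec, params.min_prominence_mads, params.min_separation)
    centers = sorted(refine_peak(spec, int(p), params.fit_window).center
                     for p in peaks)
    cid = cell_id if cell_id is not None else str(spec.origin)
    return Barcode(cell_id=cid, energies=np.asarray(centers, dtype=float))


# ---------------------------------------------------------------------------
# Imaging mode: spatial-spectral clustering of pixel peaks
# ---------------------------------------------------------------------------


def cluster_pixel_peaks(peaks, spatial_radius: int = 1,
                        energy_tol: float = 1.0) -> list[LPCluster]:
    """Single-linkage clustering of pixel peaks into per-LP emission lines.

    Two pixel peaks connect when their Chebyshev pixel distance is at most
    ``spatial_radius`` and their energies differ by at most ``energy_tol``
    meV.  Each connected component is one LP; its emission energy is the
    unweighted mean of the member centers.  Two co-located LPs closer in
    energy than ``energy_tol`` merge into one cluster — a limitation by
    construction.
    """
    peaks = list(peaks)
    n = len(peaks)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            a, b = peaks[i], peaks[j]
            if max(abs(a.x - b.x), abs(a.y - b.y)) <= spatial_radius \
                    and abs(a.center - b.center) <= energy_tol:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters = [
        LPCluster(energy=float(np.mean([peaks[i].center for i in members])),
                  members=tuple(sorted(members)))
        for members in groups.values()
    ]
    clusters.sort(key=lambda c: c.energy)
    return clusters


# ---------------------------------------------------------------------------
# Unit conversion
# ---------------------------------------------------------------------------


def nm_to_mev(wavelength_nm):
    """Photon energy in meV from vacuum wavelength in nm."""
    w = np.asarray(wavelength_nm, dtype=float)
    if np.any(w <= 0):
        raise ValueError("wavelength must be positive")
    out = 1.0e3 * HC_EV_NM / w
    return float(out) if np.isscalar(wavelength_nm) else out


def mev_to_nm(energy_mev):
    """Vacuum wavelength in nm from photon energy in meV."""
    e = np.asarray(energy_mev, dtype=float)
    if np.any(e <= 0):
        raise ValueError("energy must be positive")
    out = 1.0e3 * HC_EV_NM / e
    return float(out) if np.isscalar(energy_mev) else out


def convert_units(value, direction: str):
    """Convert between nm and meV; ``direction`` is ``nm_to_mev`` or ``mev_to_nm``."""
    if direction == "nm_to_mev":
        return nm_to_mev(value)
    if direction == "mev_to_nm":
        return mev_to_nm(value)
    raise ValueError("direction must be 'nm_to_mev' or 'mev_to_nm'")
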