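"""Peak picking on mean spectra and reduction to a top-N peak feature space.

The profile data (cohort rows or cube pixels) are reduced by (1) averaging
all spectra into one mean spectrum, (2) picking local maxima with a gradient
(first-difference sign change) method, (3) keeping the N most intense peaks
and (4) integrating each raw spectrum over a small window around every kept
peak, giving a spectra x peaks (or pixels x peaks) feature matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .spectral_io import EmptyInputError, MSIDataCube, Spectrum, SpectrumCohort

__all__ = [
    "PeakList",
    "mean_spectrum",
    "gradient_peak_pick",
    "top_n",
    "default_peak_tolerance",
    "peak_feature_matrix",
    "build_datacube",
    "cohort_features",
]

logger = logging.getLogger(__name__)


@dataclass
class PeakList:
    """Peaks sorted by ascending m/z, with intensity-descending ranks (1..n)."""

    peak_mz: np.ndarray
    peak_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.peak_mz = np.asarray(self.peak_mz, dtype=float)
        self.peak_intensity = np.asarray(self.peak_intensity, dtype=float)
        if self.peak_mz.size != self.peak_intensity.size:
            raise ValueError("peak_mz and peak_intensity length mismatch")
        if self.peak_mz.size > 1 and np.any(np.diff(self.peak_mz) <= 0):
            order = np.argsort(self.peak_mz, kind="stable")
            self.peak_mz = self.peak_mz[order]
            self.peak_intensity = self.peak_intensity[order]

    def __len__(self) -> int:
        return int(self.peak_mz.size)

    @property
    def rank(self) -> np.ndarray:
        """Intensity-descending rank (1 = most intense); ties by lower m/z."""
        order = np.lexsort((self.peak_mz, -self.peak_intensity))
        ranks = np.empty(len(self), dtype=int)
        ranks[order] = np.arange(1, len(self) + 1)
        return ranks


def mean_spectrum(cohort: SpectrumCohort | MSIDataCube) -> Spectrum:
    """Arithmetic per-bin mean over all rows (spectra or pixels)."""
    if isinstance(cohort, MSIDataCube):
        axis, matrix = cohort.mz, cohort.intensities
    else:
        axis, matrix = cohort.common_mz, cohort.matrix
    if matrix.shape[0] == 0:
        raise EmptyInputError("cannot average an empty cohort")
    return Spectrum(axis, matrix.mean(axis=0))


def gradient_peak_pick(spectrum: Spectrum, min_intensity: float = 0.0) -> PeakList:
    """Local maxima by first-difference sign change (+ to -).

    A peak is a bin the signal rises into and falls after; plateau maxima
    report the plateau's centre bin (rounding down on even plateaus). Only
    maxima with intensity >= ``min_intensity`` are kept. Endpoints are never
    peaks.
    """
    y = spectrum.intensity
    if y.size < 3:
        raise EmptyInputError("spectrum too short to peak-pick (need >= 3 bins)")
    d = np.diff(y)
    s = np.sign(d)
    nz = np.flatnonzero(s)
    centres: list[int] = []
    for i, j in zip(nz[:-1], nz[1:]):
        if s[i] > 0 and s[j] < 0:
            # plateau spans bins i+1 .. j inclusive
            centres.append((i + 1 + j) // 2)
    if not centres:
        return PeakList(np.empty(0), np.empty(0))
    idx = np.asarray(centres)
    keep = y[idx] >= min_intensity
    idx = idx[keep]
    return PeakList(spectrum.mz[idx], y[idx])


def top_n(peaks: PeakList, n: int) -> PeakList:
    """Keep the n highest-intensity peaks, re-sorted by m/z.

    Intensity ties are broken toward lower m/z. If the list has fewer than n
    peaks it is returned unchanged. Idempotent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(peaks) <= n:
        return peaks
    order = np.lexsort((peaks.peak_mz, -peaks.peak_intensity))[:n]
    order.sort()  # back to ascending m/z
    return PeakList(peaks.peak_mz[order], peaks.peak_intensity[order])


def default_peak_tolerance(peaks: PeakList, cap: float = 0.05) -> float:
    """Half the median inter-peak gap, capped (integration window half-width)."""
    if len(peaks) < 2:
        return cap
    return float(min(cap, 0.5 * np.median(np.diff(peaks.peak_mz))))


def peak_feature_matrix(axis: np.ndarray, matrix: np.ndarray, peaks: PeakList,
                        tol: float | None = None) -> np.ndarray:
    """Sum raw bins within +/- tol of each peak m/z, per row.

    Bins claimed by two overlapping peak windows are resolved by
    nearest-peak assignment (a warning is logged). Returns rows x peaks.
    """
    if len(peaks) == 0:
        raise EmptyInputError("no peaks to integrate")
    if tol is None:
        tol = default_peak_tolerance(peaks)
    if tol <= 0:
        raise ValueError("tol must be positive")
    axis = np.asarray(axis, dtype=float)
    # nearest peak per bin
    pos = np.searchsorted(peaks.peak_mz, axis)
    left = np.clip(pos - 1, 0, len(peaks) - 1)
    right = np.clip(pos, 0, len(peaks) - 1)
    d_left = np.abs(axis - peaks.peak_mz[left])
    d_right = np.abs(axis - peaks.peak_mz[right])
    nearest = np.where(d_left <= d_right, left, right)
    dist = np.minimum(d_left, d_right)
    in_window = dist <= tol
    if len(peaks) > 1 and np.any(np.diff(peaks.peak_mz) < 2 * tol):
        logger.warning("overlapping peak windows resolved by nearest-peak assignment")
    bins = np.flatnonzero(in_window)
    indicator = sparse.csr_matrix(
        (np.ones(bins.size), (bins, nearest[bins])),
        shape=(axis.size, len(peaks)),
    )
    return np.asarray(matrix @ indicator)


def build_datacube(cube_raw: MSIDataCube, peaks: PeakList,
                   tol: float | None = None) -> MSIDataCube:
    """Reduce a raw profile cube to peak space (pixels x peaks)."""
    features = peak_feature_matrix(cube_raw.mz, cube_raw.intensities, peaks, tol)
    return cube_raw.with_features(peaks.peak_mz, features)


def cohort_features(cohort: SpectrumCohort, peaks: PeakList,
                    tol: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Reduce a cohort to peak space; returns (peak_mz, spectra x peaks)."""
    return peaks.peak_mz, peak_feature_matrix(cohort.common_mz, cohort.matrix,
                                              peaks, tol)
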