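"""Spectrum containers, axis construction, rebinning, normalization and file IO.

Profile spectra live on a shared uniform m/z axis so that cohorts can be
stacked into a spectra x bins matrix. Spatial data (MSI) are carried as an
:class:`MSIDataCube` and exchanged as continuous-mode imzML; cohorts and
metadata travel as TSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SampleMeta",
    "Spectrum",
    "SpectrumCohort",
    "MSIDataCube",
    "Thresholds",
    "build_axis",
    "rebin",
    "l2_normalize",
    "read_imzml",
    "write_imzml",
    "write_cohort_tsv",
    "read_cohort_tsv",
]


class EmptyInputError(ValueError):
    """Raised when an operation receives an empty spectrum or cohort."""


class NormalizationError(ValueError):
    """Raised when a row cannot be normalized (zero norm)."""


class ImzMLFormatError(ValueError):
    """Raised for unsupported or malformed imzML input."""


@dataclass
class SampleMeta:
    """Acquisition metadata for one spectrum.

    ``group_label`` carries the genotype (cohort mode) or mutation status
    (clinical mode); ``replicate_index`` distinguishes technical replicates
    of the same biological sample/patient.
    """

    sample_id: str
    group_label: str = ""
    patient_id: str | None = None
    sex: str | None = None
    replicate_index: int = 0
    polarity: str = "negative"
    modality: str = "REIMS"

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")


@dataclass
class Spectrum:
    """A single profile mass spectrum on an ascending m/z axis."""

    mz: np.ndarray
    intensity: np.ndarray
    meta: SampleMeta | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size != self.intensity.size:
            raise ValueError(
                f"mz and intensity length mismatch: {self.mz.size} != {self.intensity.size}"
            )
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz axis must be strictly increasing")
        if self.mz.size and float(np.min(self.intensity)) < 0:
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class SpectrumCohort:
    """A stack of spectra sharing one m/z axis, one metadata record per row."""

    common_mz: np.ndarray
    matrix: np.ndarray
    meta: list[SampleMeta]
    mass_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.common_mz = np.asarray(self.common_mz, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (spectra x bins)")
        if self.matrix.shape[1] != self.common_mz.size:
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} columns but axis has "
                f"{self.common_mz.size} bins"
            )
        if len(self.meta) != self.matrix.shape[0]:
            raise ValueError("one SampleMeta required per matrix row")
        if self.mass_window is not None:
            lo, hi = self.mass_window
            if self.common_mz.size and (
                self.common_mz[0] < lo - 1e-9 or self.common_mz[-1] > hi + 1e-9
            ):
                raise ValueError("common_mz extends outside mass_window")

    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[0]

    @property
    def group_labels(self) -> np.ndarray:
        return np.array([m.group_label for m in self.meta])

    def restrict(self, mass_window: tuple[float, float]) -> "SpectrumCohort":
        """Slice the cohort to ``mass_window`` (inclusive bounds)."""
        lo, hi = mass_window
        if lo >= hi:
            raise ValueError("mass_window lower bound must be below upper bound")
        keep = (self.common_mz >= lo) & (self.common_mz <= hi)
        return SpectrumCohort(
            common_mz=self.common_mz[keep],
            matrix=self.matrix[:, keep],
            meta=list(self.meta),
            mass_window=(lo, hi),
        )

    def subset(self, rows: np.ndarray) -> "SpectrumCohort":
        rows = np.asarray(rows)
        idx = np.flatnonzero(rows) if rows.dtype == bool else rows
        return SpectrumCohort(
            common_mz=self.common_mz,
            matrix=self.matrix[idx],
            meta=[self.meta[i] for i in idx],
            mass_window=self.mass_window,
        )

    def row_spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.common_mz, self.matrix[i], self.meta[i])


@dataclass
class MSIDataCube:
    """Pixel-indexed intensity matrix with 0-based row-major coordinates.

    ``mz`` is either a dense profile axis (raw cube) or a peak m/z vector
    (peak-space datacube); ``intensities`` is pixels x features.
    """

    mz: np.ndarray
    intensities: np.ndarray
    coordinates: np.ndarray  # (n_pixels, 2) int, columns (x, y), 0-based
    width: int
    height: int

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=int)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D (pixels x features)")
        if self.intensities.shape[1] != self.mz.size:
            raise ValueError("feature axis length mismatch")
        if self.coordinates.shape != (self.intensities.shape[0], 2):
            raise ValueError("coordinates must be (n_pixels, 2)")
        if self.coordinates.size:
            x, y = self.coordinates[:, 0], self.coordinates[:, 1]
            if x.min() < 0 or y.min() < 0 or x.max() >= self.width or y.max() >= self.height:
                raise ImzMLFormatError("pixel coordinates outside cube dimensions")

    @property
    def n_pixels(self) -> int:
        return self.intensities.shape[0]

    def label_image(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a per-pixel vector onto a (height, width) image."""
        values = np.asarray(values)
        img = np.full((self.height, self.width), fill, dtype=float)
        img[self.coordinates[:, 1], self.coordinates[:, 0]] = values
        return img

    def with_features(self, mz: np.ndarray, intensities: np.ndarray) -> "MSIDataCube":
        return MSIDataCube(mz, intensities, self.coordinates, self.width, self.height)


@dataclass
class Thresholds:
    """Analysis thresholds; defaults follow the published workflow settings."""

    bin_width: float = 0.001
    top_n_peaks: int = 2000          # 4000 for MSI datacubes
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    fdr_q: float = 0.05              # 0.1 for MSI pixel comparisons
    ppm_tol: float = 5.0
    n_selected_features: int = 50

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.top_n_peaks <= 0 or self.fc_threshold <= 0:
            raise ValueError("bin_width, top_n_peaks and fc_threshold must be positive")
        for name in ("p_threshold", "fdr_q"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.ppm_tol <= 0 or self.n_selected_features <= 0:
            raise ValueError("ppm_tol and n_selected_features must be positive")

    @classmethod
    def msi(cls, **overrides) -> "Thresholds":
        defaults = dict(top_n_peaks=4000, fdr_q=0.1)
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Thresholds":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


def build_axis(mass_window: tuple[float, float], bin_width: float) -> np.ndarray:
    """Uniform m/z axis from lower to upper bound inclusive.

    Length is floor((upper - lower) / bin_width) + 1; spacing is exactly
    ``bin_width`` (the axis is generated as lower + k * bin_width so the step
    is constant to floating precision).
    """
    lo, hi = float(mass_window[0]), float(mass_window[1])
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if hi < lo:
        raise ValueError("mass_window upper bound below lower bound")
    # tolerate float division landing a hair under an integer bin count
    n = int(math.floor((hi - lo) / bin_width + 1e-9)) + 1
    return lo + np.arange(n) * bin_width


def rebin(spectrum: Spectrum, target_axis: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto ``target_axis``.

    Points outside the source m/z range get intensity 0 (absent signal, not
    extrapolation). A spectrum already sampled on the target axis is returned
    unchanged up to floating arithmetic.
    """
    target_axis = np.asarray(target_axis, dtype=float)
    if len(spectrum) == 0:
        raise EmptyInputError("cannot rebin an empty spectrum")
    if target_axis.size > 1 and np.any(np.diff(target_axis) <= 0):
        raise ValueError("target_axis must be strictly increasing")
    out = np.interp(target_axis, spectrum.mz, spectrum.intensity, left=0.0, right=0.0)
    return Spectrum(target_axis, np.maximum(out, 0.0), spectrum.meta)


def rebin_cohort(spectra: Sequence[Spectrum], target_axis: np.ndarray,
                 mass_window: tuple[float, float] | None = None) -> SpectrumCohort:
    """Rebin a list of spectra onto one axis and stack them into a cohort."""
    if not spectra:
        raise EmptyInputError("no spectra to rebin")
    rows = [rebin(s, target_axis).intensity for s in spectra]
    meta = [s.meta if s.meta is not None else SampleMeta(sample_id=f"s{i}")
            for i, s in enumerate(spectra)]
    return SpectrumCohort(np.asarray(target_axis, dtype=float), np.vstack(rows),
                          meta, mass_window)


def l2_normalize(cohort: SpectrumCohort) -> SpectrumCohort:
    """Scale every row to unit Euclidean norm.

    Raises :class:`NormalizationError` naming the offending sample if any row
    is all zero. Idempotent: normalizing twice equals normalizing once.
    """
    norms = np.linalg.norm(cohort.matrix, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise NormalizationError(
            f"cannot l2-normalize all-zero spectrum: sample_id="
            f"{cohort.meta[zero[0]].sample_id!r}"
        )
    return replace(cohort, matrix=cohort.matrix / norms[:, None])


# ---------------------------------------------------------------------------
# imzML IO (continuous mode)
# ---------------------------------------------------------------------------

def write_imzml(cube: MSIDataCube, path: str | Path) -> None:
    """Write a cube as continuous-mode imzML (.imzML + .ibd pair).

    Internal 0-based coordinates are converted to imzML's 1-based pixel
    coordinates on write.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = str(path)
    with ImzMLWriter(path, mode="continuous", mz_dtype=np.float64,
                     intensity_dtype=np.float64) as writer:
        for i in range(cube.n_pixels):
            x, y = cube.coordinates[i]
            writer.addSpectrum(cube.mz, cube.intensities[i], (int(x) + 1, int(y) + 1))


def read_imzml(path: str | Path) -> MSIDataCube:
    """Read a continuous-mode imzML file into an :class:`MSIDataCube`.

    Processed-mode files (per-pixel m/z axes) are rejected with an
    unsupported-dialect error; 1-based coordinates are converted to 0-based.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    try:
        n = len(parser.coordinates)
        if n == 0:
            raise ImzMLFormatError(f"{path}: no pixel coordinates found")
        ref_mz, first = parser.getspectrum(0)
        ref_mz = np.asarray(ref_mz, dtype=float)
        intensities = np.empty((n, ref_mz.size), dtype=float)
        intensities[0] = first
        for i in range(1, n):
            mz, ints = parser.getspectrum(i)
            mz = np.asarray(mz, dtype=float)
            if mz.size != ref_mz.size or not np.array_equal(mz, ref_mz):
                raise ImzMLFormatError(
                    f"{path}: processed-mode imzML (per-pixel m/z axes) is not supported"
                )
            intensities[i] = ints
        coords = np.asarray([(c[0] - 1, c[1] - 1) for c in parser.coordinates], dtype=int)
    finally:
        if getattr(parser, "m", None) is not None:
            parser.m.close()
    width = int(coords[:, 0].max()) + 1
    height = int(coords[:, 1].max()) + 1
    return MSIDataCube(ref_mz, intensities, coords, width, height)


# ---------------------------------------------------------------------------
# tabular cohort IO
# ---------------------------------------------------------------------------

_META_COLUMNS = ["sample_id", "group_label", "patient_id", "sex",
                 "replicate_index", "polarity", "modality"]


def write_cohort_tsv(cohort: SpectrumCohort, data_path: str | Path,
                     meta_path: str | Path) -> None:
    """Write a cohort as a data TSV (m/z header row) plus a metadata TSV."""
    df = pd.DataFrame(cohort.matrix, columns=[f"{v:.6f}" for v in cohort.common_mz])
    df.insert(0, "sample_id", [m.sample_id for m in cohort.meta])
    df.to_csv(data_path, sep="\t", index=False)
    meta = pd.DataFrame([{c: getattr(m, c) for c in _META_COLUMNS} for m in cohort.meta])
    meta.to_csv(meta_path, sep="\t", index=False)


def read_cohort_tsv(data_path: str | Path, meta_path: str | Path,
                    mass_window: tuple[float, float] | None = None) -> SpectrumCohort:
    df = pd.read_csv(data_path, sep="\t")
    meta_df = pd.read_csv(meta_path, sep="\t")
    mz = np.array([float(c) for c in df.columns[1:]])
    meta: list[SampleMeta] = []
    for _, row in meta_df.iterrows():
        meta.append(SampleMeta(
            sample_id=str(row["sample_id"]),
            group_label="" if pd.isna(row.get("group_label")) else str(row["group_label"]),
            patient_id=None if pd.isna(row.get("patient_id")) else str(row["patient_id"]),
            sex=None if pd.isna(row.get("sex")) else str(row["sex"]),
            replicate_index=int(row.get("replicate_index", 0)),
            polarity=str(row.get("polarity", "negative")),
            modality=str(row.get("modality", "REIMS")),
        ))
    return SpectrumCohort(mz, df.iloc[:, 1:].to_numpy(dtype=float), meta, mass_window)
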