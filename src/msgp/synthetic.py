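"""Synthetic data generators with planted ground truth.

Everything the pipeline consumes can be generated here at desk scale:
multi-genotype spectral cohorts (with inactive acquisition segments for burn
detection), MSI cubes with spatially contiguous tissue compartments, clinical
patient cohorts with technical replicates and batch confounders, and a toy
compound/pathway database. Generators are pure functions of (spec, seed):
the same seed yields bit-identical output.

Intensity model: each ion has a baseline amplitude; a spectrum's peak
amplitude is baseline x group/compartment effect x lognormal(0, noise_sigma),
realised as a Gaussian profile on the dense m/z axis. Inactive (forceps-off)
segments are the same spectrum scaled by 0.01. These choices emulate the
non-negative, heteroscedastic character of MS intensities, not any specific
instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .spectral_io import MSIDataCube, SampleMeta, SpectrumCohort, build_axis

__all__ = [
    "CohortSpec",
    "CohortTruth",
    "CubeSpec",
    "CubeTruth",
    "ToyCompoundDB",
    "CompoundRecord",
    "generate_cohort",
    "generate_cube",
    "generate_clinical_cohort",
    "generate_compound_db",
    "make_compartment_map",
]

INACTIVE_SCALE = 0.01  # forceps-off segments: whole spectrum scaled by this

COMPARTMENTS = ("background", "normal", "stroma", "tumour")


class InsufficientCohortError(ValueError):
    """Raised when a clinical cohort is too small to be meaningful."""


# ---------------------------------------------------------------------------
# spectral cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Design of a synthetic multi-group REIMS-style cohort.

    ``effect_matrix`` holds multiplicative group x ion effects (>= 0); a
    value of 1 means no group effect on that ion. ``background_fraction`` is
    the proportion of inactive acquisition segments in the final cohort.
    """

    n_groups: int = 5
    samples_per_group: int | Sequence[int] | None = None
    spectra_per_sample: int = 10
    n_ions: int = 200
    mz_range: tuple[float, float] = (600.0, 900.0)
    effect_matrix: np.ndarray | None = None
    noise_sigma: float = 0.2
    background_fraction: float = 0.2
    seed: int = 0
    bin_width: float = 0.01
    peak_fwhm: float = 0.05
    noise_floor: float = 0.5
    n_background_ions: int = 25
    background_ion_scale: float = 0.05
    group_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.samples_per_group is None:
            # five-genotype default mirrors the WT/KRAS/APC/APC-KRAS/
            # APC-KRAS-PTEN design (3/4/11/4/5 animals)
            self.samples_per_group = ((3, 4, 11, 4, 5) if self.n_groups == 5
                                      else 4)
        if np.isscalar(self.samples_per_group):
            self.samples_per_group = (int(self.samples_per_group),) * self.n_groups
        else:
            self.samples_per_group = tuple(int(v) for v in self.samples_per_group)
        if len(self.samples_per_group) != self.n_groups:
            raise ValueError("samples_per_group length must equal n_groups")
        if self.effect_matrix is not None:
            self.effect_matrix = np.asarray(self.effect_matrix, dtype=float)
            if self.effect_matrix.shape != (self.n_groups, self.n_ions):
                raise ValueError(
                    f"effect_matrix must be n_groups x n_ions "
                    f"({self.n_groups} x {self.n_ions}), got {self.effect_matrix.shape}"
                )
            if np.any(self.effect_matrix < 0):
                raise ValueError("effects must be >= 0")
        if self.mz_range[0] >= self.mz_range[1]:
            raise ValueError("mz_range lower bound must be below upper bound")
        if not (0 <= self.background_fraction < 1):
            raise ValueError("background_fraction must lie in [0, 1)")
        if self.group_names is None:
            self.group_names = tuple(f"G{i}" for i in range(self.n_groups))

    @classmethod
    def with_marker_ions(cls, n_groups: int = 5,
                         markers_per_group: int = 10,
                         effect: float = 4.0,
                         n_ions: int | None = None,
                         **kwargs) -> "CohortSpec":
        """Spec where each group up-regulates its own block of marker ions.

        The default design mirrors a five-genotype cohort with 4x effects on
        10 group-specific ions each.
        """
        if n_ions is None:
            n_ions = kwargs.pop("n_ions", max(200, n_groups * markers_per_group + 10))
        effects = np.ones((n_groups, n_ions))
        for g in range(n_groups):
            lo = g * markers_per_group
            effects[g, lo:lo + markers_per_group] = effect
        return cls(n_groups=n_groups, n_ions=n_ions, effect_matrix=effects, **kwargs)


@dataclass
class CohortTruth:
    """Planted ground truth accompanying a generated cohort."""

    group_labels: np.ndarray        # per spectrum, "background" for inactive rows
    active_mask: np.ndarray         # per spectrum, True for active acquisition
    ion_mz: np.ndarray              # planted ion centres (ascending)
    ion_baseline: np.ndarray        # per-ion baseline amplitude
    effect_matrix: np.ndarray       # group x ion effects actually used


def _gaussian_profiles(axis: np.ndarray, centres: np.ndarray, fwhm: float) -> np.ndarray:
    """(n_centres, n_bins) unit-height Gaussian profile matrix, truncated at 5 sigma."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    profiles = np.zeros((centres.size, axis.size))
    half = 5.0 * sigma
    for i, c in enumerate(centres):
        lo = np.searchsorted(axis, c - half)
        hi = np.searchsorted(axis, c + half)
        profiles[i, lo:hi] = np.exp(-0.5 * ((axis[lo:hi] - c) / sigma) ** 2)
    return profiles


def generate_cohort(spec: CohortSpec) -> tuple[SpectrumCohort, CohortTruth]:
    """Generate one profile spectrum per (sample, replicate) plus inactive segments.

    Ion peaks are Gaussian profiles at randomly placed m/z positions with
    amplitude = baseline x group effect x lognormal(0, noise_sigma). Inactive
    segments (a ``background_fraction`` of the final cohort) are appended
    after the active spectra, scaled by ``INACTIVE_SCALE``; every spectrum
    additionally carries an additive uniform baseline-noise floor that
    dominates the inactive segments (flat, instrument-noise-like shape) but
    is negligible against active peaks. The floor is part of the stochastic
    model and is switched off together with ``noise_sigma`` in the
    exactly-noiseless limit, so noiseless no-effect cohorts are identical
    across groups.

    Inactive segments additionally carry solvent/ambient ions at their own
    m/z positions (disjoint from the tissue ions), mirroring forceps-off
    REIMS acquisitions being dominated by the isopropanol matrix rather
    than tissue lipids; this gives them a spectral direction distinct from
    every tissue genotype, which is what the k=2 cosine burn detection
    exploits.
    """
    rng = np.random.default_rng(spec.seed)
    axis = build_axis(spec.mz_range, spec.bin_width)
    floor = spec.noise_floor if spec.noise_sigma > 0 else 0.0

    lo, hi = spec.mz_range
    margin = 3.0 * spec.peak_fwhm
    ion_mz = np.sort(rng.uniform(lo + margin, hi - margin, size=spec.n_ions))
    ion_baseline = rng.lognormal(mean=np.log(100.0), sigma=0.5, size=spec.n_ions)
    effects = (spec.effect_matrix if spec.effect_matrix is not None
               else np.ones((spec.n_groups, spec.n_ions)))
    profiles = _gaussian_profiles(axis, ion_mz, spec.peak_fwhm)

    rows, meta, labels = [], [], []
    for g, n_samples in enumerate(spec.samples_per_group):
        for s in range(n_samples):
            for r in range(spec.spectra_per_sample):
                noise = (rng.lognormal(0.0, spec.noise_sigma, size=spec.n_ions)
                         if spec.noise_sigma > 0 else np.ones(spec.n_ions))
                amps = ion_baseline * effects[g] * noise
                row = amps @ profiles
                if floor > 0:
                    row = row + rng.uniform(0.0, floor, size=axis.size)
                rows.append(row)
                meta.append(SampleMeta(
                    sample_id=f"{spec.group_names[g]}_s{s}_r{r}",
                    group_label=str(spec.group_names[g]),
                    patient_id=f"{spec.group_names[g]}_s{s}",
                    sex=("M" if (g + s) % 2 == 0 else "F"),
                    replicate_index=r,
                ))
                labels.append(str(spec.group_names[g]))

    n_active = len(rows)
    n_bg = int(round(spec.background_fraction * n_active
                     / (1.0 - spec.background_fraction)))
    solvent_mz = np.sort(rng.uniform(lo + margin, hi - margin,
                                     size=spec.n_background_ions))
    solvent_baseline = rng.lognormal(mean=np.log(100.0), sigma=0.5,
                                     size=spec.n_background_ions)
    solvent_profiles = _gaussian_profiles(axis, solvent_mz, spec.peak_fwhm)
    for b in range(n_bg):
        noise = (rng.lognormal(0.0, spec.noise_sigma, size=spec.n_ions)
                 if spec.noise_sigma > 0 else np.ones(spec.n_ions))
        amps = INACTIVE_SCALE * ion_baseline * noise
        row = amps @ profiles
        s_noise = (rng.lognormal(0.0, spec.noise_sigma,
                                 size=spec.n_background_ions)
                   if spec.noise_sigma > 0 else np.ones(spec.n_background_ions))
        row = row + (spec.background_ion_scale * solvent_baseline
                     * s_noise) @ solvent_profiles
        if floor > 0:
            row = row + rng.uniform(0.0, floor, size=axis.size)
        rows.append(row)
        meta.append(SampleMeta(sample_id=f"bg_{b}", group_label="background",
                               patient_id=None, replicate_index=b))
        labels.append("background")

    cohort = SpectrumCohort(axis, np.vstack(rows), meta, mass_window=spec.mz_range)
    active = np.array([lab != "background" for lab in labels])
    truth = CohortTruth(np.array(labels), active, ion_mz, ion_baseline, effects)
    return cohort, truth


# ---------------------------------------------------------------------------
# MSI cubes
# ---------------------------------------------------------------------------

def make_compartment_map(width: int, height: int,
                         border: int | None = None) -> np.ndarray:
    """A simple contiguous tissue layout: background border, tumour core,
    stroma ring, normal tissue elsewhere. Returns (height, width) int labels
    indexing :data:`COMPARTMENTS`.
    """
    if border is None:
        border = max(1, min(4, min(width, height) // 5))
    cmap = np.ones((height, width), dtype=int)  # normal
    cmap[:border, :] = 0
    cmap[-border:, :] = 0
    cmap[:, :border] = 0
    cmap[:, -border:] = 0
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = height / 2.0, width / 2.0
    r = np.hypot(yy - cy, xx - cx)
    r_tum = min(width, height) / 5.0
    cmap[(r < r_tum * 1.8) & (cmap != 0)] = 2   # stroma ring
    cmap[(r < r_tum) & (cmap != 0)] = 3         # tumour core
    if not np.any(cmap > 0):  # degenerate tiny cube: keep one tissue pixel
        cmap[height // 2, width // 2] = 1
    return cmap


@dataclass
class CubeSpec:
    """Design of a synthetic MSI datacube with planted compartments."""

    width: int = 40
    height: int = 40
    compartment_map: np.ndarray | None = None   # (height, width) labels into COMPARTMENTS
    signature_matrix: np.ndarray | None = None  # n_compartments x n_ions effects
    n_ions: int = 150
    mz_range: tuple[float, float] = (100.0, 250.0)
    noise_sigma: float = 0.3
    seed: int = 0
    bin_width: float = 0.02
    peak_fwhm: float = 0.05
    n_background_ions: int = 20
    background_ion_scale: float = 0.05

    def __post_init__(self) -> None:
        if self.compartment_map is None:
            self.compartment_map = make_compartment_map(self.width, self.height)
        self.compartment_map = np.asarray(self.compartment_map, dtype=int)
        if self.compartment_map.shape != (self.height, self.width):
            raise ValueError(
                f"compartment_map must be (height, width) = "
                f"({self.height}, {self.width}), got {self.compartment_map.shape}"
            )
        if not np.any(self.compartment_map == 0) or not np.any(self.compartment_map > 0):
            raise ValueError("need at least one background and one non-background pixel")
        if self.signature_matrix is not None:
            self.signature_matrix = np.asarray(self.signature_matrix, dtype=float)
            n_comp = int(self.compartment_map.max()) + 1
            if self.signature_matrix.shape != (n_comp, self.n_ions):
                raise ValueError(
                    f"signature_matrix must be n_compartments x n_ions "
                    f"({n_comp} x {self.n_ions}), got {self.signature_matrix.shape}"
                )

    @classmethod
    def with_marker_ions(cls, markers_per_compartment: int = 5,
                         effect: float = 5.0, n_ions: int = 150,
                         **kwargs) -> "CubeSpec":
        """Each tissue compartment up-regulates its own marker-ion block.

        Marker blocks are kept a small fraction of the total so that RMS /
        l2 normalization does not induce fold changes above the volcano
        threshold on null ions. Tumour markers occupy the last block.
        """
        spec = cls(n_ions=n_ions, signature_matrix=None, **kwargs)
        n_comp = int(spec.compartment_map.max()) + 1
        sig = np.ones((n_comp, n_ions))
        sig[0, :] = 0.02  # background: low-intensity distribution
        for c in range(1, n_comp):
            lo = (c - 1) * markers_per_compartment
            sig[c, lo:lo + markers_per_compartment] = effect
        spec.signature_matrix = sig
        return spec


@dataclass
class CubeTruth:
    compartment_labels: np.ndarray   # per pixel, int into COMPARTMENTS
    ion_mz: np.ndarray               # tissue ions only
    ion_baseline: np.ndarray
    signature_matrix: np.ndarray
    solvent_mz: np.ndarray = field(default_factory=lambda: np.empty(0))


def generate_cube(spec: CubeSpec, imzml_path: str | None = None
                  ) -> tuple[MSIDataCube, CubeTruth]:
    """Generate a profile-mode MSI cube from a compartment map.

    Per pixel, peak amplitudes are drawn from the pixel's compartment
    signature with multiplicative lognormal noise; background pixels use the
    (low) background signature row. Solvent/matrix ions at their own m/z
    positions are present in every pixel at a modest level, so off-tissue
    pixels (whose tissue signal is ~2% of tissue pixels) are dominated by
    the solvent signature rather than being a scaled copy of tissue - the
    spectral contrast that makes background separable by cosine k-means,
    as in real MSI acquisitions. Coordinates are 0-based, row-major.
    """
    rng = np.random.default_rng(spec.seed)
    axis = build_axis(spec.mz_range, spec.bin_width)
    lo, hi = spec.mz_range
    margin = 3.0 * spec.peak_fwhm
    ion_mz = np.sort(rng.uniform(lo + margin, hi - margin, size=spec.n_ions))
    ion_baseline = rng.lognormal(mean=np.log(100.0), sigma=0.5, size=spec.n_ions)
    sig = spec.signature_matrix
    if sig is None:
        n_comp = int(spec.compartment_map.max()) + 1
        sig = np.ones((n_comp, spec.n_ions))
        sig[0, :] = 0.02
    profiles = _gaussian_profiles(axis, ion_mz, spec.peak_fwhm)

    labels = spec.compartment_map.reshape(-1)  # row-major: y major, x minor
    n_pix = labels.size
    noise = (rng.lognormal(0.0, spec.noise_sigma, size=(n_pix, spec.n_ions))
             if spec.noise_sigma > 0 else np.ones((n_pix, spec.n_ions)))
    amps = ion_baseline[None, :] * sig[labels] * noise
    intensities = amps @ profiles
    solvent_mz = np.empty(0)
    if spec.n_background_ions > 0:
        solvent_mz = np.sort(rng.uniform(lo + margin, hi - margin,
                                         size=spec.n_background_ions))
        solvent_baseline = rng.lognormal(mean=np.log(100.0), sigma=0.5,
                                         size=spec.n_background_ions)
        s_noise = (rng.lognormal(0.0, spec.noise_sigma,
                                 size=(n_pix, spec.n_background_ions))
                   if spec.noise_sigma > 0
                   else np.ones((n_pix, spec.n_background_ions)))
        s_profiles = _gaussian_profiles(axis, solvent_mz, spec.peak_fwhm)
        intensities = intensities + (
            spec.background_ion_scale * solvent_baseline[None, :] * s_noise
        ) @ s_profiles

    yy, xx = np.divmod(np.arange(n_pix), spec.width)
    coords = np.column_stack([xx, yy])
    cube = MSIDataCube(axis, intensities, coords, spec.width, spec.height)
    truth = CubeTruth(labels.copy(), ion_mz, ion_baseline, sig, solvent_mz)
    if imzml_path is not None:
        from .spectral_io import write_imzml
        write_imzml(cube, imzml_path)
    return cube, truth


# ---------------------------------------------------------------------------
# clinical cohorts
# ---------------------------------------------------------------------------

@dataclass
class ClinicalTruth:
    informative: np.ndarray   # feature indices shifting with the label
    batch_confounded: np.ndarray  # feature indices shifting with batch
    patient_labels: pd.Series     # per patient (0/1)
    patient_batch: pd.Series      # per patient batch id


def generate_clinical_cohort(n_patients: int = 24, replicates: int = 3,
                             n_features: int = 200, n_informative: int = 20,
                             n_batch: int = 20, effect: float = 2.0,
                             noise_sigma: float = 1.0, n_positive: int | None = None,
                             n_batches: int = 2, seed: int = 0
                             ) -> tuple[pd.DataFrame, list[SampleMeta], ClinicalTruth]:
    """Replicate-structured feature table with a binary patient label.

    Informative features shift by ``effect`` with the label; batch features
    shift by the same magnitude with a batch variable assigned independently
    of the label. All rows of a patient share its label and batch. The
    default design mirrors a 24-patient 16/8 cohort with 3 technical
    replicates and 200 features.
    """
    if n_patients < 4:
        raise InsufficientCohortError("need at least 4 patients")
    if n_informative + n_batch > n_features:
        raise ValueError("n_informative + n_batch must not exceed n_features")
    rng = np.random.default_rng(seed)
    if n_positive is None:
        n_positive = 2 * n_patients // 3
    labels = np.zeros(n_patients, dtype=int)
    labels[:n_positive] = 1
    batch = rng.integers(0, n_batches, size=n_patients)

    informative = np.arange(n_informative)
    batch_feats = np.arange(n_informative, n_informative + n_batch)
    # signed effect direction per feature, fixed across the cohort
    inf_dir = rng.choice([-1.0, 1.0], size=n_informative)
    bat_dir = rng.choice([-1.0, 1.0], size=n_batch)

    rows, meta = [], []
    for p in range(n_patients):
        for r in range(replicates):
            x = rng.normal(0.0, noise_sigma, size=n_features)
            x[informative] += effect * inf_dir * labels[p]
            x[batch_feats] += effect * bat_dir * batch[p]
            rows.append(x)
            meta.append(SampleMeta(
                sample_id=f"P{p:02d}_r{r}", group_label=str(labels[p]),
                patient_id=f"P{p:02d}", replicate_index=r,
                sex=("M" if p % 2 else "F"),
            ))
    X = pd.DataFrame(np.vstack(rows),
                     columns=[f"f{j:03d}" for j in range(n_features)],
                     index=[m.sample_id for m in meta])
    truth = ClinicalTruth(
        informative=informative, batch_confounded=batch_feats,
        patient_labels=pd.Series(labels, index=[f"P{p:02d}" for p in range(n_patients)]),
        patient_batch=pd.Series(batch, index=[f"P{p:02d}" for p in range(n_patients)]),
    )
    return X, meta, truth


# ---------------------------------------------------------------------------
# toy compound database
# ---------------------------------------------------------------------------

@dataclass
class CompoundRecord:
    compound_name: str
    monoisotopic_mass: float
    formula: str | None
    pathways: list[tuple[str, str]]  # (pathway_name, subclass)

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise ValueError("monoisotopic_mass must be positive")
        for name, sub in self.pathways:
            if not sub:
                raise ValueError(f"pathway {name!r} has empty subclass")


@dataclass
class ToyCompoundDB:
    """A small local compound/pathway table standing in for a metabolite DB."""

    records: list[CompoundRecord]

    def __post_init__(self) -> None:
        names = [r.compound_name for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError("compound names must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def to_tsv(self, path) -> None:
        rows = []
        for r in self.records:
            for pathway, sub in r.pathways:
                rows.append(dict(name=r.compound_name,
                                 monoisotopic_mass=r.monoisotopic_mass,
                                 formula=r.formula or "", pathway=pathway,
                                 subclass=sub))
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ToyCompoundDB":
        df = pd.read_csv(path, sep="\t")
        records = []
        for name, grp in df.groupby("name", sort=False):
            records.append(CompoundRecord(
                compound_name=str(name),
                monoisotopic_mass=float(grp["monoisotopic_mass"].iloc[0]),
                formula=(str(grp["formula"].iloc[0]) or None)
                if not pd.isna(grp["formula"].iloc[0]) else None,
                pathways=[(str(p), str(s))
                          for p, s in zip(grp["pathway"], grp["subclass"])],
            ))
        return cls(records)


_LIPID_CLASSES = ("PC", "PE", "PS", "PI", "PG", "SM", "LPC", "LPE", "TG", "DG")
_CLASS_FULL = {
    "PC": "Phosphatidylcholine", "PE": "Phosphatidylethanolamine",
    "PS": "Phosphatidylserine", "PI": "Phosphatidylinositol",
    "PG": "Phosphatidylglycerol", "SM": "Sphingomyelin",
    "LPC": "Lysophosphatidylcholine", "LPE": "Lysophosphatidylethanolamine",
    "TG": "Triacylglycerol", "DG": "Diacylglycerol",
}
_DB_POSITIONS = ("9Z", "11Z", "13Z", "4Z,7Z", "6Z,9Z,12Z")


def generate_compound_db(n_compounds: int = 200, n_pathways: int = 25,
                         lipid_fraction: float = 0.7, seed: int = 0) -> ToyCompoundDB:
    """Toy compound DB with lipid-style names and subclass-grouped pathways.

    Masses are uniform in [50, 1500] Da; a ``lipid_fraction`` of compounds get
    names of the form CLASS(c1:d1(pos)/c2:d2) so that downstream lipid-name
    curation has material to work on. Each compound joins 1-5 pathways.
    """
    if n_compounds <= 0 or n_pathways <= 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    # pathway pool: grouped into subclasses, some carrying lipid tokens
    pathways: list[tuple[str, str]] = []
    for i in range(n_pathways):
        cls = _LIPID_CLASSES[i % len(_LIPID_CLASSES)]
        sub = f"{_CLASS_FULL[cls]} metabolism"
        if i % 2 == 0:
            c1, c2 = 2 * rng.integers(7, 13), 2 * rng.integers(7, 13)
            d1, d2 = int(rng.integers(0, 3)), int(rng.integers(0, 4))
            pos = _DB_POSITIONS[int(rng.integers(0, len(_DB_POSITIONS)))]
            token = f"{cls}({c1}:{d1}({pos})/{c2}:{d2})" if d1 else f"{cls}({c1}:{d1}/{c2}:{d2})"
            name = f"{_CLASS_FULL[cls]} Biosynthesis {token}"
        else:
            name = f"{_CLASS_FULL[cls]} pathway {i}"
        pathways.append((name, sub))

    records: list[CompoundRecord] = []
    seen: set[str] = set()
    for i in range(n_compounds):
        if rng.random() < lipid_fraction:
            cls = _LIPID_CLASSES[int(rng.integers(0, len(_LIPID_CLASSES)))]
            c1, c2 = 2 * rng.integers(6, 13), 2 * rng.integers(6, 13)
            d1, d2 = int(rng.integers(0, 3)), int(rng.integers(0, 4))
            name = f"{cls}({c1}:{d1}/{c2}:{d2})"
        else:
            name = f"compound_{i}"
        if name in seen:
            name = f"{name}#{i}"
        seen.add(name)
        mass = float(rng.uniform(50.0, 1500.0))
        k = int(rng.integers(1, 6))
        idx = rng.choice(n_pathways, size=min(k, n_pathways), replace=False)
        records.append(CompoundRecord(
            compound_name=name, monoisotopic_mass=mass, formula=None,
            pathways=[pathways[j] for j in idx],
        ))
    return ToyCompoundDB(records)
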