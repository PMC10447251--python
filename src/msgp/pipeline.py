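"""End-to-end orchestration of the cohort, MSI and clinical workflows.

Each ``run_*`` function composes the stage modules into the published order
of operations, returns a result object, and (optionally) writes all
artefacts plus a reproducibility manifest into a run directory. Stages are
pure functions of their inputs; the orchestration adds no hidden state.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import match_ions, rank_pathways
from .classify import ClassifierReport, lopo_cross_validate, visualize_refined
from .differential import DifferentialTable, pairwise_volcano
from .peaks import PeakList, build_datacube, cohort_features, gradient_peak_pick, \
    mean_spectrum, top_n
from .segment import SegmentationResult, detect_active_spectra, kmeans_cluster, \
    purity_table, segment_cube, tsne_embed
from .spectral_io import MSIDataCube, SampleMeta, SpectrumCohort, Thresholds, \
    l2_normalize
from .synthetic import ToyCompoundDB

logger = logging.getLogger(__name__)

__all__ = [
    "CohortResult",
    "MSIResult",
    "ClinicalResult",
    "run_cohort_pipeline",
    "run_msi_pipeline",
    "run_clinical_pipeline",
    "write_manifest",
]


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir: Path, config: dict) -> None:
    manifest = {
        "config": config,
        "config_hash": _config_hash(config),
        "package_version": __version__,
        "python_version": platform.python_version(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


@dataclass
class CohortResult:
    embedding: np.ndarray
    labels: np.ndarray
    active_mask: np.ndarray
    peaks: PeakList
    features: np.ndarray              # active spectra x peaks (l2-normalized space)
    meta: list[SampleMeta]            # active spectra only
    purity: pd.DataFrame
    volcano: dict[tuple[str, str], DifferentialTable]
    pathway_rankings: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        emb = pd.DataFrame(self.embedding, columns=["tsne1", "tsne2", "tsne3"])
        emb.insert(0, "sample_id", [m.sample_id for m in self.meta])
        emb["cluster"] = self.labels
        emb["group_label"] = [m.group_label for m in self.meta]
        emb.to_csv(out / "embedding.tsv", sep="\t", index=False)
        emb[["sample_id", "cluster", "group_label"]].to_csv(
            out / "labels.tsv", sep="\t", index=False)
        self.purity.to_csv(out / "purity.tsv", sep="\t", index=False)
        for (a, b), table in self.volcano.items():
            table.to_tsv(out / f"volcano_{a}_vs_{b}.tsv")
        for (a, b), ranking in self.pathway_rankings.items():
            ranking.to_csv(out / f"pathways_{a}_vs_{b}.tsv", sep="\t", index=False)


def run_cohort_pipeline(cohort: SpectrumCohort, thresholds: Thresholds | None = None,
                        mass_window: tuple[float, float] | None = None,
                        k: int | None = None, db: ToyCompoundDB | None = None,
                        seed: int = 0, tsne_preset: str = "cohort",
                        perplexity: float | None = None,
                        out_dir: str | Path | None = None) -> CohortResult:
    """REIMS cohort workflow.

    Order of operations: detect and drop inactive (forceps-off) acquisition
    segments -> restrict to the analysis mass window -> l2 normalize ->
    peak-pick the mean spectrum and keep the top-N peaks -> reduce to peak
    features -> 3-D t-SNE -> k-means on the embedding (k defaults to the
    number of group labels, Euclidean, 10 replicates) -> cluster/group
    purity -> pairwise volcano for all group pairs -> optional annotation
    and pathway ranking of each pair's discriminating ions.
    """
    t0 = time.perf_counter()
    thresholds = thresholds or Thresholds()
    active = detect_active_spectra(cohort, seed=seed)
    logger.info("active spectra: %d / %d", int(active.sum()), cohort.n_spectra)
    work = cohort.subset(active)
    if mass_window is not None:
        work = work.restrict(mass_window)
    work = l2_normalize(work)

    peaks = top_n(gradient_peak_pick(mean_spectrum(work)), thresholds.top_n_peaks)
    _, features = cohort_features(work, peaks)

    groups = sorted({m.group_label for m in work.meta})
    if k is None:
        k = len(groups)
    kwargs = {} if perplexity is None else {"perplexity": perplexity}
    if kwargs:
        from .segment import TSNE_PRESETS
        preset = dict(TSNE_PRESETS[tsne_preset], **kwargs)
        embedding = tsne_embed(features, seed=seed, **preset)
    else:
        embedding = tsne_embed(features, preset=tsne_preset, seed=seed)
    labels, _ = kmeans_cluster(embedding, k, metric="euclidean",
                               n_replicates=10, seed=seed)
    purity = purity_table(labels, work.meta)

    group_labels = np.array([m.group_label for m in work.meta])
    volcano: dict[tuple[str, str], DifferentialTable] = {}
    rankings: dict[tuple[str, str], pd.DataFrame] = {}
    for a, b in itertools.combinations(groups, 2):
        table = pairwise_volcano(features, group_labels, a, b,
                                 thresholds=thresholds, mz=peaks.peak_mz,
                                 mode="cohort")
        volcano[(a, b)] = table
        if db is not None:
            hits = match_ions(table.discriminating["mz"].to_numpy(), db,
                              ppm_tol=thresholds.ppm_tol)
            rankings[(a, b)] = rank_pathways(hits)
    result = CohortResult(embedding=embedding, labels=labels, active_mask=active,
                          peaks=peaks, features=features, meta=list(work.meta),
                          purity=purity, volcano=volcano,
                          pathway_rankings=rankings)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.write(out)
        write_manifest(out, dict(mode="cohort", seed=seed, k=k,
                                 mass_window=mass_window,
                                 thresholds=thresholds.__dict__,
                                 tsne_preset=tsne_preset))
    logger.info("cohort pipeline done in %.1fs", time.perf_counter() - t0)
    return result


@dataclass
class MSIResult:
    segmentation: SegmentationResult
    peaks: PeakList
    datacube: MSIDataCube                  # peak space
    volcano: DifferentialTable | None = None
    embedding: np.ndarray | None = None    # tissue pixels x 3

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        seg = self.segmentation
        df = pd.DataFrame(self.datacube.coordinates, columns=["x", "y"])
        df["cluster"] = seg.labels
        df["background"] = seg.background_mask
        if seg.second_pass is not None:
            df["cluster_pass2"] = seg.second_pass.labels
        df.to_csv(out / "pixel_labels.tsv", sep="\t", index=False)
        np.savetxt(out / "background_mask.txt",
                   self.datacube.label_image(seg.background_mask.astype(int), fill=1),
                   fmt="%d")
        if self.volcano is not None:
            self.volcano.to_tsv(out / "volcano_pixels.tsv")


def run_msi_pipeline(cube_raw: MSIDataCube, thresholds: Thresholds | None = None,
                     k: int = 4, metric: str = "cosine", seed: int = 0,
                     background_mask: np.ndarray | None = None,
                     second_pass_k: int | None = None,
                     compare_labels: np.ndarray | None = None,
                     compare_pair: tuple[str, str] | None = None,
                     embed_tissue: bool = False,
                     out_dir: str | Path | None = None) -> MSIResult:
    """MSI workflow on a raw (profile-mode) datacube.

    Peak-picks the cube mean spectrum, keeps the top-N peaks (4000 by
    default), builds the peak-space datacube, segments pixels by cosine
    k-means (k=4), separates tissue from background (auto by lowest mean
    intensity, or a manual mask), optionally re-clusters the
    background-subtracted pixels with ``second_pass_k``, optionally embeds
    tissue pixels with correlation-metric t-SNE, and optionally runs a
    pixel volcano (RMS normalized, zeros removed, q=0.1) between two
    region-of-interest label sets supplied via ``compare_labels`` /
    ``compare_pair``.
    """
    thresholds = thresholds or Thresholds.msi()
    peaks = top_n(gradient_peak_pick(mean_spectrum(cube_raw)),
                  thresholds.top_n_peaks)
    cube = build_datacube(cube_raw, peaks)
    seg = segment_cube(cube, k=k, metric=metric, seed=seed,
                       background_mask=background_mask,
                       second_pass_k=second_pass_k)
    embedding = None
    if embed_tissue:
        tissue = ~seg.background_mask
        embedding = tsne_embed(cube.intensities[tissue], preset="msi", seed=seed)
    volcano = None
    if compare_labels is not None:
        if compare_pair is None:
            raise ValueError("compare_pair required with compare_labels")
        a, b = compare_pair
        volcano = pairwise_volcano(cube.intensities, np.asarray(compare_labels),
                                   a, b, thresholds=thresholds,
                                   mz=peaks.peak_mz, mode="msi")
    result = MSIResult(segmentation=seg, peaks=peaks, datacube=cube,
                       volcano=volcano, embedding=embedding)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.write(out)
        write_manifest(out, dict(mode="msi", seed=seed, k=k, metric=metric,
                                 second_pass_k=second_pass_k,
                                 thresholds=thresholds.__dict__))
    return result


@dataclass
class ClinicalResult:
    report: ClassifierReport
    embedding: np.ndarray | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.report.to_json(out / "report.json")
        self.report.per_patient_predictions.to_csv(
            out / "per_patient_predictions.tsv", sep="\t", index=False)


def run_clinical_pipeline(X: pd.DataFrame | np.ndarray, meta: list[SampleMeta],
                          batch: np.ndarray | None = None, target_k: int = 50,
                          C: float = 1.0, seed: int = 0,
                          refine_once: bool = False, embed: bool = True,
                          positive_label: str = "1",
                          out_dir: str | Path | None = None) -> ClinicalResult:
    """Clinical workflow: LOPO folds -> per-fold refine + fit + predict ->
    patient aggregation -> report -> clinical-preset t-SNE of the refined
    feature space."""
    report = lopo_cross_validate(X, meta, batch=batch, target_k=target_k, C=C,
                                 seed=seed, refine_once=refine_once,
                                 positive_label=positive_label)
    embedding = None
    if embed:
        names = (list(X.columns) if isinstance(X, pd.DataFrame)
                 else [f"f{j}" for j in range(np.asarray(X).shape[1])])
        sel = [names.index(f) for f in report.selected_features]
        embedding = visualize_refined(np.asarray(X, dtype=float)[:, sel], seed=seed)
    result = ClinicalResult(report=report, embedding=embedding)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.write(out)
        write_manifest(out, dict(mode="clinical", seed=seed, target_k=target_k,
                                 C=C, refine_once=refine_once))
    return result
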