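"""Unsupervised structure discovery.

Burn-region (active-acquisition) detection by cosine k-means with k=2,
t-SNE embedding to three dimensions under named presets, k-means clustering
with cosine or Euclidean dissimilarity and best-of-N replicates, elbow-method
selection of k, MSI cube segmentation with tissue/background handling, and
cluster-by-group purity tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .spectral_io import SampleMeta, SpectrumCohort, MSIDataCube

__all__ = [
    "SegmentationResult",
    "TSNE_PRESETS",
    "detect_active_spectra",
    "tsne_embed",
    "kmeans_cluster",
    "elbow_select_k",
    "segment_cube",
    "purity_table",
]


class DegenerateClusteringError(ValueError):
    """Raised when the data admit no meaningful clustering (all rows equal)."""


@dataclass
class SegmentationResult:
    """Output of an embedding and/or clustering stage."""

    labels: np.ndarray
    k: int
    metric: str
    seed: int
    embedding: np.ndarray | None = None          # n x 3 when computed
    wcss_curve: dict[int, float] | None = None   # per candidate k
    background_mask: np.ndarray | None = None    # MSI: True = background pixel
    second_pass: "SegmentationResult | None" = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and self.labels.max() >= self.k:
            raise ValueError("cluster ids must lie in 0..k-1")


# t-SNE presets. The cohort preset maps the source tool's defaults to
# portable values (perplexity 30, exaggeration 4, auto learning rate,
# random init); the clinical preset uses the published hyperparameters
# verbatim. Exaggeration 4 matters: the stronger default exaggeration of
# some implementations fragments clusters and occasionally strands single
# spectra, which degrades downstream k-means on the embedding.
TSNE_PRESETS: dict[str, dict] = {
    "cohort": dict(metric="cosine", perplexity=30.0, learning_rate="auto",
                   init="random", early_exaggeration=4.0),
    "msi": dict(metric="correlation", perplexity=30.0, learning_rate="auto",
                init="random", early_exaggeration=4.0),
    "clinical": dict(metric="euclidean", perplexity=5.0, learning_rate=50.0,
                     init="pca", early_exaggeration=4.0),
}


def detect_active_spectra(cohort: SpectrumCohort, seed: int = 0,
                          n_replicates: int = 10) -> np.ndarray:
    """Boolean mask of active (forceps-on) spectra.

    Clusters the rows by cosine k-means with k=2 and marks the cluster with
    the higher mean total ion current as active.
    """
    X = cohort.matrix
    if X.shape[0] < 2:
        raise ValueError("need at least 2 spectra")
    if np.allclose(X, X[0]):
        raise DegenerateClusteringError("all spectra identical; cannot split k=2")
    labels, _ = kmeans_cluster(X, 2, metric="cosine", n_replicates=n_replicates,
                               seed=seed)
    tic = X.sum(axis=1)
    mean_tic = [tic[labels == c].mean() for c in (0, 1)]
    active_cluster = int(np.argmax(mean_tic))
    return labels == active_cluster


def tsne_embed(matrix: np.ndarray, metric: str = "cosine", dims: int = 3,
               perplexity: float = 30.0, learning_rate: float | str = "auto",
               init: str = "random", early_exaggeration: float = 4.0,
               seed: int = 0, preset: str | None = None) -> np.ndarray:
    """Embed rows into ``dims`` dimensions with t-SNE.

    ``preset`` selects one of :data:`TSNE_PRESETS` ('cohort', 'msi',
    'clinical'), overriding metric/perplexity/learning_rate/init/
    early_exaggeration. Deterministic given seed (exact-gradient
    implementation).
    """
    X = np.asarray(matrix, dtype=float)
    if preset is not None:
        p = TSNE_PRESETS[preset]
        metric, perplexity = p["metric"], p["perplexity"]
        learning_rate, init = p["learning_rate"], p["init"]
        early_exaggeration = p["early_exaggeration"]
    n = X.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} too large for n={n} (need n > 3*perplexity)"
        )
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    tsne = TSNE(n_components=dims, metric=metric, perplexity=perplexity,
                learning_rate=learning_rate, init=init,
                early_exaggeration=early_exaggeration, random_state=seed,
                method="exact")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        return tsne.fit_transform(X)


def _prepare_metric(points: np.ndarray, metric: str) -> np.ndarray:
    """Cosine k-means is k-means on unit-normalized rows (Euclidean centroids)."""
    X = np.asarray(points, dtype=float)
    if metric == "euclidean":
        return X
    if metric == "cosine":
        norms = np.linalg.norm(X, axis=1)
        norms[norms == 0] = 1.0
        return X / norms[:, None]
    raise ValueError(f"unsupported metric {metric!r}")


def _hartigan_polish(X: np.ndarray, labels: np.ndarray, k: int,
                     max_moves: int = 10000) -> np.ndarray:
    """Greedy single-point improvement of a k-means partition.

    Lloyd iterations stop at centroidal-Voronoi fixed points, but the true
    WCSS optimum need not be one: the exact gain of moving point x from
    cluster A (size nA) to B (size nB) is
    nA/(nA-1)*|x-muA|^2 - nB/(nB+1)*|x-muB|^2, with size factors Lloyd
    ignores. Applying the best positive-gain move until none remains
    (Hartigan-style) strictly improves on Lloyd, which matters on small
    instances. Deterministic: ties resolve to the first (point, cluster).
    """
    labels = labels.copy()
    n = X.shape[0]
    for _ in range(max_moves):
        counts = np.bincount(labels, minlength=k).astype(float)
        sums = np.zeros((k, X.shape[1]))
        np.add.at(sums, labels, X)
        means = sums / counts[:, None]
        d2 = (np.einsum("ij,ij->i", X, X)[:, None]
              - 2.0 * X @ means.T
              + np.einsum("ij,ij->i", means, means)[None, :])  # n x k
        np.maximum(d2, 0.0, out=d2)
        own = labels
        removable = counts[own] > 1  # never empty a cluster
        gain_out = np.where(removable,
                            counts[own] / np.maximum(counts[own] - 1, 1)
                            * d2[np.arange(n), own], -np.inf)
        cost_in = counts[None, :] / (counts[None, :] + 1) * d2
        cost_in[np.arange(n), own] = np.inf
        gains = gain_out[:, None] - cost_in
        best = np.unravel_index(np.argmax(gains), gains.shape)
        if gains[best] <= 1e-12:
            break
        labels[best[0]] = best[1]
    return labels


def _wcss(X: np.ndarray, labels: np.ndarray, k: int) -> float:
    total = 0.0
    for c in range(k):
        pts = X[labels == c]
        if len(pts):
            total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def _exact_kmeans(X: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Globally optimal k-means by exhaustive partition enumeration.

    Point 0 is pinned to cluster 0; all k^(n-1) assignments of the rest are
    scored. Only viable for tiny instances, where it subsumes any number of
    replicate restarts.
    """
    import itertools

    n = X.shape[0]
    best_w, best_labels = np.inf, None
    for assign in itertools.product(range(k), repeat=n - 1):
        labels = np.fromiter((0,) + assign, dtype=int, count=n)
        if len(set(assign) | {0}) < k:
            continue  # some cluster empty
        w = _wcss(X, labels, k)
        if w < best_w:
            best_w, best_labels = w, labels
    return best_labels, best_w


def kmeans_cluster(points: np.ndarray, k: int, metric: str = "euclidean",
                   n_replicates: int = 10, seed: int = 0
                   ) -> tuple[np.ndarray, float]:
    """Best-of-``n_replicates`` k-means labelling and its within-cluster SS.

    On tiny instances the replicate search is replaced by exhaustive
    partition enumeration, which returns the exact WCSS optimum (Lloyd's
    fixed points are centroidal-Voronoi partitions and can miss it, since
    the true single-point move gain carries cluster-size factors Lloyd
    ignores). Larger instances use Lloyd iterations with k-means++ starts
    followed by a Hartigan-style single-point polish. Returns
    (labels, wcss). Deterministic given seed. ``metric='cosine'``
    normalizes rows to unit norm first, so wcss is measured in that space.
    """
    X = _prepare_metric(points, metric)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")
    if k == n:
        return np.arange(n), 0.0
    if k ** (n - 1) <= 40000:
        return _exact_kmeans(X, k)
    km = KMeans(n_clusters=k, n_init=n_replicates, random_state=seed)
    labels = km.fit_predict(X)
    if n * k <= 20000:  # polish cost is O(n*k) per move; skip on huge cubes
        labels = _hartigan_polish(X, labels, k)
    return labels, _wcss(X, labels, k)


def elbow_select_k(points: np.ndarray, k_range: range | list[int],
                   metric: str = "euclidean", seed: int = 0,
                   n_replicates: int = 10,
                   return_curve: bool = False):
    """Elbow-method choice of k: maximal second difference of the WCSS curve.

    Only interior candidates can be selected; ties break toward smaller k.
    A non-monotone curve (failed fits) triggers one recompute with more
    replicates.
    """
    ks = sorted(int(k) for k in k_range)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values")

    def curve(reps: int) -> np.ndarray:
        return np.array([kmeans_cluster(points, k, metric, reps, seed)[1]
                         for k in ks])

    wcss = curve(n_replicates)
    if np.any(np.diff(wcss) > 1e-9):
        warnings.warn("non-monotone WCSS curve; recomputing with more replicates")
        wcss = curve(4 * n_replicates)
    d2 = wcss[:-2] - 2.0 * wcss[1:-1] + wcss[2:]
    best = int(np.argmax(np.round(d2, 9)))  # ties -> smaller k via argmax
    k_sel = ks[1 + best]
    if return_curve:
        return k_sel, dict(zip(ks, wcss))
    return k_sel


def segment_cube(cube: MSIDataCube, k: int = 4, metric: str = "cosine",
                 seed: int = 0, n_replicates: int = 10,
                 background_mask: np.ndarray | None = None,
                 second_pass_k: int | None = None) -> SegmentationResult:
    """Spatial segmentation of a peak-space cube by k-means.

    Background handling: a user-supplied per-pixel boolean mask takes
    precedence (manual mode, mirroring labelling against optical images);
    otherwise the cluster with the lowest mean total intensity is flagged
    background (auto mode). With ``second_pass_k``, the background-subtracted
    (tissue-only) pixels are re-clustered with that k; second-pass labels are
    -1 on background pixels.
    """
    X = cube.intensities
    labels, wcss = kmeans_cluster(X, k, metric=metric, n_replicates=n_replicates,
                                  seed=seed)
    if background_mask is not None:
        background_mask = np.asarray(background_mask, dtype=bool).reshape(-1)
        if background_mask.size != cube.n_pixels:
            raise ValueError(
                f"background mask covers {background_mask.size} pixels, "
                f"cube has {cube.n_pixels}"
            )
        bg = background_mask
    else:
        tic = X.sum(axis=1)
        cluster_tic = np.array([tic[labels == c].mean() for c in range(k)])
        bg = labels == int(np.argmin(cluster_tic))
    result = SegmentationResult(labels=labels, k=k, metric=metric, seed=seed,
                                background_mask=bg)
    if second_pass_k is not None:
        tissue = ~bg
        sub_labels, _ = kmeans_cluster(X[tissue], second_pass_k, metric=metric,
                                       n_replicates=n_replicates, seed=seed)
        full = np.full(cube.n_pixels, -1, dtype=int)
        full[tissue] = sub_labels
        result.second_pass = SegmentationResult(
            labels=np.where(full < 0, 0, full), k=second_pass_k, metric=metric,
            seed=seed, background_mask=bg)
        result.second_pass.labels = full  # keep -1 sentinel for background
    return result


def purity_table(labels: np.ndarray, meta: list[SampleMeta] | np.ndarray
                 ) -> pd.DataFrame:
    """Cluster x group cross-tabulation with within-group percentages.

    Returns a tidy frame (cluster, group_label, count, pct_of_group); for
    every group the percentages over clusters sum to 100.
    """
    labels = np.asarray(labels)
    groups = (np.asarray(meta) if not isinstance(meta[0], SampleMeta)
              else np.array([m.group_label for m in meta]))
    df = pd.DataFrame({"cluster": labels, "group_label": groups})
    counts = (df.groupby(["cluster", "group_label"], sort=True)
              .size().rename("count").reset_index())
    totals = counts.groupby("group_label")["count"].transform("sum")
    counts["pct_of_group"] = 100.0 * counts["count"] / totals
    return counts
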