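"""Burn detection, embedding, k-means (with exhaustive oracle), elbow, purity."""

import itertools

import numpy as np
import pytest

from msgp.segment import (
    DegenerateClusteringError,
    detect_active_spectra,
    elbow_select_k,
    kmeans_cluster,
    purity_table,
    segment_cube,
    tsne_embed,
)
from msgp.spectral_io import SampleMeta, SpectrumCohort


def exhaustive_two_partition_wcss(points):
    """Minimum within-cluster sum of squares over all 2-partitions."""
    n = len(points)
    best = np.inf
    for assign in itertools.product([0, 1], repeat=n - 1):
        labels = np.array((0,) + assign)
        if labels.max() == 0:
            continue
        wcss = 0.0
        for c in (0, 1):
            pts = points[labels == c]
            if len(pts):
                wcss += ((pts - pts.mean(axis=0)) ** 2).sum()
        best = min(best, wcss)
    return best


class TestDetectActive:
    def test_planted_activity_recovered(self, small_cohort):
        cohort, truth = small_cohort
        mask = detect_active_spectra(cohort, seed=0)
        np.testing.assert_array_equal(mask, truth.active_mask)

    def test_two_tier_all_active_brighter_tier_wins(self):
        # two intensity tiers of the same shape family: the brighter tier is
        # marked active (documented consequence of the higher-mean-TIC rule)
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 2, 30)
        alt = rng.uniform(1, 2, 30)
        bright = np.vstack([10 * base + rng.uniform(0, 0.1, 30) for _ in range(8)])
        dim = np.vstack([0.5 * alt + rng.uniform(0, 0.1, 30) for _ in range(8)])
        mat = np.vstack([bright, dim])
        cohort = SpectrumCohort(np.arange(30.0), mat,
                                [SampleMeta(sample_id=f"s{i}") for i in range(16)])
        mask = detect_active_spectra(cohort, seed=1)
        np.testing.assert_array_equal(mask, np.arange(16) < 8)

    def test_deterministic(self, small_cohort):
        cohort, _ = small_cohort
        a = detect_active_spectra(cohort, seed=3)
        b = detect_active_spectra(cohort, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_identical_spectra_rejected(self):
        mat = np.ones((5, 10))
        cohort = SpectrumCohort(np.arange(10.0), mat,
                                [SampleMeta(sample_id=f"s{i}") for i in range(5)])
        with pytest.raises(DegenerateClusteringError):
            detect_active_spectra(cohort)


class TestTsneEmbed:
    def test_shape_contract(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 10))
        emb = tsne_embed(X, perplexity=5, seed=0)
        assert emb.shape == (40, 3)

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 8))
        a = tsne_embed(X, perplexity=5, seed=7)
        b = tsne_embed(X, perplexity=5, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_classes_separate_in_embedding(self):
        rng = np.random.default_rng(2)
        a = np.abs(rng.normal(5, 0.1, size=(20, 12)))
        b = np.abs(rng.normal(1, 0.1, size=(20, 12)))
        b[:, :6] *= 5  # distinct direction
        X = np.vstack([a, b])
        emb = tsne_embed(X, metric="cosine", perplexity=8, seed=0)
        labels = np.repeat([0, 1], 20)
        intra = [np.linalg.norm(p - q) for c in (0, 1)
                 for p, q in itertools.combinations(emb[labels == c], 2)]
        inter = [np.linalg.norm(p - q) for p in emb[labels == 0]
                 for q in emb[labels == 1]]
        assert np.mean(inter) > np.mean(intra)

    def test_perplexity_guard(self):
        X = np.random.default_rng(3).normal(size=(10, 4))
        with pytest.raises(ValueError, match="perplexity"):
            tsne_embed(X, perplexity=30, seed=0)

    def test_presets_exist_and_run(self):
        rng = np.random.default_rng(4)
        X = np.abs(rng.normal(1, 0.3, size=(30, 10)))
        for preset in ("cohort", "msi", "clinical"):
            if preset in ("cohort", "msi"):
                with pytest.raises(ValueError):  # n too small for perplexity 30
                    tsne_embed(X, preset=preset, seed=0)
            else:
                emb = tsne_embed(X, preset=preset, seed=0)
                assert emb.shape == (30, 3)


class TestKmeans:
    def test_separable_blobs_exact(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (15, 2)), rng.normal(8, 0.1, (15, 2))])
        labels, _ = kmeans_cluster(X, 2, seed=0)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(np.repeat([0, 1], 15), labels) == 1.0

    def test_k_equals_n(self):
        X = np.random.default_rng(1).normal(size=(6, 3))
        labels, wcss = kmeans_cluster(X, 6, seed=0)
        assert sorted(labels) == list(range(6))
        assert wcss == 0.0

    def test_k_exceeds_n(self):
        with pytest.raises(ValueError):
            kmeans_cluster(np.ones((3, 2)), 4)

    def test_matches_exhaustive_partition_optimum(self):
        # small instances: returned wcss equals the exhaustive 2-partition minimum
        rng = np.random.default_rng(42)
        for trial in range(60):
            n = int(rng.integers(4, 9))
            X = rng.uniform(-1, 1, size=(n, 2))
            _, wcss = kmeans_cluster(X, 2, n_replicates=30, seed=trial)
            best = exhaustive_two_partition_wcss(X)
            assert wcss == pytest.approx(best, rel=1e-9, abs=1e-12)

    def test_labels_stable_under_row_reorder(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.2, (10, 3)), rng.normal(5, 0.2, (10, 3))])
        labels, _ = kmeans_cluster(X, 2, seed=0)
        perm = rng.permutation(20)
        labels_p, _ = kmeans_cluster(X[perm], 2, seed=0)
        # same partition up to label permutation
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(labels[perm], labels_p) == 1.0


class TestElbow:
    def test_hand_curve_oracle(self, monkeypatch):
        # wcss (100, 40, 35, 33) over k=1..4: second differences peak at k=2
        curve = {1: 100.0, 2: 40.0, 3: 35.0, 4: 33.0}
        import msgp.segment as seg

        monkeypatch.setattr(seg, "kmeans_cluster",
                            lambda pts, k, *a, **kw: (None, curve[k]))
        assert seg.elbow_select_k(np.zeros((10, 2)), range(1, 5)) == 2

    def test_linear_curve_picks_smallest_interior_k(self, monkeypatch):
        import msgp.segment as seg

        monkeypatch.setattr(seg, "kmeans_cluster",
                            lambda pts, k, *a, **kw: (None, 100.0 - 10.0 * k))
        assert seg.elbow_select_k(np.zeros((10, 2)), range(1, 6)) == 2

    def test_three_blob_recovery(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = np.vstack([rng.normal(c, 0.3, (25, 2))
                           for c in ((0, 0), (6, 0), (0, 6))])
            if elbow_select_k(X, range(1, 9), seed=seed) == 3:
                hits += 1
        assert hits >= 9

    def test_needs_three_candidates(self):
        with pytest.raises(ValueError):
            elbow_select_k(np.zeros((10, 2)), [2, 3])


class TestSegmentCube:
    def test_auto_background_matches_planted(self, small_cube):
        from msgp.peaks import build_datacube, gradient_peak_pick, mean_spectrum, top_n

        cube, truth = small_cube
        peaks = top_n(gradient_peak_pick(mean_spectrum(cube)), 4000)
        dc = build_datacube(cube, peaks)
        seg = segment_cube(dc, k=4, seed=0)
        np.testing.assert_array_equal(seg.background_mask,
                                      truth.compartment_labels == 0)

    def test_manual_mask_excludes_pixels_from_second_pass(self, small_cube):
        from msgp.peaks import build_datacube, gradient_peak_pick, mean_spectrum, top_n

        cube, truth = small_cube
        peaks = top_n(gradient_peak_pick(mean_spectrum(cube)), 4000)
        dc = build_datacube(cube, peaks)
        manual = truth.compartment_labels == 0
        seg = segment_cube(dc, k=4, seed=0, background_mask=manual,
                           second_pass_k=3)
        np.testing.assert_array_equal(seg.background_mask, manual)
        assert np.all(seg.second_pass.labels[manual] == -1)
        assert np.all(seg.second_pass.labels[~manual] >= 0)

    def test_mask_shape_checked(self, small_cube):
        from msgp.peaks import build_datacube, gradient_peak_pick, mean_spectrum, top_n

        cube, _ = small_cube
        peaks = top_n(gradient_peak_pick(mean_spectrum(cube)), 100)
        dc = build_datacube(cube, peaks)
        with pytest.raises(ValueError, match="mask"):
            segment_cube(dc, k=4, background_mask=np.zeros(5, dtype=bool))

    def test_noiseless_four_compartments_exact(self):
        from msgp.synthetic import CubeSpec, generate_cube
        from sklearn.metrics import adjusted_rand_score

        spec = CubeSpec.with_marker_ions(width=16, height=16, effect=5.0,
                                         n_ions=60, mz_range=(100.0, 160.0),
                                         noise_sigma=0.0, seed=3)
        cube, truth = generate_cube(spec)
        labels, _ = kmeans_cluster(cube.intensities, 4, metric="cosine", seed=0)
        assert adjusted_rand_score(truth.compartment_labels, labels) == 1.0


class TestPurityTable:
    def test_single_cluster_all_hundred(self):
        t = purity_table(np.zeros(6, dtype=int),
                         np.array(["a", "a", "b", "b", "b", "c"]))
        assert (t["pct_of_group"] == 100.0).all()

    def test_constructed_percentage(self):
        # 30 of 39 male spectra in cluster 1 -> 76.9%
        labels = np.array([1] * 30 + [0] * 9 + [0] * 5)
        groups = np.array(["male"] * 39 + ["female"] * 5)
        t = purity_table(labels, groups)
        row = t[(t["cluster"] == 1) & (t["group_label"] == "male")]
        assert row["pct_of_group"].iloc[0] == pytest.approx(76.923, abs=0.001)

    def test_percentages_sum_to_hundred(self, small_cohort):
        cohort, truth = small_cohort
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, cohort.n_spectra)
        t = purity_table(labels, cohort.meta)
        sums = t.groupby("group_label")["pct_of_group"].sum()
        np.testing.assert_allclose(sums, 100.0, atol=1e-9)
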