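"""LOPO folding, SVM behaviour, feature refinement and patient-level metrics."""

import numpy as np
import pandas as pd
import pytest

from msgp.classify import (
    DegenerateFoldError,
    evaluate,
    feature_elimination_order,
    fit_predict_svm,
    lopo_cross_validate,
    lopo_folds,
    refine_features,
    visualize_refined,
)
from msgp.spectral_io import SampleMeta


def _meta(n_patients, replicates, labels=None):
    out = []
    for p in range(n_patients):
        lab = str(labels[p]) if labels is not None else str(p % 2)
        for r in range(replicates):
            out.append(SampleMeta(sample_id=f"P{p}_r{r}", group_label=lab,
                                  patient_id=f"P{p}", replicate_index=r))
    return out


class TestLopoFolds:
    def test_one_fold_per_patient(self):
        meta = _meta(24, 3)
        assert len(lopo_folds(meta)) == 24

    def test_replicates_held_out_together(self):
        meta = _meta(6, 3)
        for train, test in lopo_folds(meta):
            test_patients = {meta[i].patient_id for i in test}
            assert len(test_patients) == 1
            patient = test_patients.pop()
            assert len(test) == 3
            assert all(meta[i].patient_id != patient for i in train)

    def test_test_sets_partition_cohort(self):
        meta = _meta(5, 2)
        folds = lopo_folds(meta)
        all_test = sorted(i for _, test in folds for i in test)
        assert all_test == list(range(len(meta)))

    def test_missing_patient_id(self):
        meta = [SampleMeta(sample_id="a", group_label="0"),
                SampleMeta(sample_id="b", group_label="1")]
        with pytest.raises(ValueError, match="patient_id"):
            lopo_folds(meta)

    def test_needs_two_patients_per_class(self):
        meta = _meta(4, 1, labels=[0, 0, 0, 1])
        with pytest.raises(ValueError, match="fewer than 2"):
            lopo_folds(meta)


class TestFitPredictSvm:
    def test_separable_2d(self):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [5.0, 5.0], [5.1, 5.0]])
        y = np.array(["0", "0", "1", "1"])
        pred = fit_predict_svm(X, y, X)
        np.testing.assert_array_equal(pred, y)

    def test_equidistant_tie_goes_to_lower_label(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array(["0", "1"])
        pred = fit_predict_svm(X, y, np.array([[0.0]]))
        assert pred[0] == "0"

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateFoldError):
            fit_predict_svm(np.ones((3, 2)), np.array(["a"] * 3), np.ones((1, 2)))

    def test_1d_margin_matches_brute_force(self):
        # 4-point 1-D instance: the max-margin boundary is the midpoint of
        # the innermost pair; brute-force over thresholds agrees
        X = np.array([[0.0], [1.0], [3.0], [4.0]])
        y = np.array(["0", "0", "1", "1"])
        boundary = 2.0  # midpoint of 1 and 3
        tests = np.array([[1.9], [2.1]])
        pred = fit_predict_svm(X, y, tests)
        np.testing.assert_array_equal(pred, ["0", "1"])
        # brute force: best threshold maximizes min distance to both classes
        grid = np.linspace(1.0, 3.0, 2001)
        margins = [min(abs(g - 1.0), abs(g - 3.0)) for g in grid]
        assert grid[int(np.argmax(margins))] == pytest.approx(boundary, abs=1e-3)


class TestRefineFeatures:
    def test_identity_when_target_equals_n(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 10))
        y = np.array(["0", "1"] * 10)
        np.testing.assert_array_equal(refine_features(X, y, target_k=10),
                                      np.arange(10))

    def test_warns_when_target_exceeds_n(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        y = np.array(["0", "1"] * 10)
        with pytest.warns(UserWarning):
            sel = refine_features(X, y, target_k=9)
        np.testing.assert_array_equal(sel, np.arange(5))

    def test_nested_across_target_k(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 40))
        X[:15, :5] += 2.0
        y = np.array(["1"] * 15 + ["0"] * 15)
        s10 = set(refine_features(X, y, target_k=10, seed=3))
        s20 = set(refine_features(X, y, target_k=20, seed=3))
        assert s10 <= s20

    def test_informative_features_recovered(self):
        # 20 planted informative features, selection cut exactly at 20:
        # the refinement keeps nearly all of them (median over cohorts)
        from msgp.synthetic import generate_clinical_cohort

        recovered = []
        for seed in range(5):
            X, meta, truth = generate_clinical_cohort(seed=seed)
            y = np.array([m.group_label for m in meta])
            batch = np.array([truth.patient_batch[m.patient_id] for m in meta])
            pids = np.array([m.patient_id for m in meta])
            sel = set(refine_features(np.asarray(X), y, batch=batch,
                                      target_k=20, patient_ids=pids, seed=seed))
            recovered.append(len(sel & set(truth.informative)))
        assert np.median(recovered) >= 18

    def test_batch_features_rejected(self):
        # batch-only signal with the covariate supplied: top selections are
        # batch-free in nearly all seeds
        from msgp.synthetic import generate_clinical_cohort

        clean = 0
        n_seeds = 10
        for seed in range(n_seeds):
            X, meta, truth = generate_clinical_cohort(
                n_patients=16, replicates=2, n_features=60, n_informative=0,
                n_batch=20, effect=2.0, seed=seed)
            y = np.array([m.group_label for m in meta])
            batch = np.array([truth.patient_batch[m.patient_id] for m in meta])
            pids = np.array([m.patient_id for m in meta])
            sel = set(refine_features(np.asarray(X), y, batch=batch,
                                      target_k=10, patient_ids=pids, seed=seed))
            if not (sel & set(truth.batch_confounded)):
                clean += 1
        assert clean >= 0.9 * n_seeds

    def test_elimination_order_is_permutation(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(24, 15))
        y = np.array(["0", "1"] * 12)
        order = feature_elimination_order(X, y, seed=0)
        assert sorted(order) == list(range(15))


class TestEvaluate:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "patient_id", "true",
                                           "predicted"])

    def test_perfect_predictions(self):
        rows = [(f"P{p}_r{r}", f"P{p}", str(p % 2), str(p % 2))
                for p in range(6) for r in range(2)]
        rep = evaluate(self._frame(rows))
        assert (rep.tpr, rep.tnr, rep.fpr, rep.balanced_accuracy) == (1, 1, 0, 1)

    def test_formula_oracle(self):
        # TP=3 FN=1 TN=4 FP=0 -> tpr .75, tnr 1, fpr 0, BA .875
        rows = []
        for p in range(4):  # positives, one misclassified
            pred = "0" if p == 0 else "1"
            rows.append((f"P{p}", f"P{p}", "1", pred))
        for p in range(4, 8):
            rows.append((f"P{p}", f"P{p}", "0", "0"))
        rep = evaluate(self._frame(rows))
        assert rep.tp == 3 and rep.fn == 1 and rep.tn == 4 and rep.fp == 0
        assert rep.tpr == 0.75 and rep.tnr == 1.0
        assert rep.fpr == 0.0 and rep.balanced_accuracy == 0.875

    def test_majority_vote_tie_goes_positive(self):
        rows = [("P0_r0", "P0", "0", "0"), ("P0_r1", "P0", "0", "1"),
                ("P1_r0", "P1", "0", "0"), ("P1_r1", "P1", "0", "0")]
        rep = evaluate(self._frame(rows))
        assert rep.per_patient_predictions.set_index("patient_id") \
            .loc["P0", "predicted_label"] == "1"

    def test_invariants_hold_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            rows = [(f"P{p}", f"P{p}", str(rng.integers(0, 2)),
                     str(rng.integers(0, 2))) for p in range(8)]
            rep = evaluate(self._frame(rows))
            assert rep.fpr == 1.0 - rep.tnr
            assert rep.balanced_accuracy == (rep.tpr + rep.tnr) / 2.0
            assert rep.tp + rep.fn == sum(1 for r in rows if r[2] == "1")
            assert rep.tn + rep.fp == sum(1 for r in rows if r[2] == "0")


class TestLopoCrossValidate:
    def test_separable_cohort_high_balanced_accuracy(self, clinical_cohort):
        X, meta, truth = clinical_cohort
        batch = np.array([truth.patient_batch[m.patient_id] for m in meta])
        rep = lopo_cross_validate(X, meta, batch=batch, target_k=50, seed=0)
        assert rep.balanced_accuracy >= 0.9
        assert len(rep.selected_features) == 50

    def test_permuted_labels_near_chance(self, clinical_cohort):
        X, meta, truth = clinical_cohort
        rng = np.random.default_rng(0)
        patients = sorted({m.patient_id for m in meta})
        perm_labels = dict(zip(patients,
                               rng.permutation([truth.patient_labels[p]
                                                for p in patients])))
        meta_perm = [SampleMeta(sample_id=m.sample_id,
                                group_label=str(perm_labels[m.patient_id]),
                                patient_id=m.patient_id,
                                replicate_index=m.replicate_index)
                     for m in meta]
        rep = lopo_cross_validate(X, meta_perm, target_k=50, seed=0)
        assert 0.2 <= rep.balanced_accuracy <= 0.8  # single-seed sanity band

    def test_refine_once_mode_runs(self, clinical_cohort):
        X, meta, _ = clinical_cohort
        rep = lopo_cross_validate(X, meta, target_k=50, seed=0, refine_once=True)
        assert rep.balanced_accuracy >= 0.9


class TestVisualizeRefined:
    def test_embedding_shape_and_determinism(self, clinical_cohort):
        X, meta, truth = clinical_cohort
        sub = np.asarray(X)[:, truth.informative]
        a = visualize_refined(sub, seed=0)
        b = visualize_refined(sub, seed=0)
        assert a.shape == (len(meta), 3)
        np.testing.assert_array_equal(a, b)

    def test_needs_three_features(self):
        with pytest.raises(ValueError):
            visualize_refined(np.ones((30, 2)))
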