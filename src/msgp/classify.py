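"""Replicate-aware SVM classification with leave-one-patient-out CV.

The clinical workflow: fold the cohort so that every patient's technical
replicates are held out together; inside each training fold, refine the
feature set by backward elimination on linear-SVM weights (optionally
rejecting features more associated with a batch covariate than with the
label); fit a class-balanced linear SVM; aggregate per-spectrum predictions
to a patient call by majority vote; report TPR, TNR, FPR and balanced
accuracy at the patient level.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .spectral_io import SampleMeta

__all__ = [
    "ClassifierReport",
    "lopo_folds",
    "refine_features",
    "feature_elimination_order",
    "fit_predict_svm",
    "evaluate",
    "visualize_refined",
    "lopo_cross_validate",
]


class DegenerateFoldError(ValueError):
    """Raised when a training fold contains a single class."""


@dataclass
class ClassifierReport:
    """Patient-level evaluation of a replicate-aware classifier.

    Invariants held exactly: TP+FN = positive patients, TN+FP = negative
    patients, fpr = 1 - tnr, balanced_accuracy = (tpr + tnr) / 2.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    tpr: float
    tnr: float
    fpr: float
    balanced_accuracy: float
    per_patient_predictions: pd.DataFrame  # patient_id, true_label, predicted_label
    per_spectrum_predictions: pd.DataFrame  # sample_id, patient_id, true, predicted
    selected_features: list[str] = field(default_factory=list)
    per_fold_features: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.fpr == 1.0 - self.tnr
        assert self.balanced_accuracy == (self.tpr + self.tnr) / 2.0

    def to_json(self, path=None) -> str:
        payload = {
            "confusion": {"TP": self.tp, "FN": self.fn, "TN": self.tn, "FP": self.fp},
            "tpr": self.tpr, "tnr": self.tnr, "fpr": self.fpr,
            "balanced_accuracy": self.balanced_accuracy,
            "selected_features": list(self.selected_features),
            "per_patient": self.per_patient_predictions.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def lopo_folds(meta: list[SampleMeta]) -> list[tuple[np.ndarray, np.ndarray]]:
    """One (train indices, test indices) fold per patient.

    All of a patient's technical replicates land in the same test fold; the
    test sets partition the cohort.
    """
    for m in meta:
        if not m.patient_id:
            raise ValueError(f"spectrum {m.sample_id!r} has no patient_id")
    patients = sorted({m.patient_id for m in meta})
    by_class: dict[str, set[str]] = {}
    for m in meta:
        by_class.setdefault(m.group_label, set()).add(m.patient_id)
    for cls, pats in by_class.items():
        if len(pats) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 patients")
    idx_by_patient = {p: np.array([i for i, m in enumerate(meta)
                                   if m.patient_id == p]) for p in patients}
    folds = []
    for p in patients:
        test = idx_by_patient[p]
        train = np.array([i for i, m in enumerate(meta) if m.patient_id != p])
        folds.append((train, test))
    return folds


def _batch_filter(X: np.ndarray, y: np.ndarray, batch: np.ndarray) -> np.ndarray:
    """Features whose one-way F statistic vs batch exceeds that vs label.

    Returns a boolean mask of features to *reject* (more batch- than
    label-associated).
    """
    def f_stats(groups: np.ndarray) -> np.ndarray:
        vals = np.unique(groups)
        with np.errstate(divide="ignore", invalid="ignore"):
            f, _ = stats.f_oneway(*[X[groups == v] for v in vals])
        return np.nan_to_num(f, nan=0.0)

    return f_stats(batch) > f_stats(y)


def _collapse_replicates(X: np.ndarray, y: np.ndarray,
                         batch: np.ndarray | None,
                         patient_ids: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Average technical replicates to one row per patient."""
    patients = sorted(set(patient_ids))
    Xc = np.vstack([X[patient_ids == p].mean(axis=0) for p in patients])
    yc = np.array([y[patient_ids == p][0] for p in patients])
    bc = (None if batch is None
          else np.array([np.asarray(batch)[patient_ids == p][0]
                         for p in patients]))
    return Xc, yc, bc


def feature_elimination_order(X: np.ndarray, y: np.ndarray,
                              batch: np.ndarray | None = None,
                              patient_ids: np.ndarray | None = None,
                              C: float = 1.0, step: float = 0.2,
                              inner_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Full backward-elimination order, most important feature first.

    Repeatedly fit a linear SVM on the surviving features over inner
    stratified CV folds and drop the ``step`` fraction with smallest mean
    |weight|. Batch-rejected features (if a batch covariate is supplied) are
    eliminated first, so any top-k slice of the order is batch-clean when
    possible. With ``patient_ids``, technical replicates are averaged to one
    row per patient before ranking (replicate-aware: replicate noise cancels
    and no patient is over-weighted). Computing one order and slicing it
    guarantees nested selections across target sizes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if patient_ids is not None:
        X, y, batch = _collapse_replicates(X, y, batch,
                                           np.asarray(patient_ids))
    n_feat = X.shape[1]
    eliminated: list[int] = []  # worst first
    surviving = np.arange(n_feat)

    if batch is not None:
        reject = _batch_filter(X, y, np.asarray(batch))
        rejected_idx = surviving[reject]
        # order rejected features among themselves by label association (worst first)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_label, _ = stats.f_oneway(*[X[y == v] for v in np.unique(y)])
        f_label = np.nan_to_num(f_label, nan=0.0)
        eliminated.extend(rejected_idx[np.argsort(f_label[rejected_idx],
                                                  kind="stable")].tolist())
        surviving = surviving[~reject]

    rng_seed = seed % (2 ** 31 - 1)
    while surviving.size > 1:
        n_splits = min(inner_folds, *(np.bincount(pd.factorize(y)[0])))
        if n_splits >= 2:
            cv = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                 random_state=rng_seed)
            splits = [tr for tr, _ in cv.split(X[:, surviving], y)]
        else:
            splits = [np.arange(X.shape[0])]
        weights = np.zeros(surviving.size)
        for tr in splits:
            if len(np.unique(y[tr])) < 2:
                continue
            clf = SVC(kernel="linear", C=C, class_weight="balanced")
            clf.fit(X[np.ix_(tr, surviving)], y[tr])
            weights += np.abs(clf.coef_).sum(axis=0)
        weights /= len(splits)
        n_drop = max(1, int(np.ceil(step * surviving.size)))
        n_drop = min(n_drop, surviving.size - 1)
        drop_local = np.argsort(weights, kind="stable")[:n_drop]
        eliminated.extend(surviving[np.sort(drop_local)].tolist())
        surviving = np.delete(surviving, drop_local)
    eliminated.extend(surviving.tolist())
    return np.asarray(eliminated[::-1])  # best first


def refine_features(train_matrix: np.ndarray, train_labels: np.ndarray,
                    batch: np.ndarray | None = None, target_k: int = 50,
                    patient_ids: np.ndarray | None = None,
                    C: float = 1.0, step: float = 0.2, inner_folds: int = 5,
                    seed: int = 0) -> np.ndarray:
    """Indices of the ``target_k`` features kept by backward elimination.

    Deterministic given seed; selections are nested across target_k (the
    set at k is a subset of the set at any k' > k).
    """
    n_feat = np.asarray(train_matrix).shape[1]
    if target_k >= n_feat:
        if target_k > n_feat:
            warnings.warn(f"target_k={target_k} >= n features={n_feat}; keeping all")
        return np.arange(n_feat)
    order = feature_elimination_order(train_matrix, train_labels, batch=batch,
                                      patient_ids=patient_ids, C=C, step=step,
                                      inner_folds=inner_folds, seed=seed)
    return np.sort(order[:target_k])


def fit_predict_svm(train_matrix: np.ndarray, train_labels: np.ndarray,
                    test_matrix: np.ndarray, C: float = 1.0,
                    seed: int = 0) -> np.ndarray:
    """Linear-kernel SVM with class-balanced weights; predict test labels.

    A test point exactly on the decision boundary is assigned the class
    with the lower label id (deterministic tie-break).
    """
    y = np.asarray(train_labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateFoldError("training fold contains a single class")
    clf = SVC(kernel="linear", C=C, class_weight="balanced", random_state=seed)
    clf.fit(np.asarray(train_matrix, dtype=float), y)
    d = clf.decision_function(np.asarray(test_matrix, dtype=float))
    # decision_function > 0 -> clf.classes_[1]; ties (==0) -> lower label id
    return np.where(d > 0, clf.classes_[1], clf.classes_[0])


def evaluate(per_spectrum_predictions: pd.DataFrame,
             meta: list[SampleMeta] | None = None,
             positive_label: str = "1") -> ClassifierReport:
    """Aggregate spectrum predictions to patient calls and score them.

    ``per_spectrum_predictions`` needs columns sample_id, patient_id, true,
    predicted. Patient call = majority vote over that patient's replicate
    spectra, ties resolved to the positive class. Metrics are patient-level.
    """
    df = per_spectrum_predictions
    patient_rows = []
    for patient, grp in df.groupby("patient_id", sort=True):
        counts = grp["predicted"].value_counts()
        top = counts[counts == counts.max()].index.tolist()
        call = positive_label if positive_label in top else sorted(top)[0]
        truth = grp["true"].iloc[0]
        patient_rows.append({"patient_id": patient, "true_label": truth,
                             "predicted_label": call})
    per_patient = pd.DataFrame(patient_rows)
    t = per_patient["true_label"].astype(str)
    p = per_patient["predicted_label"].astype(str)
    pos = positive_label
    tp = int(((t == pos) & (p == pos)).sum())
    fn = int(((t == pos) & (p != pos)).sum())
    tn = int(((t != pos) & (p != pos)).sum())
    fp = int(((t != pos) & (p == pos)).sum())
    tpr = tp / (tp + fn) if (tp + fn) else 0.0
    tnr = tn / (tn + fp) if (tn + fp) else 0.0
    return ClassifierReport(
        tp=tp, fn=fn, tn=tn, fp=fp, tpr=tpr, tnr=tnr, fpr=1.0 - tnr,
        balanced_accuracy=(tpr + tnr) / 2.0,
        per_patient_predictions=per_patient,
        per_spectrum_predictions=df.reset_index(drop=True),
    )


def visualize_refined(feature_matrix: np.ndarray, seed: int = 0) -> np.ndarray:
    """3-D t-SNE of the refined feature space under the clinical preset."""
    from .segment import tsne_embed

    X = np.asarray(feature_matrix, dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 selected features to embed")
    return tsne_embed(X, preset="clinical", seed=seed)


def lopo_cross_validate(X: np.ndarray | pd.DataFrame, meta: list[SampleMeta],
                        batch: np.ndarray | None = None, target_k: int = 50,
                        C: float = 1.0, seed: int = 0,
                        refine_once: bool = False,
                        positive_label: str = "1") -> ClassifierReport:
    """Leave-one-patient-out evaluation with per-fold feature refinement.

    By default features are refined inside each training fold (never on the
    held-out patient). ``refine_once=True`` reproduces the optimistic
    variant that refines once on the full cohort before cross-validation.
    The report's ``selected_features`` is the refinement of the full cohort
    (used for visualization); per-fold selections are kept alongside.
    """
    feature_names = (list(X.columns) if isinstance(X, pd.DataFrame)
                     else [f"f{j}" for j in range(np.asarray(X).shape[1])])
    Xa = np.asarray(X, dtype=float)
    y = np.array([m.group_label for m in meta])
    folds = lopo_folds(meta)
    # leakage check: no patient in both sides of a fold, test sets partition
    all_test: list[int] = []
    for train, test in folds:
        train_p = {meta[i].patient_id for i in train}
        test_p = {meta[i].patient_id for i in test}
        assert not (train_p & test_p), "patient leakage across a LOPO fold"
        all_test.extend(test.tolist())
    assert sorted(all_test) == list(range(len(meta))), "test folds must partition"

    pids = np.array([m.patient_id for m in meta])
    full_sel = refine_features(Xa, y, batch=batch, target_k=target_k,
                               patient_ids=pids, C=C, seed=seed)
    rows = []
    per_fold: dict[str, list[str]] = {}
    for train, test in folds:
        sel = (full_sel if refine_once else
               refine_features(Xa[train], y[train],
                               batch=None if batch is None else np.asarray(batch)[train],
                               target_k=target_k, patient_ids=pids[train],
                               C=C, seed=seed))
        pred = fit_predict_svm(Xa[np.ix_(train, sel)], y[train],
                               Xa[np.ix_(test, sel)], C=C, seed=seed)
        patient = meta[test[0]].patient_id
        per_fold[patient] = [feature_names[j] for j in sel]
        for i, ph in zip(test, pred):
            rows.append({"sample_id": meta[i].sample_id,
                         "patient_id": meta[i].patient_id,
                         "true": meta[i].group_label, "predicted": ph})
    report = evaluate(pd.DataFrame(rows), positive_label=positive_label)
    report.selected_features = [feature_names[j] for j in full_sel]
    report.per_fold_features = per_fold
    return report
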