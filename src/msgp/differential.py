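"""Pairwise differential-ion analysis with volcano-style filtering.

Cohort mode compares two genotype groups of (l2-normalized) spectra; MSI
mode compares two pixel region-of-interest sets after RMS normalization and
per-feature zero removal. Both compute per-feature log2 fold changes of
group mean intensities, two-sided two-sample t-tests, Benjamini-Hochberg
adjustment across all testable features, and a pass flag under the combined
|FC| / p / q thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .spectral_io import Thresholds

__all__ = [
    "DifferentialTable",
    "bh_adjust",
    "rms_normalize",
    "pairwise_volcano",
]


@dataclass
class DifferentialTable:
    """Per-ion differential results.

    ``testable`` is False for features excluded before BH adjustment
    (zero variance in both groups, or fewer than 2 nonzero values in a
    group after MSI zero removal); their q is NaN and ``passes`` False.
    """

    table: pd.DataFrame  # columns: mz, log2_fc, p_value, q_value, passes, testable
    group_a: str
    group_b: str
    thresholds: Thresholds

    def __post_init__(self) -> None:
        required = {"mz", "log2_fc", "p_value", "q_value", "passes", "testable"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        q = self.table["q_value"].dropna()
        if len(q) and (q.min() < 0 or q.max() > 1):
            raise ValueError("q_value outside [0, 1]")

    @property
    def discriminating(self) -> pd.DataFrame:
        return self.table[self.table["passes"]]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (q-values).

    Sort ascending; q_(i) = min over j >= i of p_(j) * m / j, capped at 1;
    returned in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rms_normalize(pixel_matrix: np.ndarray) -> np.ndarray:
    """Divide each row by its root-mean-square intensity. Idempotent.

    Raises on any all-zero row, naming the pixel index.
    """
    X = np.asarray(pixel_matrix, dtype=float)
    rms = np.sqrt(np.mean(X ** 2, axis=1))
    zero = np.flatnonzero(rms == 0)
    if zero.size:
        raise ValueError(f"cannot RMS-normalize all-zero pixel at row {zero[0]}")
    return X / rms[:, None]


def _ttest(a: np.ndarray, b: np.ndarray, welch: bool) -> float:
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.pvalue)


def pairwise_volcano(matrix: np.ndarray, labels: np.ndarray, group_a: str,
                     group_b: str, thresholds: Thresholds | None = None,
                     mz: np.ndarray | None = None, mode: str = "cohort",
                     welch: bool = False,
                     sample_ids: np.ndarray | None = None) -> DifferentialTable:
    """Volcano comparison of two groups of rows.

    ``matrix`` is items x features (spectra in cohort mode, pixels in MSI
    mode); ``labels`` assigns each row to a group. In MSI mode rows are
    first RMS-normalized and zero intensities are dropped per feature
    before testing (so each feature's test may use fewer pixels). log2 fold
    change is log2(mean_a / mean_b) on the (normalized) intensities.
    Swapping the groups negates log2_fc and preserves p.

    Tests run at the row (spectrum) level by default. Passing ``sample_ids``
    collapses technical replicates to per-sample means first, making the
    biological sample the unit of replication — analytically consequential
    and left to the caller.
    """
    if thresholds is None:
        thresholds = Thresholds() if mode == "cohort" else Thresholds.msi()
    labels = np.asarray(labels)
    X = np.asarray(matrix, dtype=float)
    if sample_ids is not None:
        sample_ids = np.asarray(sample_ids)
        uniq = sorted(set(sample_ids))
        X = np.vstack([X[sample_ids == s].mean(axis=0) for s in uniq])
        labels = np.array([labels[sample_ids == s][0] for s in uniq])
    a_rows = np.flatnonzero(labels == group_a)
    b_rows = np.flatnonzero(labels == group_b)
    if a_rows.size < 2 or b_rows.size < 2:
        raise ValueError(
            f"need >= 2 items per group (got {a_rows.size} for {group_a!r}, "
            f"{b_rows.size} for {group_b!r})"
        )
    if mode == "msi":
        X = rms_normalize(X)
    elif mode != "cohort":
        raise ValueError(f"unknown mode {mode!r}")
    A, B = X[a_rows], X[b_rows]
    n_feat = X.shape[1]
    if mz is None:
        mz = np.arange(n_feat, dtype=float)

    log2_fc = np.full(n_feat, np.nan)
    p_value = np.full(n_feat, np.nan)
    testable = np.zeros(n_feat, dtype=bool)
    for j in range(n_feat):
        a, b = A[:, j], B[:, j]
        if mode == "msi":
            a, b = a[a != 0], b[b != 0]
        if a.size < 2 or b.size < 2:
            continue  # untestable: not enough nonzero observations
        if np.var(a) == 0 and np.var(b) == 0:
            if a.mean() != b.mean():
                # perfectly separated constants: fc defined, p degenerate
                log2_fc[j] = np.log2(a.mean() / b.mean()) if b.mean() > 0 else np.nan
            continue  # p undefined under zero pooled variance
        ma, mb = a.mean(), b.mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            log2_fc[j] = np.log2(ma / mb) if ma > 0 and mb > 0 else (
                np.inf if mb == 0 else -np.inf)
        p_value[j] = _ttest(a, b, welch)
        testable[j] = True

    q_value = np.full(n_feat, np.nan)
    if testable.any():
        q_value[testable] = bh_adjust(p_value[testable])

    fc_cut = np.log2(thresholds.fc_threshold)
    with np.errstate(invalid="ignore"):
        passes = (testable
                  & (np.abs(log2_fc) > fc_cut)
                  & (p_value < thresholds.p_threshold)
                  & (q_value <= thresholds.fdr_q))
    table = pd.DataFrame({
        "mz": np.asarray(mz, dtype=float),
        "log2_fc": log2_fc,
        "p_value": p_value,
        "q_value": q_value,
        "passes": passes,
        "testable": testable,
    })
    return DifferentialTable(table, group_a, group_b, thresholds)
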