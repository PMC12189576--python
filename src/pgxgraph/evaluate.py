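"""Per-medication AUC evaluation, paired model comparison, sample-size binning."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score


def auc(y_true, scores) -> float:
    """ROC AUC with the pairwise-comparison semantics.

    Equals ``P(score_pos > score_neg) + 0.5 * P(tie)`` over all
    positive/negative pairs. Returns NaN when ``y_true`` contains a single
    class, for which the AUC is undefined.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    scores = np.asarray(scores, dtype=np.float64)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have the same shape")
    if y_true.min() == y_true.max():
        return float("nan")
    return float(roc_auc_score(y_true, scores))


@dataclass
class AUCTable:
    """Per-medication AUC values with companion user counts."""

    medication_ids: list[str]
    values: np.ndarray  # AUC per medication, NaN where undefined
    user_counts: np.ndarray = field(default=None)

    def mean(self) -> float:
        return float(np.nanmean(self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "medication_id": self.medication_ids,
            "n_users": self.user_counts,
            "auc": self.values,
        })


def auc_table(y_true, scores, medication_ids=None, user_counts=None) -> AUCTable:
    """Per-medication AUC on a test block (one AUC per label column)."""
    y_true = np.asarray(getattr(y_true, "values", y_true), dtype=np.float64)
    scores = np.asarray(scores, dtype=np.float64)
    k = y_true.shape[1]
    if medication_ids is None:
        medication_ids = [f"med{j}" for j in range(k)]
    vals = np.array([auc(y_true[:, j], scores[:, j]) for j in range(k)])
    counts = (np.asarray(user_counts) if user_counts is not None
              else y_true.sum(axis=0).astype(int))
    return AUCTable(list(medication_ids), vals, counts)


def paired_ttest(auc_a, auc_b) -> tuple[float, float]:
    """Paired two-sided t-test on per-medication AUC differences.

    ``t = mean(d) / (sd(d)/sqrt(m))`` with ``d = a - b`` over m medications;
    p from Student t with m-1 degrees of freedom. All-zero differences give
    (0, 1); zero-variance nonzero differences raise (degenerate, no silent
    infinity). Medication pairs where either AUC is undefined are dropped.
    """
    a = np.asarray(auc_a, dtype=np.float64)
    b = np.asarray(auc_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("AUC vectors must be over the same medication set")
    ok = np.isfinite(a) & np.isfinite(b)
    d = a[ok] - b[ok]
    m = len(d)
    if m < 2:
        raise ValueError("need at least 2 medications for a paired t-test")
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        raise ValueError("degenerate paired t-test: constant nonzero differences")
    res = stats.ttest_rel(a[ok], b[ok])
    return float(res.statistic), float(res.pvalue)


def percentile_bin_means(table: AUCTable, n_bins: int = 5) -> pd.DataFrame:
    """Mean AUC per medication-sample-size percentile range.

    Medications are binned by the percentile of their user count
    (0-20, 20-40, ... for 5 bins) using nearest-rank percentile boundaries;
    a medication exactly on a boundary goes to the lower bin. Empty bins are
    reported with NaN means.
    """
    counts = np.asarray(table.user_counts, dtype=np.float64)
    aucs = np.asarray(table.values, dtype=np.float64)
    m = len(counts)
    if m == 0:
        raise ValueError("empty AUC table")
    edges = [
        np.percentile(counts, 100.0 * b / n_bins, method="inverted_cdf")
        for b in range(1, n_bins)
    ]
    bins = np.zeros(m, dtype=int)
    for j in range(m):
        b = 0
        for e in edges:
            if counts[j] > e:
                b += 1
        bins[j] = b
    rows = []
    for b in range(n_bins):
        sel = bins == b
        lo, hi = 100 * b // n_bins, 100 * (b + 1) // n_bins
        rows.append({
            "percentile_range": f"{lo}-{hi}",
            "n_medications": int(sel.sum()),
            "mean_auc": float(np.nanmean(aucs[sel])) if sel.any() else math.nan,
        })
    return pd.DataFrame(rows)


def auc_report(tables: dict[str, AUCTable]) -> pd.DataFrame:
    """Side-by-side per-medication AUC report for a set of named models."""
    first = next(iter(tables.values()))
    out = pd.DataFrame({
        "medication_id": first.medication_ids,
        "n_users": first.user_counts,
    })
    for name, tab in tables.items():
        if tab.medication_ids != first.medication_ids:
            raise ValueError("AUC tables cover different medication sets")
        out[f"auc_{name.replace('-', '_')}"] = tab.values
    return out
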