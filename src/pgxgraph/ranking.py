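"""Rank-based interpretation of medication-usage predictions.

Predicted probabilities are standardized per medication into Z-scores,
converted within each patient into ranks (rank 1 = highest Z-score), and the
association between a medication ranking in a patient's top five and the
patient actually using it is quantified with a logistic-regression odds
ratio and a 95% Wald confidence interval. The analysis is restricted to
medications with at least ``min_n`` users.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


def zscore_columns(pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize each medication column to mean 0, sd 1 (sample sd, ddof=1).

    Returns (Z, degenerate_flags); a zero-variance column becomes all zeros
    with its flag set.
    """
    pred = np.asarray(pred, dtype=np.float64)
    if pred.ndim != 2 or pred.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 patients")
    mu = pred.mean(axis=0)
    sd = pred.std(axis=0, ddof=1)
    degenerate = sd == 0.0
    safe = np.where(degenerate, 1.0, sd)
    Z = (pred - mu) / safe
    Z[:, degenerate] = 0.0
    return Z, degenerate


def rank_rows(Z: np.ndarray) -> np.ndarray:
    """Within-patient ranks of the Z-scores: rank 1 = largest.

    Ties are broken by medication column index (lower index ranks better),
    so each row is a permutation of 1..k.
    """
    Z = np.asarray(Z, dtype=np.float64)
    order = np.argsort(-Z, axis=1, kind="stable")
    R = np.empty_like(order)
    rows = np.arange(Z.shape[0])[:, None]
    R[rows, order] = np.arange(1, Z.shape[1] + 1)
    return R


def top_k_indicator(R: np.ndarray, k_top: int = 5) -> np.ndarray:
    """Binary indicator of a medication ranking in the patient's top ``k_top``."""
    R = np.asarray(R)
    if k_top > R.shape[1]:
        raise ValueError(f"k_top={k_top} exceeds {R.shape[1]} medications")
    return (R <= k_top).astype(np.int64)


@dataclass
class ORResult:
    """Odds ratio of usage given a top-rank indicator, with a 95% Wald CI."""

    medication_id: str
    n_users: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    degenerate: bool = False

    @property
    def table(self) -> tuple:
        return (self.odds_ratio, self.ci_low, self.ci_high)


def rank_association(indicator, usage, medication_id: str = "",
                     min_n: int = 5000) -> ORResult:
    """Logistic regression of actual usage on the top-rank indicator.

    With a single binary predictor the fitted slope equals the log
    cross-product ratio of the 2x2 table, so OR = (a*d)/(b*c) where a = users
    with the top rank, b = non-users with it, c = users without, d = non-users
    without. CI is exp(slope +/- 1.96*SE). A zero cell makes the OR undefined
    and the result is returned flagged degenerate (no continuity correction).
    """
    x = np.asarray(indicator, dtype=np.float64)
    y = np.asarray(usage, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("indicator and usage must be 1-D of equal length")
    n_users = int(y.sum())
    if n_users < min_n:
        raise ValueError(
            f"medication {medication_id!r} has {n_users} users < min_n={min_n}"
        )
    a = int(np.sum((y == 1) & (x == 1)))
    b = int(np.sum((y == 0) & (x == 1)))
    c = int(np.sum((y == 1) & (x == 0)))
    d = int(np.sum((y == 0) & (x == 0)))
    if min(a, b, c, d) == 0:
        return ORResult(medication_id, n_users, float("nan"), float("nan"),
                        float("nan"), float("nan"), degenerate=True)
    model = sm.Logit(y, sm.add_constant(x))
    fit = model.fit(disp=0)
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    return ORResult(
        medication_id=medication_id,
        n_users=n_users,
        odds_ratio=float(np.exp(slope)),
        ci_low=float(np.exp(slope - 1.96 * se)),
        ci_high=float(np.exp(slope + 1.96 * se)),
        p_value=float(fit.pvalues[1]),
    )


def rank_report(probs: np.ndarray, usage: np.ndarray,
                medication_ids: list[str], k_top: int = 5,
                min_n: int = 5000) -> pd.DataFrame:
    """Full ranking analysis: Z-scores, ranks, top-k indicator, per-medication OR.

    Only medications with at least ``min_n`` users are analyzed; degenerate
    (zero-cell) medications are flagged and carry NaN estimates. Rows are
    sorted from highest to lowest odds ratio.
    """
    Z, _ = zscore_columns(probs)
    R = rank_rows(Z)
    top = top_k_indicator(R, k_top=k_top)
    usage = np.asarray(getattr(usage, "values", usage), dtype=np.float64)
    rows = []
    for j, med in enumerate(medication_ids):
        if usage[:, j].sum() < min_n:
            continue
        res = rank_association(top[:, j], usage[:, j], medication_id=med,
                               min_n=min_n)
        rows.append({
            "medication_id": med, "n_users": res.n_users,
            "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "p": res.p_value,
            "degenerate": res.degenerate,
        })
    df = pd.DataFrame(rows, columns=["medication_id", "n_users", "odds_ratio",
                                     "ci_low", "ci_high", "p", "degenerate"])
    return df.sort_values("odds_ratio", ascending=False, na_position="last",
                          ignore_index=True)
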