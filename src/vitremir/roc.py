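"""Ratio biomarker and ROC analysis.

The candidate diagnostic is the ratio of two miRNAs' per-sample linear fold
changes (numerator up in disease, denominator down, so the ratio amplifies
the contrast; the endogenous reference cancels in the ratio).  The ROC AUC
is computed by the Mann-Whitney pair-counting identity -- the probability
that a random case outranks a random control, ties counting one half --
which equals the trapezoidal area under the empirical ROC curve.  The
confidence interval uses the Hanley-McNeil standard error with a plain
normal interval, deliberately not truncated at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RocResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    points: pd.DataFrame          # columns threshold, fpr, tpr
    n_case: int
    n_control: int


def ratio_values(
    fc_table: pd.DataFrame,
    numerator: str,
    denominator: str,
) -> pd.DataFrame:
    """Per-sample ratio of linear fold changes FC_num / FC_den.

    Samples missing either fold change are omitted with a log entry.
    Columns: sample_id, group, ratio.
    """
    num = fc_table[fc_table["mir_id"] == numerator].set_index("sample_id")
    den = fc_table[fc_table["mir_id"] == denominator].set_index("sample_id")
    if den.empty:
        raise AnalysisError(f"ratio_not_computable: no fold changes for denominator {denominator!r}")
    if num.empty:
        raise AnalysisError(f"ratio_not_computable: no fold changes for numerator {numerator!r}")
    common = num.index.intersection(den.index)
    for s in num.index.symmetric_difference(den.index):
        logger.warning("sample %s omitted from ratio: one of the two fold changes missing", s)
    out = pd.DataFrame(
        {
            "sample_id": common,
            "group": num.loc[common, "group"].to_numpy(),
            "ratio": (num.loc[common, "fc"] / den.loc[common, "fc"]).to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def auc_mann_whitney(cases, controls) -> float:
    """AUC = (#{case > control} + 0.5 * #ties) / (n_case * n_control)."""
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise AnalysisError("both groups must be non-empty")
    pooled = np.concatenate([cases, controls])
    ranks = stats.rankdata(pooled)  # midranks handle ties
    r_case = ranks[: cases.size].sum()
    u = r_case - cases.size * (cases.size + 1) / 2.0
    return float(u / (cases.size * controls.size))


def roc_points(cases, controls) -> pd.DataFrame:
    """Empirical ROC points thresholded on the score (higher = more case-like).

    Rows run from (inf threshold, fpr 0, tpr 0) to (-inf, 1, 1); at each
    distinct observed score the predicate is score >= threshold.
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    thresholds = np.unique(np.concatenate([cases, controls]))[::-1]
    rows = [{"threshold": np.inf, "fpr": 0.0, "tpr": 0.0}]
    for t in thresholds:
        rows.append(
            {
                "threshold": float(t),
                "fpr": float(np.mean(controls >= t)),
                "tpr": float(np.mean(cases >= t)),
            }
        )
    if rows[-1]["fpr"] != 1.0 or rows[-1]["tpr"] != 1.0:
        rows.append({"threshold": -np.inf, "fpr": 1.0, "tpr": 1.0})
    return pd.DataFrame(rows)


def auc_ci(auc: float, n_case: int, n_control: int, level: float = 0.95) -> tuple[float, float, float]:
    """Hanley-McNeil SE and normal CI for an AUC (interval not truncated at 1).

    SE^2 = [A(1-A) + (n_case-1)(Q1-A^2) + (n_control-1)(Q2-A^2)]
           / (n_case * n_control),
    Q1 = A/(2-A), Q2 = 2A^2/(1+A).
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must be in [0, 1]")
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n_case - 1) * (q1 - a * a) + (n_control - 1) * (q2 - a * a)) / (
        n_case * n_control
    )
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return se, a - z * se, a + z * se


def auc_pvalue(auc: float, n_case: int, n_control: int) -> float:
    """Two-sided p for H0: AUC = 0.5, normal approximation to Mann-Whitney U."""
    n1, n0 = n_case, n_control
    u = auc * n1 * n0
    mu = n1 * n0 / 2.0
    sigma = np.sqrt(n1 * n0 * (n1 + n0 + 1) / 12.0)
    if sigma == 0:
        raise AnalysisError("degenerate group sizes")
    z = (u - mu) / sigma
    return float(2.0 * stats.norm.sf(abs(z)))


def roc_analysis(ratios: pd.DataFrame, case_label: str = "case", level: float = 0.95) -> RocResult:
    """Full ROC summary from a ratio-biomarker table (columns group, ratio)."""
    cases = ratios.loc[ratios["group"] == case_label, "ratio"].to_numpy(dtype=float)
    controls = ratios.loc[ratios["group"] != case_label, "ratio"].to_numpy(dtype=float)
    a = auc_mann_whitney(cases, controls)
    se, lo, hi = auc_ci(a, len(cases), len(controls), level=level)
    p = auc_pvalue(a, len(cases), len(controls))
    return RocResult(
        auc=a, se=se, ci_low=lo, ci_high=hi, p_value=p,
        points=roc_points(cases, controls), n_case=len(cases), n_control=len(controls),
    )
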