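"""Group comparison of fold changes: Student t-tests and per-miRNA summaries.

The t-test operates on centered log2 fold changes (log transformation makes
the multiplicative qPCR error model approximately Gaussian); summaries
report both the linear-scale and log2-scale group mean with SEM, since mean
and log transform do not commute across patients and readers of qPCR
figures expect both.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldChangeSummary:
    mir_id: str
    n_control: int
    n_case: int
    mean_linear_fc_case: float
    sem_linear_case: float
    mean_log2_case: float
    sem_log2: float
    t_statistic: float
    df: float
    p_value: float
    evaluable: bool = True


def student_t(group_a, group_b, variant: str = "pooled") -> tuple[float, float, float]:
    """Two-sided Student t-test; returns (t, df, p).

    'pooled' uses the classical equal-variance test with df = n_a + n_b - 2;
    'welch' the unequal-variance form.  Degenerate zero-variance inputs:
    equal means give p = 1, unequal means p -> 0 (with a warning).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise AnalysisError("each group needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise AnalysisError("non-finite values in t-test input")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        df = len(a) + len(b) - 2
        if a.mean() == b.mean():
            return 0.0, float(df), 1.0
        warnings.warn("zero variance with unequal means: p underflows to 0")
        return float(np.inf if a.mean() > b.mean() else -np.inf), float(df), 0.0
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def summarize_mir(
    fc_table: pd.DataFrame,
    mir_id: str,
    control_label: str = "control",
    case_label: str = "case",
    variant: str = "pooled",
) -> FoldChangeSummary:
    """Linear and log2 group summaries plus the group-comparison p for one miRNA.

    The t-test compares centered log2 fold changes between groups; the
    case-side summaries are the linear-FC mean +/- SEM and the centered
    log2 mean +/- SEM.
    """
    sub = fc_table[fc_table["mir_id"] == mir_id]
    value_col = "centered_log2fc" if "centered_log2fc" in sub.columns else "log2fc"
    ctrl = sub[sub["group"] == control_label]
    case = sub[sub["group"] == case_label]
    n_c, n_a = len(ctrl), len(case)
    if n_c < 2 or n_a < 2:
        logger.warning("miRNA %s not evaluable: group with n < 2 after QC", mir_id)
        return FoldChangeSummary(mir_id, n_c, n_a, *(float("nan"),) * 7, evaluable=False)
    t, df, p = student_t(ctrl[value_col], case[value_col], variant=variant)
    case_fc = case["fc"].to_numpy(dtype=float)
    case_log2 = case[value_col].to_numpy(dtype=float)
    return FoldChangeSummary(
        mir_id=mir_id,
        n_control=n_c,
        n_case=n_a,
        mean_linear_fc_case=float(case_fc.mean()),
        sem_linear_case=float(case_fc.std(ddof=1) / np.sqrt(n_a)) if n_a > 1 else float("nan"),
        mean_log2_case=float(case_log2.mean()),
        sem_log2=float(case_log2.std(ddof=1) / np.sqrt(n_a)) if n_a > 1 else float("nan"),
        t_statistic=t,
        df=df,
        p_value=p,
    )


def summarize_all(fc_table: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """summarize_mir over every miRNA present, as a tidy DataFrame."""
    rows = [summarize_mir(fc_table, mir, **kwargs).__dict__ for mir in fc_table["mir_id"].unique()]
    return pd.DataFrame(rows)


def age_correlation(fc_table: pd.DataFrame, meta: pd.DataFrame, mir_id: str) -> tuple[float, float]:
    """Pearson r^2 (and signed r) between patient age and per-sample fold change.

    Used to check that a miRNA signature tracks disease rather than age.
    """
    sub = fc_table[fc_table["mir_id"] == mir_id].merge(
        meta[["sample_id", "age"]], on="sample_id", how="inner"
    )
    ages = sub["age"].to_numpy(dtype=float)
    fcs = sub["fc"].to_numpy(dtype=float)
    if len(ages) < 3:
        raise AnalysisError("age correlation needs at least 3 samples")
    if np.std(ages) == 0:
        raise AnalysisError("age vector is constant; correlation undefined")
    r = float(stats.pearsonr(ages, fcs).statistic)
    return r * r, r
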