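"""Quality-control exclusions applied before normalization.

Exclusion order is fixed: undetected reactions (past the 40-cycle limit) ->
amplification-efficiency cutoff (default 80% of perfect doubling) ->
plasma hemolysis index (> 1 excluded) -> clinical-flag blocklist -> Grubbs
single-outlier test on per-group log2 fold changes.  Every exclusion carries
one machine-readable reason code and is accumulated in a QcReport.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError

logger = logging.getLogger(__name__)

REASON_UNDETECTED = "undetected"
REASON_EFFICIENCY = "efficiency_below_cutoff"
REASON_HEMOLYSIS = "hemolysis_index_above_cutoff"
REASON_HEMOLYSIS_MISSING = "missing_hemolysis_index"
REASON_CLINICAL = "clinical_flag"
REASON_GRUBBS = "grubbs_outlier"


@dataclass
class QcReport:
    excluded_reactions: list[tuple[str, str]] = field(default_factory=list)
    excluded_samples: list[tuple[str, str]] = field(default_factory=list)
    retained: dict[str, int] = field(default_factory=dict)

    def add_reaction(self, reaction_id: str, reason: str) -> None:
        self.excluded_reactions.append((str(reaction_id), reason))
        logger.warning("excluding reaction %s: %s", reaction_id, reason)

    def add_sample(self, sample_id: str, reason: str) -> None:
        self.excluded_samples.append((str(sample_id), reason))
        logger.warning("excluding sample %s: %s", sample_id, reason)

    def merge(self, other: "QcReport") -> "QcReport":
        self.excluded_reactions.extend(other.excluded_reactions)
        self.excluded_samples.extend(other.excluded_samples)
        self.retained.update(other.retained)
        return self

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"entity_id": rid, "entity_type": "reaction", "reason": reason}
            for rid, reason in self.excluded_reactions
        ] + [
            {"entity_id": sid, "entity_type": "sample", "reason": reason}
            for sid, reason in self.excluded_samples
        ]
        return pd.DataFrame(rows, columns=["entity_id", "entity_type", "reason"])


def filter_detection(records: pd.DataFrame) -> tuple[pd.DataFrame, QcReport]:
    """Drop reactions whose Ct is undetected (NaN, i.e. past 40 cycles)."""
    report = QcReport()
    mask = records["ct"].isna()
    for rid in records.loc[mask, "reaction_id"]:
        report.add_reaction(rid, REASON_UNDETECTED)
    return records.loc[~mask].copy(), report


def filter_efficiency(records: pd.DataFrame, cutoff_percent: float = 80.0) -> tuple[pd.DataFrame, QcReport]:
    """Exclude reactions amplifying below ``cutoff_percent`` of perfect doubling.

    Each record must carry an ``efficiency`` column (amplification base, or a
    plate-level base broadcast onto it); percent = 100 * base / 2.
    """
    report = QcReport()
    percent = 100.0 * records["efficiency"].to_numpy(dtype=float) / 2.0
    bad = percent < cutoff_percent
    for rid in records.loc[bad, "reaction_id"]:
        report.add_reaction(rid, REASON_EFFICIENCY)
    return records.loc[~bad].copy(), report


def filter_hemolysis(samples: pd.DataFrame, cutoff: float = 1.0) -> tuple[pd.DataFrame, QcReport]:
    """Exclude plasma samples with hemolysis index strictly above ``cutoff``.

    Vitreous samples are untouched; a plasma sample with a missing index is
    excluded conservatively.
    """
    report = QcReport()
    keep = np.ones(len(samples), dtype=bool)
    for i, row in enumerate(samples.itertuples(index=False)):
        if row.matrix != "plasma":
            continue
        idx = getattr(row, "hemolysis_index", np.nan)
        if pd.isna(idx):
            report.add_sample(row.sample_id, REASON_HEMOLYSIS_MISSING)
            keep[i] = False
        elif idx > cutoff:
            report.add_sample(row.sample_id, REASON_HEMOLYSIS)
            keep[i] = False
    return samples.loc[keep].copy(), report


def filter_clinical(samples: pd.DataFrame, blocklist: set[str] | frozenset[str] = frozenset()) -> tuple[pd.DataFrame, QcReport]:
    """Exclude samples whose clinical_flags intersect a configurable blocklist."""
    report = QcReport()
    keep = np.ones(len(samples), dtype=bool)
    if blocklist:
        for i, row in enumerate(samples.itertuples(index=False)):
            flags = {f.strip() for f in str(getattr(row, "clinical_flags", "") or "").split(";") if f.strip()}
            if flags & set(blocklist):
                report.add_sample(row.sample_id, REASON_CLINICAL)
                keep[i] = False
    return samples.loc[keep].copy(), report


def grubbs_statistic(values) -> tuple[float, int]:
    """Grubbs statistic G = max |x - mean| / s (sample SD) and its position."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise AnalysisError("grubbs_undefined: n < 3")
    s = x.std(ddof=1)
    if s == 0:
        raise AnalysisError("grubbs_undefined: zero variance")
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    return float(dev[idx] / s), idx


def grubbs_critical(n: int, alpha: float = 0.05, two_sided: bool = True) -> float:
    """Critical value of the Grubbs single-outlier test.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2)) with t the upper
    alpha/(2n) (two-sided) or alpha/n (one-sided) Student-t quantile on
    n-2 degrees of freedom.
    """
    if n < 3:
        raise AnalysisError("grubbs_undefined: n < 3")
    tail = alpha / (2 * n) if two_sided else alpha / n
    t = stats.t.ppf(1 - tail, n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2)))


def grubbs_test(values, alpha: float = 0.05, two_sided: bool = True, iterative: bool = False) -> list[int]:
    """Positions (into the input) of Grubbs outliers; one per pass.

    Non-iterative by default (single most extreme value tested once,
    matching the common single-outlier calculator); with ``iterative`` the
    test repeats on the reduced set until no outlier remains.
    """
    x = np.asarray(values, dtype=float)
    positions = list(range(len(x)))
    flagged: list[int] = []
    while len(x) >= 3:
        try:
            g, idx = grubbs_statistic(x)
        except AnalysisError:
            break
        if g > grubbs_critical(len(x), alpha, two_sided):
            flagged.append(positions[idx])
            x = np.delete(x, idx)
            del positions[idx]
            if not iterative:
                break
        else:
            break
    return flagged


def grubbs_filter_groups(
    fc_table: pd.DataFrame,
    value_col: str = "log2fc",
    alpha: float = 0.05,
    iterative: bool = False,
) -> tuple[pd.DataFrame, QcReport]:
    """Apply the Grubbs test within each (miRNA, group) cell of a fold-change table.

    Flagged samples lose that miRNA's fold change only (not the whole sample).
    Groups too small or degenerate for the test are left untouched.
    """
    report = QcReport()
    drop = np.zeros(len(fc_table), dtype=bool)
    for (mir, group), sub in fc_table.groupby(["mir_id", "group"]):
        vals = sub[value_col].to_numpy(dtype=float)
        if len(vals) < 3 or np.std(vals, ddof=1) == 0:
            continue
        for pos in grubbs_test(vals, alpha=alpha, iterative=iterative):
            i = sub.index[pos]
            drop[fc_table.index.get_loc(i)] = True
            report.add_reaction(f"{sub.loc[i, 'sample_id']}:{mir}", REASON_GRUBBS)
    return fc_table.loc[~drop].copy(), report
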