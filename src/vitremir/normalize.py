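"""Weighted-mean reference, dCt/ddCt and efficiency-based fold change.

The quantification chain, per sample i and target miRNA:

    Ct0(i)   = sum_j w_j * Ct_j(i)           (endogenous reference)
    dCt(i)   = Ct_miR(i) - Ct0(i)
    ddCt(i)  = dCt(i) - mean(dCt over control samples)
    FC(i)    = E ** (-ddCt(i))               (E = amplification base)
    log2FC   = log2(FC)
    centered = log2FC - mean(control log2FC) (control mean becomes 0)

When no single housekeeping miRNA is established (vitreous humour), the
reference is the weighted mean of several panel miRNAs with weights
inversely proportional to their across-sample Ct variability,

    w_j = (1 / SD_j)^wmp / sum_k (1 / SD_k)^wmp,

which reduces to the plain mean when all SDs are equal or wmp = 0.  For
plasma, miR-16 serves as a conventional single reference (the degenerate
weighted mean with one member).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceModel:
    """The endogenous reference actually used: mode, members and weights."""

    mode: str                                   # 'weighted_mean' | 'single_mir'
    members: tuple[str, ...]
    wmp: float = 1.0
    weights: dict[str, float] = field(default_factory=dict)
    per_mir_sd: dict[str, float] = field(default_factory=dict)


def ct_matrix(records: pd.DataFrame, collapse: str = "mean") -> pd.DataFrame:
    """Collapse replicate reactions and pivot to a sample x miRNA Ct matrix.

    Undetected replicates (NaN) are ignored in the collapse; a cell is NaN
    only when every replicate was undetected.
    """
    if collapse not in ("mean", "median"):
        raise ValueError("collapse must be 'mean' or 'median'")
    agg = records.groupby(["sample_id", "mir_id"])["ct"].agg(collapse)
    return agg.unstack("mir_id")


def weighted_reference(
    ct_mat: pd.DataFrame,
    members,
    wmp: float = 1.0,
) -> tuple[pd.Series, ReferenceModel, list[str]]:
    """Per-sample weighted-mean reference Ct0 over ``members``.

    Samples in which any member is undetected cannot anchor the reference
    and are flagged (returned as the third element) and excluded.
    Weights are (1/SD_j)^wmp normalized to sum to 1, SD taken across the
    retained samples.
    """
    members = list(members)
    missing = [m for m in members if m not in ct_mat.columns]
    if missing:
        raise AnalysisError(f"reference member(s) absent from Ct table: {missing}")
    sub = ct_mat[members]
    flagged = sub.index[sub.isna().any(axis=1)].tolist()
    for s in flagged:
        logger.warning("sample %s excluded from reference: member miRNA undetected", s)
    sub = sub.dropna()
    if sub.empty:
        raise AnalysisError("no sample retains all reference members")
    sds = sub.std(ddof=1)
    if (sds <= 0).any() and wmp != 0:
        bad = sds.index[sds <= 0].tolist()
        raise AnalysisError(f"reference member(s) with zero Ct variability: {bad}")
    raw = (1.0 / sds) ** wmp if wmp != 0 else pd.Series(1.0, index=sds.index)
    weights = raw / raw.sum()
    ct0 = sub.mul(weights, axis=1).sum(axis=1)
    ct0.name = "ct0"
    model = ReferenceModel(
        mode="weighted_mean" if len(members) > 1 else "single_mir",
        members=tuple(members),
        wmp=wmp,
        weights=weights.to_dict(),
        per_mir_sd=sds.to_dict(),
    )
    return ct0, model, flagged


def single_reference(ct_mat: pd.DataFrame, reference_mir: str) -> tuple[pd.Series, ReferenceModel, list[str]]:
    """Per-sample Ct0 equal to a single reference miRNA's Ct (e.g. miR-16)."""
    if reference_mir not in ct_mat.columns:
        raise AnalysisError(f"reference miRNA {reference_mir!r} absent from Ct table")
    col = ct_mat[reference_mir]
    flagged = col.index[col.isna()].tolist()
    for s in flagged:
        logger.warning("sample %s excluded: reference %s undetected", s, reference_mir)
    ct0 = col.dropna().copy()
    ct0.name = "ct0"
    model = ReferenceModel(mode="single_mir", members=(reference_mir,), weights={reference_mir: 1.0})
    return ct0, model, flagged


def delta_ct(ct_mat: pd.DataFrame, ct0: pd.Series) -> pd.DataFrame:
    """dCt = Ct_miR - Ct0, restricted to samples with a reference value."""
    return ct_mat.loc[ct0.index].sub(ct0, axis=0)


def fold_change(
    dct: pd.DataFrame,
    groups: pd.Series,
    base: float,
    control_label: str = "control",
) -> pd.DataFrame:
    """Per-sample ddCt and efficiency-based fold change, long format.

    ddCt is each sample's dCt minus the control-group mean dCt of that
    miRNA (so controls get per-sample fold changes too, scattering around
    1); FC = base^(-ddCt).  miRNAs with no detected control sample are
    dropped with a logged reason.  Columns of the result: sample_id,
    mir_id, group, ddct, fc, log2fc.
    """
    if not 1.0 < base <= 2.0:
        raise ValueError("amplification base must be in (1, 2]")
    groups = groups.loc[groups.index.intersection(dct.index)]
    controls = groups.index[groups == control_label]
    if len(controls) == 0:
        raise AnalysisError("control group empty")
    rows = []
    for mir in dct.columns:
        col = dct[mir]
        ctrl_mean = col.loc[col.index.intersection(controls)].mean()
        if pd.isna(ctrl_mean):
            logger.warning("miRNA %s dropped: no detected control sample", mir)
            continue
        ddct = col - ctrl_mean
        fc = np.power(base, -ddct)
        for sample in dct.index:
            if pd.isna(ddct.loc[sample]) or sample not in groups.index:
                continue
            rows.append(
                {
                    "sample_id": sample,
                    "mir_id": mir,
                    "group": groups.loc[sample],
                    "ddct": float(ddct.loc[sample]),
                    "fc": float(fc.loc[sample]),
                    "log2fc": float(np.log2(fc.loc[sample])),
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "mir_id", "group", "ddct", "fc", "log2fc"])


def log2_center(
    fc_table: pd.DataFrame,
    control_label: str = "control",
    center: str = "mean",
) -> pd.DataFrame:
    """Center log2 fold changes on the control group, per miRNA.

    centered_log2fc = log2fc - mean(control log2fc); after centering the
    control mean is 0 to machine precision.  ``center='median'`` substitutes
    the control median.
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    out = fc_table.copy()
    out["centered_log2fc"] = np.nan
    for mir, sub in fc_table.groupby("mir_id"):
        ctrl = sub.loc[sub["group"] == control_label, "log2fc"]
        if ctrl.empty:
            logger.warning("miRNA %s not centered: no control fold changes", mir)
            continue
        shift = ctrl.mean() if center == "mean" else ctrl.median()
        out.loc[sub.index, "centered_log2fc"] = sub["log2fc"] - shift
    return out
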