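"""End-to-end pipeline: QC -> normalization -> group stats -> ratio ROC.

A run is fully determined by a PipelineConfig plus its input tables; every
exclusion is logged and written to the QC report, and all stage outputs are
serialized so each number in the final summary is traceable back through
Ct -> dCt -> FC -> summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import diffstats, io, normalize, qc, roc
from .errors import ConfigError

logger = logging.getLogger(__name__)

VITREOUS_REFERENCE = ("miR-16", "miR-106b", "miR-146a", "miR-152")


@dataclass
class PipelineConfig:
    """Declarative description of one analysis run."""

    matrix: str = "vitreous"
    reference_mode: str = "weighted_mean"       # 'weighted_mean' | 'single_mir'
    reference_members: tuple[str, ...] = VITREOUS_REFERENCE
    reference_mir: str = "miR-16"
    wmp: float = 1.0
    efficiency_base: float = 1.75               # plate-level base when no curves given
    efficiency_policy: str = "mean"
    efficiency_cutoff_percent: float = 80.0
    hemolysis_cutoff: float = 1.0
    clinical_blocklist: tuple[str, ...] = ("glaucoma", "eye_medical_treatment")
    grubbs_alpha: float = 0.05
    grubbs_iterative: bool = False
    t_variant: str = "pooled"
    center: str = "mean"
    replicate_collapse: str = "mean"
    ratio_numerator: str = "miR-146a"
    ratio_denominator: str = "miR-106b"
    control_label: str = "control"
    case_label: str = "case"
    seed: int = 0

    @classmethod
    def for_matrix(cls, matrix: str, **kwargs) -> "PipelineConfig":
        """Defaults mirroring the two study arms: weighted-mean reference
        over four panel miRNAs for vitreous, single miR-16 for plasma."""
        if matrix == "plasma":
            kwargs.setdefault("reference_mode", "single_mir")
        return cls(matrix=matrix, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        for key in ("reference_members", "clinical_blocklist"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def validate(self) -> None:
        if self.matrix not in ("vitreous", "plasma"):
            raise ConfigError("matrix must be 'vitreous' or 'plasma'")
        if self.reference_mode not in ("weighted_mean", "single_mir"):
            raise ConfigError("reference_mode must be 'weighted_mean' or 'single_mir'")
        if not 1.0 < self.efficiency_base <= 2.0:
            raise ConfigError("efficiency_base must be in (1, 2]")
        if self.wmp < 0:
            raise ConfigError("wmp must be >= 0")


@dataclass
class PipelineResult:
    fc_table: pd.DataFrame
    summary: pd.DataFrame
    roc: roc.RocResult | None
    qc_report: qc.QcReport
    reference: normalize.ReferenceModel


def run_pipeline(
    records: pd.DataFrame,
    meta: pd.DataFrame,
    config: PipelineConfig,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute QC, normalization, group statistics and the ratio ROC.

    ``records`` are reaction records (reaction_id, sample_id, mir_id,
    replicate, ct, [efficiency]); ``meta`` is the sample metadata table.
    When ``outdir`` is given all report files are written there.
    """
    config.validate()
    if config.matrix == "plasma" and "hemolysis_index" not in meta.columns:
        raise ConfigError("plasma run requires a hemolysis_index metadata column")

    report = qc.QcReport()

    # reaction-level QC: detection threshold, then efficiency cutoff
    records = records.copy()
    if "efficiency" not in records.columns:
        records["efficiency"] = config.efficiency_base
    records, rep = qc.filter_detection(records)
    report.merge(rep)
    records, rep = qc.filter_efficiency(records, config.efficiency_cutoff_percent)
    report.merge(rep)

    # sample-level QC: hemolysis (plasma), clinical blocklist
    meta_kept, rep = qc.filter_hemolysis(meta, config.hemolysis_cutoff)
    report.merge(rep)
    meta_kept, rep = qc.filter_clinical(meta_kept, set(config.clinical_blocklist))
    report.merge(rep)
    records = records[records["sample_id"].isin(meta_kept["sample_id"])]

    # normalization
    ct_mat = normalize.ct_matrix(records, collapse=config.replicate_collapse)
    if config.reference_mode == "weighted_mean":
        ct0, ref_model, flagged = normalize.weighted_reference(
            ct_mat, [m for m in config.reference_members if m in ct_mat.columns], config.wmp
        )
    else:
        ct0, ref_model, flagged = normalize.single_reference(ct_mat, config.reference_mir)
    for s in flagged:
        report.add_sample(s, "reference_undetected")

    groups = meta_kept.set_index("sample_id")["group"]
    dct = normalize.delta_ct(ct_mat, ct0)
    fc = normalize.fold_change(dct, groups, config.efficiency_base, config.control_label)
    fc = normalize.log2_center(fc, config.control_label, center=config.center)

    # outlier pass on per-group centered log2 fold changes
    fc, rep = qc.grubbs_filter_groups(
        fc, value_col="centered_log2fc", alpha=config.grubbs_alpha,
        iterative=config.grubbs_iterative,
    )
    report.merge(rep)
    report.retained = fc.groupby("group")["sample_id"].nunique().to_dict()

    summary = diffstats.summarize_all(
        fc, control_label=config.control_label, case_label=config.case_label,
        variant=config.t_variant,
    )

    roc_result = None
    if config.ratio_numerator in set(fc["mir_id"]) and config.ratio_denominator in set(fc["mir_id"]):
        ratios = roc.ratio_values(fc, config.ratio_numerator, config.ratio_denominator)
        roc_result = roc.roc_analysis(ratios, case_label=config.case_label)
    else:
        logger.warning("ratio ROC skipped: numerator or denominator miRNA absent after QC")

    result = PipelineResult(fc_table=fc, summary=summary, roc=roc_result,
                            qc_report=report, reference=ref_model)
    if outdir is not None:
        _write_reports(result, records, config, Path(outdir))
    return result


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_reports(result: PipelineResult, records: pd.DataFrame,
                   config: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    records.to_csv(outdir / "retained_reactions.csv", index=False)
    result.fc_table.to_csv(outdir / "fold_changes.tsv", sep="\t", index=False)
    result.summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    result.qc_report.to_frame().to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    if result.roc is not None:
        result.roc.points.to_csv(outdir / "roc_points.tsv", sep="\t", index=False)
        io.write_json(
            {
                "auc": result.roc.auc,
                "se": result.roc.se,
                "ci_low": result.roc.ci_low,
                "ci_high": result.roc.ci_high,
                "p_value": result.roc.p_value,
                "n_case": result.roc.n_case,
                "n_control": result.roc.n_control,
                "numerator": config.ratio_numerator,
                "denominator": config.ratio_denominator,
            },
            outdir / "roc_summary.json",
        )
    io.write_json(
        {
            "version": __version__,
            "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
            "config_hash": _config_hash(config),
            "reference": {
                "mode": result.reference.mode,
                "members": list(result.reference.members),
                "weights": result.reference.weights,
            },
            "n_reactions_retained": int(len(records)),
        },
        outdir / "manifest.json",
    )
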