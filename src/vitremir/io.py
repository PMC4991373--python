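"""Readers and writers for the pipeline's plain-text formats.

Ct tables are long CSV (sample_id, mir_id, replicate, ct) with
"Undetermined", "NA" or empty cells for undetected reactions and Ct values
past the 40-cycle detection threshold coerced to undetected with a warning.
Decimal commas ("18,2") are rejected outright rather than guessed at --
silent locale coercion corrupts data.  Motif intervals arrive as BED6 and
are converted to the 1-based inclusive coordinates used internally.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

logger = logging.getLogger(__name__)

DETECTION_LIMIT = 40.0
UNDETECTED_TOKENS = {"undetermined", "na", "n/a", ""}


def _parse_ct(value) -> float:
    if isinstance(value, float) and np.isnan(value):
        return np.nan
    s = str(value).strip()
    if s.lower() in UNDETECTED_TOKENS:
        return np.nan
    if "," in s:
        raise SchemaError(f"decimal comma in ct value {s!r}: use '.' as the decimal separator")
    try:
        return float(s)
    except ValueError as exc:
        raise SchemaError(f"unparseable ct value {s!r}") from exc


def read_ct_table(path) -> pd.DataFrame:
    """Parse a long-format Ct CSV into reaction records.

    Returns columns reaction_id, sample_id, mir_id, replicate, ct (NaN =
    undetected).  Raises SchemaError for missing columns or duplicate
    (sample, mir, replicate) keys.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "mir_id": str}, keep_default_na=False)
    required = ["sample_id", "mir_id", "replicate", "ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"ct table {path}: missing column(s) {missing}")
    dup = df.duplicated(subset=["sample_id", "mir_id", "replicate"])
    if dup.any():
        first = df.loc[dup, ["sample_id", "mir_id", "replicate"]].iloc[0].tolist()
        raise SchemaError(f"ct table {path}: duplicate (sample, mir, replicate) key {first}")
    ct = df["ct"].map(_parse_ct)
    over = ct > DETECTION_LIMIT
    if over.any():
        warnings.warn(f"{int(over.sum())} ct value(s) above the {DETECTION_LIMIT:.0f}-cycle "
                      "detection threshold coerced to undetected")
        ct = ct.where(~over, np.nan)
    out = df[["sample_id", "mir_id"]].copy()
    out["replicate"] = df["replicate"].astype(int)
    out["ct"] = ct
    out.insert(0, "reaction_id",
               out["sample_id"] + ":" + out["mir_id"] + ":" + out["replicate"].astype(str))
    return out


def read_sample_meta(path) -> pd.DataFrame:
    """Sample metadata CSV/TSV: sample_id, group, matrix, age, sex, [hemolysis_index, clinical_flags]."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    required = ["sample_id", "group", "matrix"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"sample metadata {path}: missing column(s) {missing}")
    bad_group = set(df["group"]) - {"control", "case"}
    if bad_group:
        raise SchemaError(f"sample metadata {path}: unknown group label(s) {sorted(bad_group)}")
    bad_matrix = set(df["matrix"]) - {"vitreous", "plasma"}
    if bad_matrix:
        raise SchemaError(f"sample metadata {path}: unknown matrix value(s) {sorted(bad_matrix)}")
    if "hemolysis_index" not in df.columns:
        if (df["matrix"] == "plasma").any():
            raise SchemaError(f"sample metadata {path}: plasma samples require a hemolysis_index column")
        df["hemolysis_index"] = np.nan
    if "clinical_flags" not in df.columns:
        df["clinical_flags"] = ""
    df["clinical_flags"] = df["clinical_flags"].fillna("")
    return df


def read_curves(path) -> pd.DataFrame:
    """Raw amplification curves: long CSV reaction_id, sample_id, mir_id, cycle, fluorescence."""
    df = pd.read_csv(path)
    required = ["reaction_id", "sample_id", "mir_id", "cycle", "fluorescence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"curve table {path}: missing column(s) {missing}")
    if (df["cycle"] < 1).any():
        raise SchemaError(f"curve table {path}: cycle numbers must be >= 1")
    return df


def read_motifs_bed(path) -> pd.DataFrame:
    """BED6 motif intervals -> 1-based inclusive (chrom, start, end, mir_id, gene, evidence, score).

    BED name field encodes mir_id|gene|evidence; BED's 0-based half-open
    [start, end) becomes 1-based inclusive [start+1, end].
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score", "strand"])
    parts = df["name"].astype(str).str.split("|", expand=True)
    if parts.shape[1] < 3:
        raise SchemaError(f"motif BED {path}: name field must be mir_id|gene|evidence")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "start": df["start"].astype(int) + 1,
            "end": df["end"].astype(int),
            "mir_id": parts[0],
            "gene": parts[1],
            "evidence": parts[2],
            "score": pd.to_numeric(df["score"], errors="coerce"),
        }
    )
    if (out["start"] > out["end"]).any():
        raise SchemaError(f"motif BED {path}: interval with start > end")
    return out


def read_assoc(path) -> pd.DataFrame:
    """Association summary statistics TSV: rsid, chrom, pos, p [, gene]."""
    df = pd.read_csv(path, sep="\t")
    rename = {"p": "p_value"}
    df = df.rename(columns=rename)
    required = ["rsid", "chrom", "pos", "p_value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"association table {path}: missing column(s) {missing}")
    if ((df["p_value"] <= 0) | (df["p_value"] > 1)).any():
        raise SchemaError(f"association table {path}: p-values must lie in (0, 1]")
    if "gene" not in df.columns:
        df["gene"] = ""
    df["chrom"] = df["chrom"].astype(str)
    df["gene"] = df["gene"].fillna("")
    return df


def read_ld(path) -> pd.DataFrame:
    """LD table TSV: rsid_a, rsid_b, r2 [, chrom_b, pos_b]."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ["rsid_a", "rsid_b", "r2"] if c not in df.columns]
    if missing:
        raise SchemaError(f"LD table {path}: missing column(s) {missing}")
    return df


def read_gene_sets(path) -> dict[str, list[str]]:
    """Two-column TSV mir_id, gene -> {mir_id: [genes]}."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ["mir_id", "gene"] if c not in df.columns]
    if missing:
        raise SchemaError(f"gene-set table {path}: missing column(s) {missing}")
    return {mir: sub["gene"].tolist() for mir, sub in df.groupby("mir_id")}


def write_ct_table(records: pd.DataFrame, path) -> None:
    out = records[["sample_id", "mir_id", "replicate", "ct"]].copy()
    out["ct"] = out["ct"].map(lambda v: "Undetermined" if pd.isna(v) else f"{v:.4f}")
    out.to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
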