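"""Filtering GWAS summary statistics against miRNA binding-site motifs.

Given (i) genomic intervals with the capacity to encode miRNA binding
motifs (validated or predicted upstream with microT-CDS score > 0.70 /
miRDB Target Score > 80 -- those thresholds are applied at load, not here),
(ii) disease-association summary statistics (rsid, position, p), and
optionally (iii) an LD table for proxy lookup, the three-phase procedure is:

  Phase 1  annotate and enumerate: motif regions, resident genes and the
           SNPs falling inside each motif interval.
  Phase 2  test motif-resident SNPs at alpha = 0.05 / sqrt(N), N the number
           of SNPs tested in that motif-encoding region (the square-root
           adjustment is applied as stated, though it is neither Bonferroni
           nor Sidak; a conventional Bonferroni mode is available).
  Phase 3  widen to every SNP in the genes of each miRNA's target gene set,
           flag p < 0.005, and report Bonferroni-adjusted p and Storey
           q-values within that miRNA's gene-set SNP pool.

All coordinates are 1-based inclusive internally; BED input is converted
from 0-based half-open at the parsing boundary (see `io.read_motifs_bed`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import AnalysisError

logger = logging.getLogger(__name__)

PHASE3_P = 0.005


@dataclass
class PhaseReport:
    phase: int
    n_tested: int
    alpha_used: float | None
    hits: pd.DataFrame
    notes: list[str] = field(default_factory=list)


def _norm_chrom(c) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


def overlap_snps(snps: pd.DataFrame, motifs: pd.DataFrame) -> pd.DataFrame:
    """All (SNP, motif) pairs with chrom match and start <= pos <= end.

    Chromosome names are normalized ('chr6' and '6' match, with a warning
    when conventions are mixed).  Returns the SNP columns joined with the
    motif columns (suffixed _motif where colliding).
    """
    s_chrom = snps["chrom"].map(_norm_chrom)
    m_chrom = motifs["chrom"].map(_norm_chrom)
    had_prefix = set(snps["chrom"].astype(str).str.lower().str.startswith("chr")) | set(
        motifs["chrom"].astype(str).str.lower().str.startswith("chr")
    )
    if had_prefix == {True, False}:
        warnings.warn("mixed chromosome naming conventions; normalized to bare names")

    trees: dict[str, IntervalTree] = {}
    for i, (c, start, end) in enumerate(zip(m_chrom, motifs["start"], motifs["end"])):
        # IntervalTree is half-open; +1 on end makes [start, end] inclusive
        trees.setdefault(c, IntervalTree()).addi(int(start), int(end) + 1, i)

    pairs = []
    for j, (c, pos) in enumerate(zip(s_chrom, snps["pos"])):
        tree = trees.get(c)
        if tree is None:
            continue
        for iv in tree.at(int(pos)):
            pairs.append((j, iv.data))
    if not pairs:
        return pd.DataFrame(columns=list(snps.columns) + [f"{c}_motif" if c in snps.columns else c for c in motifs.columns])
    sj, mi = zip(*pairs)
    left = snps.iloc[list(sj)].reset_index(drop=True)
    right = motifs.iloc[list(mi)].reset_index(drop=True)
    right = right.rename(columns={c: f"{c}_motif" for c in right.columns if c in left.columns})
    return pd.concat([left, right], axis=1)


def phase2_alpha(n_tested: int) -> float:
    """Region-wise significance level alpha = 0.05 / sqrt(N)."""
    if n_tested < 1:
        raise AnalysisError("phase2_alpha requires n_tested >= 1")
    return 0.05 / np.sqrt(n_tested)


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni family-wise adjustment: p_adj = min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, p * p.size)


def estimate_pi0(p_values, lambdas=None) -> float:
    """Storey's null-proportion estimate via the lambda-grid smoother.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed on the grid
    and smoothed with a cubic polynomial evaluated at the largest lambda;
    the estimate is clamped into (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)
    m = p.size
    pi0s = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if len(lambdas) >= 4:
        coef = np.polyfit(lambdas, pi0s, 3)
        pi0 = float(np.polyval(coef, lambdas.max()))
    else:
        pi0 = float(pi0s[-1])
    if pi0 > 1.0:
        warnings.warn(f"pi0 estimate {pi0:.3f} > 1; clamped to 1")
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_qvalues(p_values, pi0: float | str = "estimate") -> np.ndarray:
    """Storey q-values; with pi0 = 1 these are exactly Benjamini-Hochberg.

    q_(i) = min over t >= p_(i) of pi0 * m * t / #{p <= t}, enforced
    monotone non-decreasing in p, computed by the standard step-up sweep.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise AnalysisError("storey_qvalues requires at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise AnalysisError("p-values must lie in (0, 1]")
    pi0_val = estimate_pi0(p) if pi0 == "estimate" else float(pi0)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = pi0_val * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def ld_proxy_expand(snps: pd.DataFrame, ld_table: pd.DataFrame, r2_min: float = 0.80) -> pd.DataFrame:
    """Attach LD proxies (r^2 strictly above ``r2_min``) to an association table.

    For every genotyped SNP in ``snps``, partners in the LD table become
    additional rows inheriting the source association p-value, with
    provenance recorded in a ``proxy_for`` column.  Single hop only; a
    proxy of a proxy is never chained.  Partner coordinates come from
    optional chrom_b/pos_b columns; partners without coordinates are
    attached without a position (excluded from later overlap).
    """
    ld = ld_table.copy()
    sym = ld.rename(columns={"rsid_a": "rsid_b", "rsid_b": "rsid_a"})
    if "chrom_b" in ld.columns:
        sym = sym.drop(columns=[c for c in ("chrom_b", "pos_b") if c in sym.columns])
    ld = pd.concat([ld, sym], ignore_index=True, sort=False)

    known = set(snps["rsid"])
    out = snps.copy()
    out["proxy_for"] = ""
    new_rows = []
    for row in ld.itertuples(index=False):
        if row.r2 <= r2_min:       # strict inequality: r2 == 0.80 is NOT a proxy
            continue
        if row.rsid_a in known and row.rsid_b not in known:
            src = snps.loc[snps["rsid"] == row.rsid_a].iloc[0]
            new_rows.append(
                {
                    "rsid": row.rsid_b,
                    "chrom": getattr(row, "chrom_b", src["chrom"]) if hasattr(row, "chrom_b") else src["chrom"],
                    "pos": int(getattr(row, "pos_b", -1)) if hasattr(row, "pos_b") else -1,
                    "p_value": src["p_value"],
                    "gene": src.get("gene", ""),
                    "proxy_for": row.rsid_a,
                }
            )
    if new_rows:
        extra = pd.DataFrame(new_rows).drop_duplicates(subset="rsid")
        extra = extra[~extra["rsid"].isin(known)]
        out = pd.concat([out, extra], ignore_index=True, sort=False)
    return out


def run_phases(
    snps: pd.DataFrame,
    motifs: pd.DataFrame,
    gene_sets: dict[str, list[str]] | None = None,
    ld_table: pd.DataFrame | None = None,
    *,
    phase3_p: float = PHASE3_P,
    phase2_mode: str = "sqrt",
    pi0: float | str = "estimate",
) -> list[PhaseReport]:
    """Execute the three filtering phases and return one report per phase.

    ``phase2_mode='sqrt'`` applies alpha = 0.05/sqrt(N) per motif-encoding
    region; 'bonferroni' substitutes 0.05/N.
    """
    if ld_table is not None and len(ld_table):
        snps = ld_proxy_expand(snps, ld_table)

    # Phase 1: enumeration
    pairs = overlap_snps(snps, motifs)
    mir_col = "mir_id" if "mir_id" in motifs.columns else None
    region_key = [c for c in ("mir_id", "gene_motif", "gene", "chrom_motif", "start", "end") if c in pairs.columns]
    phase1_counts = (
        pairs.groupby(region_key).size().rename("n_snps").reset_index()
        if len(pairs)
        else pd.DataFrame(columns=region_key + ["n_snps"])
    )
    reports = [PhaseReport(phase=1, n_tested=len(pairs), alpha_used=None, hits=phase1_counts,
                           notes=[f"{len(motifs)} motif regions, {len(snps)} SNPs in panel"])]

    # Phase 2: motif-resident SNPs at the region-adjusted alpha
    hits2 = []
    if len(pairs):
        group_cols = [c for c in ("mir_id", "gene_motif", "gene") if c in pairs.columns] or ["chrom"]
        for _, region in pairs.groupby(group_cols):
            n = len(region)
            alpha = phase2_alpha(n) if phase2_mode == "sqrt" else 0.05 / n
            sig = region[region["p_value"] < alpha].copy()
            sig["alpha_used"] = alpha
            sig["n_region"] = n
            hits2.append(sig)
    hits2_df = pd.concat(hits2, ignore_index=True) if hits2 else pd.DataFrame(
        columns=list(pairs.columns) + ["alpha_used", "n_region"]
    )
    reports.append(PhaseReport(phase=2, n_tested=len(pairs),
                               alpha_used=phase2_alpha(len(pairs)) if len(pairs) else None,
                               hits=hits2_df))

    # Phase 3: all SNPs in each miRNA's target-gene set
    hits3 = []
    n3 = 0
    notes3 = []
    for mir, genes in (gene_sets or {}).items():
        if not genes:
            notes3.append(f"{mir}: empty gene set, skipped")
            logger.warning("Phase 3 skipped for %s: empty gene set", mir)
            continue
        pool = snps[snps["gene"].isin(set(genes))].copy()
        if pool.empty:
            notes3.append(f"{mir}: no SNPs in gene set")
            continue
        n3 += len(pool)
        pool["mir_id"] = mir
        pool["p_bonferroni"] = bonferroni(pool["p_value"].to_numpy())
        pool["q_value"] = storey_qvalues(pool["p_value"].to_numpy(), pi0=pi0)
        hits3.append(pool[pool["p_value"] < phase3_p])
    hits3_df = pd.concat(hits3, ignore_index=True) if hits3 else pd.DataFrame(
        columns=list(snps.columns) + ["mir_id", "p_bonferroni", "q_value"]
    )
    reports.append(PhaseReport(phase=3, n_tested=n3, alpha_used=phase3_p, hits=hits3_df, notes=notes3))
    return reports
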