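"""Motif overlap, multiplicity adjustments and the three-phase SNP filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import vitremir.mirsnp as ms
from vitremir.errors import AnalysisError


def snp_df(rows):
    return pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "p_value", "gene"])


def brute_force_overlap(snps, motifs):
    pairs = set()
    for j, s in snps.iterrows():
        for i, m in motifs.iterrows():
            if ms._norm_chrom(s["chrom"]) == ms._norm_chrom(m["chrom"]) and m["start"] <= s["pos"] <= m["end"]:
                pairs.add((s["rsid"], i))
    return pairs


class TestOverlap:
    def test_documented_binding_site_contains_snp(self, hla_g_motif):
        # the HLA-G 3'UTR motif on chr6 spans 29830959-29830978
        snps = snp_df([("rs1063320", "6", 29830970, 0.026, "HLA-G")])
        pairs = ms.overlap_snps(snps, hla_g_motif)
        assert len(pairs) == 1
        assert pairs["rsid"].iloc[0] == "rs1063320"

    @pytest.mark.parametrize("pos, hit", [(29830959, True), (29830978, True),
                                          (29830958, False), (29830979, False)])
    def test_inclusive_boundaries(self, hla_g_motif, pos, hit):
        snps = snp_df([("rsX", "6", pos, 0.5, "")])
        assert (len(ms.overlap_snps(snps, hla_g_motif)) == 1) == hit

    def test_mixed_chromosome_naming_normalized_with_warning(self, hla_g_motif):
        snps = snp_df([("rsX", "chr6", 29830970, 0.5, "")])
        with pytest.warns(UserWarning, match="naming"):
            pairs = ms.overlap_snps(snps, hla_g_motif)
        assert len(pairs) == 1

    def test_agrees_with_double_loop_oracle(self, rng):
        n_snps, n_motifs = 2000, 150
        motif_start = rng.integers(1, 10_000, size=n_motifs)
        motifs = pd.DataFrame(
            {
                "chrom": rng.choice(["1", "6", "15"], size=n_motifs),
                "start": motif_start,
                "end": motif_start + rng.integers(5, 30, size=n_motifs),
                "mir_id": "m", "gene": "g",
            }
        )
        snps = snp_df(
            [(f"rs{i}", str(c), int(p), 0.5, "")
             for i, (c, p) in enumerate(zip(rng.choice(["1", "6", "15"], size=n_snps),
                                            rng.integers(1, 10_050, size=n_snps)))]
        )
        got = ms.overlap_snps(snps, motifs)
        got_pairs = set(zip(got["rsid"], got.index))  # index not comparable; compare counts per rsid
        oracle = brute_force_overlap(snps, motifs)
        assert len(got) == len(oracle)
        assert set(got["rsid"]) == {r for r, _ in oracle}


class TestAdjustments:
    @pytest.mark.parametrize("n, expected", [(1, 0.05), (4, 0.025), (100, 0.005)])
    def test_sqrt_n_alpha(self, n, expected):
        assert ms.phase2_alpha(n) == pytest.approx(expected)

    def test_zero_tested_rejected(self):
        with pytest.raises(AnalysisError):
            ms.phase2_alpha(0)

    def test_bonferroni_closed_forms(self):
        np.testing.assert_allclose(ms.bonferroni([0.01]), [0.01])
        np.testing.assert_allclose(ms.bonferroni([0.01] * 10), [0.1] * 10)
        assert ms.bonferroni([0.5] * 10)[0] == 1.0  # capped

    def test_bonferroni_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(1e-6, 1, size=200)
        expected = multipletests(p, method="bonferroni")[1]
        np.testing.assert_allclose(ms.bonferroni(p), expected, atol=1e-12)


class TestStoreyQvalues:
    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0, exclude_min=False),
                    min_size=1, max_size=200))
    @settings(max_examples=60, deadline=None)
    def test_pi0_one_equals_benjamini_hochberg(self, pvals):
        from statsmodels.stats.multitest import multipletests

        q = ms.storey_qvalues(np.array(pvals), pi0=1.0)
        bh = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_single_pvalue(self):
        assert ms.storey_qvalues([0.04], pi0=1.0)[0] == pytest.approx(0.04)

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(1e-6, 1, size=500)
        q = ms.storey_qvalues(p, pi0="estimate")
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_null_panel_yields_no_discoveries(self):
        hits = 0
        for seed in range(5):
            p = np.random.default_rng(seed).uniform(0, 1, size=1000)
            p = np.clip(p, 1e-12, 1.0)
            hits += (ms.storey_qvalues(p) < 0.05).sum()
        assert hits <= 2

    def test_pi0_estimate_clamped_with_warning(self, rng):
        # p-values piled near 1 push the raw estimate above 1
        p = np.clip(rng.uniform(0.8, 1.0, size=300), None, 1.0)
        with pytest.warns(UserWarning, match="clamped"):
            pi0 = ms.estimate_pi0(p)
        assert 0 < pi0 <= 1.0

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(AnalysisError):
            ms.storey_qvalues([0.0, 0.5])


class TestLdProxy:
    def _snps(self):
        return snp_df([("rsA", "6", 100, 0.001, "HLA-G")])

    def test_boundary_r2_not_a_proxy(self):
        ld = pd.DataFrame({"rsid_a": ["rsA"], "rsid_b": ["rsB"], "r2": [0.80]})
        out = ms.ld_proxy_expand(self._snps(), ld)
        assert "rsB" not in set(out["rsid"])

    def test_strong_ld_attached_with_provenance(self):
        ld = pd.DataFrame({"rsid_a": ["rsA"], "rsid_b": ["rsB"], "r2": [0.95],
                           "chrom_b": ["6"], "pos_b": [150]})
        out = ms.ld_proxy_expand(self._snps(), ld)
        row = out[out["rsid"] == "rsB"].iloc[0]
        assert row["proxy_for"] == "rsA"
        assert row["pos"] == 150
        assert row["p_value"] == pytest.approx(0.001)

    def test_no_chaining_single_hop(self):
        ld = pd.DataFrame({"rsid_a": ["rsA", "rsB"], "rsid_b": ["rsB", "rsC"],
                           "r2": [0.95, 0.95]})
        out = ms.ld_proxy_expand(self._snps(), ld)
        assert "rsB" in set(out["rsid"])
        assert "rsC" not in set(out["rsid"])  # proxy of a proxy never chained


class TestRunPhases:
    def test_empty_motif_overlap_still_reports_phase1(self, hla_g_motif):
        snps = snp_df([("rs1", "2", 500, 0.01, "")])
        reports = ms.run_phases(snps, hla_g_motif, gene_sets={})
        assert reports[0].phase == 1 and reports[0].n_tested == 0
        assert len(reports[1].hits) == 0

    def test_planted_motif_snp_passes_sqrt_alpha(self, hla_g_motif):
        # 4 motif-resident SNPs -> alpha = 0.05/2 = 0.025; one planted at 1e-5
        rows = [("rs_hit", "6", 29830960, 1e-5, "HLA-G")] + [
            (f"rs{i}", "6", 29830960 + i, 0.5, "HLA-G") for i in range(1, 4)
        ]
        reports = ms.run_phases(snp_df(rows), hla_g_motif)
        phase2 = reports[1]
        assert list(phase2.hits["rsid"]) == ["rs_hit"]
        assert phase2.hits["alpha_used"].iloc[0] == pytest.approx(0.025)

    def test_phase3_threshold(self):
        rows = [("rs1", "1", 10, 0.004, "NFKB1"), ("rs2", "1", 20, 0.5, "NFKB1"),
                ("rs3", "1", 30, 0.9, "NFKB1")]
        motifs = pd.DataFrame([{"chrom": "1", "start": 1000, "end": 1019,
                                "mir_id": "miR-146a-5p", "gene": "NFKB1"}])
        reports = ms.run_phases(snp_df(rows), motifs,
                                gene_sets={"miR-146a-5p": ["NFKB1"]}, pi0=1.0)
        phase3 = reports[2]
        assert list(phase3.hits["rsid"]) == ["rs1"]
        assert phase3.hits["p_bonferroni"].iloc[0] == pytest.approx(0.012)

    def test_empty_gene_set_skipped_with_note(self, hla_g_motif):
        snps = snp_df([("rs1", "6", 29830970, 0.001, "HLA-G")])
        reports = ms.run_phases(snps, hla_g_motif, gene_sets={"miR-152-3p": []})
        assert any("empty gene set" in n for n in reports[2].notes)
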