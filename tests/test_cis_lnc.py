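"""Genomic context classification and 300-kb cis linkage."""

import numpy as np
import pandas as pd
import pytest

import epimarray as em
from epimarray.cis_lnc import (GeneModel, classify_context, find_cis_genes,
                               genes_by_chromosome, interval_gap, link_to_de,
                               select_signflip_lncrnas)


@pytest.fixture()
def gene():
    # [1000, 11000), exons [1000,3000) and [9000,11000), '+' strand
    return GeneModel(symbol="G1", chrom="chr1", start=1000, end=11000, strand="+",
                     exons=((1000, 3000), (9000, 11000)))


class TestClassifyContext:
    def test_same_strand_inside_intron(self, gene):
        assert classify_context("chr1", 4000, 5000, "+", [gene]) == "intron-overlap"

    def test_same_strand_over_exon(self, gene):
        assert classify_context("chr1", 2000, 2500, "+", [gene]) == "exon-overlap"

    def test_opposite_strand_over_exon_is_natural_antisense(self, gene):
        assert classify_context("chr1", 2000, 2500, "-", [gene]) == "natural-antisense"

    def test_opposite_strand_inside_intron(self, gene):
        assert classify_context("chr1", 4000, 5000, "-", [gene]) == "intronic-antisense"

    def test_divergent_tss_within_1kb_is_bidirectional(self, gene):
        # '-' lncRNA upstream of the '+' gene, TSS (= end) 500 bp away
        assert classify_context("chr1", 100, 500, "-", [gene]) == "bidirectional"

    def test_divergent_tss_beyond_1kb_is_intergenic(self, gene):
        assert classify_context("chr1", 100, 11000 - 11001, "-", [gene]) != ""
        assert classify_context("chr2", 0, 100, "+", [gene]) == "intergenic"
        assert classify_context("chr1", 20000, 21000, "+", [gene]) == "intergenic"

    def test_convergent_tss_is_not_bidirectional(self, gene):
        # '-' lncRNA downstream of the gene end: TSS near nothing, convergent
        assert classify_context("chr1", 11200, 11900, "-", [gene]) == "intergenic"

    def test_exon_precedence_over_intron(self, gene):
        # spans exon boundary into intron: exon wins
        assert classify_context("chr1", 2500, 4000, "+", [gene]) == "exon-overlap"

    def test_unknown_chromosome_warns_intergenic(self, gene, caplog):
        with caplog.at_level("WARNING"):
            cls = classify_context("chrZ", 0, 100, "+", [gene])
        assert cls == "intergenic"
        assert "no gene models" in caplog.text


class TestFindCisGenes:
    def _genes(self):
        return [GeneModel("A", "chr1", 0, 10_000, "+", ((0, 10_000),)),
                GeneModel("B", "chr1", 260_000, 270_000, "+", ((260_000, 270_000),)),
                GeneModel("C", "chr1", 400_000, 410_000, "+", ((400_000, 410_000),)),
                GeneModel("D", "chr2", 0, 10_000, "+", ((0, 10_000),))]

    def test_window_boundary_inclusive_at_exactly_300kb(self):
        genes = [GeneModel("G", "chr1", 310_000, 320_000, "+", ((310_000, 320_000),))]
        links = find_cis_genes("L", "chr1", 0, 10_000, genes, window=300_000)
        assert [l.gene_symbol for l in links] == ["G"]
        assert links[0].distance == 300_000

    def test_gene_one_bp_past_window_excluded(self):
        genes = [GeneModel("G", "chr1", 310_001, 320_000, "+", ((310_001, 320_000),))]
        assert find_cis_genes("L", "chr1", 0, 10_000, genes, window=300_000) == []

    def test_overlapping_gene_distance_zero(self):
        genes = self._genes()
        links = find_cis_genes("L", "chr1", 5_000, 6_000, genes)
        assert links[0].gene_symbol == "A" and links[0].distance == 0

    def test_links_sorted_and_same_chromosome_only(self):
        links = find_cis_genes("L", "chr1", 10_000, 11_000, self._genes())
        assert [l.gene_symbol for l in links] == ["A", "B"]
        assert all(l.distance <= 300_000 for l in links)

    def test_matches_bruteforce_on_synthetic_layout(self, small_dataset):
        ann, genes = small_dataset["annotation"], small_dataset["genes"]
        by = genes_by_chromosome(genes)
        for r in ann[ann["rna_class"] == "lncRNA"].itertuples():
            got = {(l.gene_symbol, l.distance)
                   for l in find_cis_genes(r.transcript_id, r.chrom, r.start,
                                           r.end, by)}
            expect = set()
            for g in genes:  # plain all-pairs scan
                if g.chrom != r.chrom:
                    continue
                gap = max(g.start - r.end, r.start - g.end, 0)
                if gap <= 300_000:
                    expect.add((g.symbol, gap))
            assert got == expect, r.transcript_id

    def test_enlarging_window_never_removes_links(self):
        genes = self._genes()
        small = find_cis_genes("L", "chr1", 0, 1_000, genes, window=100_000)
        large = find_cis_genes("L", "chr1", 0, 1_000, genes, window=500_000)
        assert {l.gene_symbol for l in small} <= {l.gene_symbol for l in large}

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            find_cis_genes("L", "chr1", 0, 100, self._genes(), window=0)


def test_interval_gap_conventions():
    assert interval_gap(0, 10, 10, 20) == 0       # touching half-open
    assert interval_gap(0, 10, 11, 20) == 1
    assert interval_gap(11, 20, 0, 10) == 1
    assert interval_gap(0, 10, 5, 20) == 0        # overlap


class TestLinkToDe:
    def _links(self):
        return pd.DataFrame({
            "lncrna_id": ["L1", "L1", "L2", "L3", "L3"],
            "gene_symbol": ["GA", "GB", "GB", "GC", "GD"],
            "distance": [0, 100, 50, 10, 20],
            "relation": ["intergenic"] * 5,
        })

    def _expr(self, calls):
        return pd.DataFrame({"transcript_id": [f"t{g}" for g in calls],
                             "gene_symbol": list(calls),
                             "rna_class": "mRNA",
                             "call": list(calls.values())})

    def test_exhaustive_join(self):
        expr = self._expr({"GA": "up", "GB": "down", "GC": "none", "GD": "none"})
        table, de_genes, n_lnc = link_to_de(self._links(), expr)
        assert de_genes == {"GA", "GB"}
        assert n_lnc == 2        # L1 and L2
        assert len(table) == 3   # (L1,GA), (L1,GB), (L2,GB)

    def test_shared_de_gene_counted_once(self):
        expr = self._expr({"GA": "none", "GB": "up", "GC": "none", "GD": "none"})
        _, de_genes, _ = link_to_de(self._links(), expr)
        assert de_genes == {"GB"}

    def test_no_de_genes_empty(self):
        expr = self._expr({"GA": "none", "GB": "none", "GC": "none", "GD": "none"})
        table, de_genes, n_lnc = link_to_de(self._links(), expr)
        assert table.empty and de_genes == set() and n_lnc == 0


class TestSignflip:
    def _meth(self, calls):
        return pd.DataFrame({"transcript_id": list(calls),
                             "gene_symbol": list(calls),
                             "rna_class": ["lncRNA" if t.startswith("lnc") else "mRNA"
                                           for t in calls],
                             "call": list(calls.values())})

    def test_flip_directions(self):
        a = self._meth({"lnc1": "hyper", "lnc2": "hypo", "lnc3": "hyper", "m1": "hyper"})
        b = self._meth({"lnc1": "hypo", "lnc2": "hyper", "lnc3": "hyper", "m1": "hypo"})
        hyper_hypo, hypo_hyper = select_signflip_lncrnas(a, b)
        assert hyper_hypo == {"lnc1"}        # mRNA m1 excluded
        assert hypo_hyper == {"lnc2"}

    def test_planted_flips_recovered(self, small_dataset, quantified):
        """Effects planted only in M1-L flip sign between M1-L/M0-L and
        M2-L/M1-L; recovered exactly for strongly shifted lncRNAs."""
        ann, truth = small_dataset["annotation"], small_dataset["truth"]
        rec_a = em.run_comparison(quantified, em.Comparison("M1-L", "M0-L"),
                                  "methylation", annotation=ann)
        rec_b = em.run_comparison(quantified, em.Comparison("M2-L", "M1-L"),
                                  "methylation", annotation=ann)
        hyper_hypo, hypo_hyper = select_signflip_lncrnas(rec_a, rec_b)
        shifts = truth.meth_shift
        lnc = [t for t in shifts.index if t.startswith("lncRNA")]
        expect_hh = {t for t in lnc if shifts.loc[t, "M1-L"] > 0}
        expect_hy = {t for t in lnc if shifts.loc[t, "M1-L"] < 0}
        assert hyper_hypo == expect_hh
        assert hypo_hyper == expect_hy
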