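import numpy as np
import pytest

from postasm.gene_set_filter import (
    RULE_ENCOMPASSED,
    RULE_MIN_LENGTH,
    RULE_UNSUPPORTED,
    ExpressionTable,
    apply_final_filter,
    encompassment_fraction,
    filter_by_aed,
    focal_specific_single_copy,
    gene_tpm,
    merged_tpm,
    read_expression_table,
    select_primary,
    write_expression_table,
)
from postasm.io_formats import GeneModel, GenomicInterval, Transcript


def make_gene(gene_id, start, end, aeds=(0.1,), exon_counts=None, chrom="chr1"):
    """Gene whose isoform i has AED aeds[i]; exon_counts[i] exons tiling the span."""
    exon_counts = exon_counts or [1] * len(aeds)
    transcripts = []
    for i, (aed, n_exons) in enumerate(zip(aeds, exon_counts)):
        if n_exons == 1:
            exons = (GenomicInterval(chrom, start, end, "+"),)
        else:
            width = (end - start) // (2 * n_exons - 1)
            exons = tuple(
                GenomicInterval(
                    chrom, start + 2 * j * width, start + (2 * j + 1) * width, "+"
                )
                for j in range(n_exons)
            )
        transcripts.append(Transcript(f"{gene_id}.t{i + 1}", gene_id, exons, aed))
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, "+"), tuple(transcripts))


def flat_expr(genes, value):
    """Single-sample table assigning every isoform the same TPM."""
    return ExpressionTable(
        samples=("merged",),
        tpm={t.id: {"merged": value} for g in genes for t in g.transcripts},
    )


class TestFilterByAed:
    def test_boundary_050_kept(self):
        gene = make_gene("g", 0, 1000, aeds=(0.50, 0.9))
        assert filter_by_aed([gene]) == [gene]

    def test_051_removed(self):
        gene = make_gene("g", 0, 1000, aeds=(0.51, 0.9))
        assert filter_by_aed([gene]) == []

    def test_all_zero_identity(self):
        genes = [make_gene(f"g{i}", i * 2000, i * 2000 + 1000, aeds=(0.0,)) for i in range(5)]
        assert filter_by_aed(genes) == genes


class TestSelectPrimary:
    def test_lowest_aed(self):
        gene = make_gene("g", 0, 1000, aeds=(0.2, 0.4))
        assert select_primary(gene).aed == 0.2

    def test_tie_broken_by_exonic_length(self):
        t_short = Transcript(
            "g.a", "g", (GenomicInterval("c", 0, 900, "+"),), 0.3
        )
        t_long = Transcript(
            "g.b", "g", (GenomicInterval("c", 0, 1200, "+"),), 0.3
        )
        gene = GeneModel("g", GenomicInterval("c", 0, 1200, "+"), (t_short, t_long))
        assert select_primary(gene).id == "g.b"

    def test_single_transcript_identity(self):
        gene = make_gene("g", 0, 500)
        assert select_primary(gene) is gene.transcripts[0]

    def test_full_tie_lexicographic(self):
        t1 = Transcript("g.b", "g", (GenomicInterval("c", 0, 100, "+"),), 0.3)
        t2 = Transcript("g.a", "g", (GenomicInterval("c", 0, 100, "+"),), 0.3)
        gene = GeneModel("g", GenomicInterval("c", 0, 100, "+"), (t1, t2))
        assert select_primary(gene).id == "g.a"


class TestGeneTpm:
    def test_isoform_sum(self):
        gene = make_gene("g", 0, 1000, aeds=(0.1, 0.2))
        expr = ExpressionTable(
            samples=("s1",),
            tpm={"g.t1": {"s1": 0.6}, "g.t2": {"s1": 0.6}},
        )
        assert gene_tpm(expr, gene) == {"s1": pytest.approx(1.2)}

    def test_single_isoform_identity(self):
        gene = make_gene("g", 0, 1000)
        expr = ExpressionTable(samples=("s1",), tpm={"g.t1": {"s1": 7.25}})
        assert gene_tpm(expr, gene) == {"s1": 7.25}

    def test_missing_isoform_rejected(self):
        gene = make_gene("g", 0, 1000)
        expr = ExpressionTable(samples=("s1",), tpm={})
        with pytest.raises(KeyError):
            gene_tpm(expr, gene)

    def test_random_tables_vs_independent_summation(self, rng):
        genes = [
            make_gene(f"g{i}", i * 3000, i * 3000 + 2000, aeds=(0.1, 0.2, 0.3))
            for i in range(10)
        ]
        samples = ("a", "b", "c")
        tpm = {
            t.id: {s: float(rng.uniform(0, 50)) for s in samples}
            for g in genes
            for t in g.transcripts
        }
        expr = ExpressionTable(samples=samples, tpm=tpm)
        for gene in genes:
            got = gene_tpm(expr, gene)
            for s in samples:
                expect = sum(tpm[t.id][s] for t in gene.transcripts)
                assert got[s] == pytest.approx(expect)

    def test_roundtrip(self, tmp_path, rng):
        samples = ("x", "y")
        tpm = {f"t{i}": {"x": float(i), "y": float(2 * i)} for i in range(20)}
        table = ExpressionTable(samples=samples, tpm=tpm)
        path = tmp_path / "tpm.tsv"
        write_expression_table(table, path)
        assert read_expression_table(path) == table

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValueError):
            ExpressionTable(samples=("s",), tpm={"t": {"s": -1.0}})


class TestEncompassment:
    def test_nested(self):
        a = GenomicInterval("c", 100, 200)
        b = GenomicInterval("c", 0, 1000)
        assert encompassment_fraction(a, b) == 1.0

    def test_disjoint(self):
        a = GenomicInterval("c", 0, 100)
        b = GenomicInterval("c", 500, 600)
        assert encompassment_fraction(a, b) == 0.0

    def test_half_overlap(self):
        a = GenomicInterval("c", 0, 100)
        b = GenomicInterval("c", 50, 200)
        assert encompassment_fraction(a, b) == 0.5

    def test_different_chromosomes(self):
        a = GenomicInterval("c1", 0, 100)
        b = GenomicInterval("c2", 0, 100)
        assert encompassment_fraction(a, b) == 0.0


class TestFocalSpecificSingleCopy:
    def test_identification(self):
        membership = [
            ("OG1", "focal", "gA"),  # focal-specific single copy
            ("OG2", "focal", "gB"),
            ("OG2", "other", "xB"),  # shared
            ("OG3", "focal", "gC"),
            ("OG3", "focal", "gD"),  # focal-specific but two copies
        ]
        gene_to_og, specific = focal_specific_single_copy(membership, "focal")
        assert specific == {"OG1"}
        assert gene_to_og == {"gA": "OG1", "gB": "OG2", "gC": "OG3", "gD": "OG3"}


class TestApplyFinalFilter:
    def _fixture(self):
        # six genes exercising each clause
        genes = [
            # long multi-exon, focal-specific: kept (single-exon clause vacuous)
            make_gene("g_multi", 0, 2_000, aeds=(0.1,), exon_counts=[3]),
            # single-exon specific, TPM 0.5: removed (unsupported)
            make_gene("g_lowtpm", 10_000, 11_000),
            # single-exon specific, TPM 2, un-encompassed: kept
            make_gene("g_free", 20_000, 21_000),
            # single-exon specific, TPM 2, 95% encompassed: removed
            make_gene("g_nested", 30_000, 31_000),
            make_gene("g_host", 29_970, 31_100, aeds=(0.2,), exon_counts=[2]),
            # single-exon in a shared orthogroup, TPM 0: kept (clause needs specific OG)
            make_gene("g_shared", 40_000, 41_000),
            # 30-base gene: removed (min length)
            make_gene("g_tiny", 50_000, 50_030),
        ]
        membership = [
            ("OG1", "focal", "g_multi"),
            ("OG2", "focal", "g_lowtpm"),
            ("OG3", "focal", "g_free"),
            ("OG4", "focal", "g_nested"),
            ("OG5", "focal", "g_host"),
            ("OG5", "other", "x_host"),
            ("OG6", "focal", "g_shared"),
            ("OG6", "other", "x_shared"),
            ("OG7", "focal", "g_tiny"),
        ]
        tpm = {
            "g_multi.t1": 5.0,
            "g_lowtpm.t1": 0.5,
            "g_free.t1": 2.0,
            "g_nested.t1": 2.0,
            "g_host.t1": 3.0,
            "g_shared.t1": 0.0,
            "g_tiny.t1": 9.0,
        }
        expr = ExpressionTable(
            samples=("merged",), tpm={k: {"merged": v} for k, v in tpm.items()}
        )
        return genes, membership, expr

    def test_hand_oracle(self):
        genes, membership, expr = self._fixture()
        report = apply_final_filter(genes, membership, expr, "focal")
        assert set(report.kept) == {"g_multi", "g_free", "g_host", "g_shared"}
        assert report.rules_for("g_lowtpm") == (RULE_UNSUPPORTED,)
        assert report.rules_for("g_nested") == (RULE_ENCOMPASSED,)
        assert report.rules_for("g_tiny") == (RULE_MIN_LENGTH,)

    def test_length_boundary(self):
        g49 = make_gene("g49", 0, 49)
        g50 = make_gene("g50", 1000, 1050)
        expr = flat_expr([g49, g50], 10.0)
        report = apply_final_filter([g49, g50], [], expr, "focal")
        assert report.rules_for("g49") == (RULE_MIN_LENGTH,)
        assert report.rules_for("g50") == ()
        assert set(report.kept) == {"g50"}

    def test_no_specific_ogs_only_length_rule(self):
        genes = [
            make_gene("gA", 0, 40),
            make_gene("gB", 1000, 2000),
        ]
        membership = [("OG1", "focal", "gA"), ("OG1", "other", "x"),
                      ("OG2", "focal", "gB"), ("OG2", "other", "y")]
        expr = flat_expr(genes, 0.0)  # no expression anywhere
        report = apply_final_filter(genes, membership, expr, "focal")
        assert set(report.removed) == {"gA"}
        assert report.rules_for("gA") == (RULE_MIN_LENGTH,)

    def test_tpm_exactly_one_boundary(self):
        gene = make_gene("g1", 0, 1000)
        other = make_gene("g2", 5000, 6000)
        membership = [("OG1", "focal", "g1"), ("OG2", "focal", "g2"),
                      ("OG2", "other", "x")]
        expr = flat_expr([gene, other], 1.0)
        report = apply_final_filter([gene, other], membership, expr, "focal")
        d = next(x for x in report.dispositions if x.gene_id == "g1")
        assert d.kept  # removal needs TPM < 1
        assert "tpm_boundary" in d.notes

    def test_idempotent(self):
        genes, membership, expr = self._fixture()
        first = apply_final_filter(genes, membership, expr, "focal")
        survivors = [g for g in genes if g.gene_id in set(first.kept)]
        second = apply_final_filter(survivors, membership, expr, "focal")
        assert set(second.kept) == set(first.kept)
        assert not second.removed

    def test_merged_tpm_modes(self):
        gene = make_gene("g", 0, 1000)
        expr = ExpressionTable(
            samples=("a", "b"), tpm={"g.t1": {"a": 1.0, "b": 3.0}}
        )
        assert merged_tpm(expr, gene, how="mean") == pytest.approx(2.0)
        assert merged_tpm(expr, gene, how="sum") == pytest.approx(4.0)
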