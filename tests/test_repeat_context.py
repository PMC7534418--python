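import numpy as np
import pytest

from postasm.io_formats import GenomicInterval, RepeatFeature
from postasm.repeat_context import (
    GENIC,
    NON_GENIC,
    GeneIndex,
    class_count_ratio,
    classify_repeat,
    classify_repeats,
    context_composition,
    merge_intervals,
    window_coverage,
)

from .conftest import make_repeat


def gene_span(chrom="chr1", start=0, end=1000, strand="+"):
    return GenomicInterval(chrom, start, end, strand)


class TestClassifyRepeat:
    def test_inside_same_strand(self):
        genes = GeneIndex([gene_span("chr1", 100, 2000, "+")])
        call = classify_repeat(make_repeat("chr1", 500, 800, "+"), genes)
        assert (call.context, call.strand_relation) == (GENIC, "same")

    def test_different_strand(self):
        genes = GeneIndex([gene_span("chr1", 100, 2000, "-")])
        call = classify_repeat(make_repeat("chr1", 500, 800, "+"), genes)
        assert call.strand_relation == "different"

    def test_no_overlap(self):
        genes = GeneIndex([gene_span("chr1", 100, 200)])
        call = classify_repeat(make_repeat("chr1", 5000, 5100), genes)
        assert (call.context, call.strand_relation) == (NON_GENIC, "unstranded")

    def test_single_base_overlap_is_genic(self):
        genes = GeneIndex([gene_span("chr1", 100, 200, "+")])
        call = classify_repeat(make_repeat("chr1", 199, 300, "+"), genes)
        assert call.context == GENIC
        call = classify_repeat(make_repeat("chr1", 200, 300, "+"), genes)
        assert call.context == NON_GENIC  # half-open: no shared base

    def test_leftmost_gene_wins_ties(self):
        genes = GeneIndex(
            [gene_span("chr1", 100, 600, "+"), gene_span("chr1", 400, 900, "-")]
        )
        call = classify_repeat(make_repeat("chr1", 450, 500, "+"), genes)
        assert call.strand_relation == "same"  # from the start=100 gene

    def test_unstranded_repeat(self):
        genes = GeneIndex([gene_span("chr1", 100, 600, "+")])
        call = classify_repeat(make_repeat("chr1", 200, 300, "."), genes)
        assert call.strand_relation == "unstranded"

    def test_oracle_equivalence_random_layouts(self, rng):
        for _ in range(1000):
            genes = [
                gene_span("chr1", s, s + rng.integers(50, 500), "+" if rng.random() < 0.5 else "-")
                for s in rng.integers(0, 5000, size=rng.integers(1, 8))
            ]
            start = int(rng.integers(0, 5400))
            rep = make_repeat("chr1", start, start + int(rng.integers(10, 400)))
            call = classify_repeat(rep, GeneIndex(genes))
            # brute force over all pairs
            hits = sorted(
                (g for g in genes if g.overlap(rep.interval) > 0),
                key=lambda g: (g.start, g.end),
            )
            if hits:
                assert call.context == GENIC
                expect = "same" if hits[0].strand == rep.interval.strand else "different"
                assert call.strand_relation == expect
            else:
                assert call.context == NON_GENIC


class TestContextComposition:
    def test_counts_partition(self, sim_genome):
        comp = context_composition(sim_genome.repeats, sim_genome.genes)
        assert comp.genic_total + comp.non_genic_total == len(sim_genome.repeats)

    def test_shares_sum_to_one(self, sim_genome):
        comp = context_composition(sim_genome.repeats, sim_genome.genes)
        if comp.genic_total:
            assert sum(r.genic_share for r in comp.per_class) == pytest.approx(1.0, abs=1e-9)
        if comp.non_genic_total:
            assert sum(r.non_genic_share for r in comp.per_class) == pytest.approx(1.0, abs=1e-9)

    def test_hand_fixture(self):
        genes = [gene_span("chr1", 0, 100_000, "+")]
        repeats = []
        # 100 genic elements: 10 LINE + 90 DNA
        for i in range(100):
            cls = "LINE" if i < 10 else "DNA"
            repeats.append(make_repeat("chr1", i * 100, i * 100 + 50, "+", cls, ""))
        # 500 non-genic elements: 5 LINE + 495 DNA
        for i in range(500):
            cls = "LINE" if i < 5 else "DNA"
            start = 200_000 + i * 100
            repeats.append(make_repeat("chr1", start, start + 50, "+", cls, ""))
        comp = context_composition(repeats, genes)
        line = next(r for r in comp.per_class if r.class_name == "LINE")
        assert line.genic_share == pytest.approx(0.10)
        assert line.non_genic_share == pytest.approx(0.01)
        assert line.fold_difference == pytest.approx(0.1)

    def test_uniform_distribution_fold_one(self):
        genes = [gene_span("chr1", 0, 10_000, "+")]
        repeats = []
        for cls in ("LTR", "LINE"):
            for i in range(10):  # 10 genic + 10 non-genic per class
                repeats.append(make_repeat("chr1", i * 100, i * 100 + 50, "+", cls, ""))
                start = 50_000 + i * 100
                repeats.append(make_repeat("chr1", start, start + 50, "+", cls, ""))
        comp = context_composition(repeats, genes)
        for row in comp.per_class:
            assert row.fold_difference == pytest.approx(1.0)

    def test_empty_repeats_rejected(self):
        with pytest.raises(ValueError):
            context_composition([], [gene_span()])

    def test_planted_genic_bias_recovered(self):
        from postasm.synthetic_data import (
            LengthMixture,
            RepeatFamilySpec,
            SimulationConfig,
            simulate_genome,
        )

        short = LengthMixture(((1.0, 300.0, 100.0),))
        config = SimulationConfig(
            seed=21,
            repeat_families=(
                RepeatFamilySpec("LTR/Gypsy", 150, short, genic_bias=0.6),
                RepeatFamilySpec("DNA/MULE-MuDR", 150, short, genic_bias=0.0),
            ),
            gene_count=60,
        )
        genome = simulate_genome(config)
        comp = context_composition(genome.repeats, genome.genes)
        gypsy = next(r for r in comp.per_class if r.class_name == "LTR")
        dna = next(r for r in comp.per_class if r.class_name == "DNA")
        # biased family must be relatively enriched in genic space
        assert gypsy.genic_count / 150 > dna.genic_count / 150
        assert gypsy.fold_difference < dna.fold_difference


class TestClassCountRatio:
    def test_published_counts(self):
        repeats = [make_repeat(cls="LTR", fam="Gypsy")] * 64_897 + [
            make_repeat(cls="LTR", fam="Copia")
        ] * 20_632
        ratio, rendered = class_count_ratio(repeats, "LTR/Gypsy", "LTR/Copia")
        assert ratio == pytest.approx(3.1455, abs=1e-4)
        assert rendered == "3:1"

    def test_equal_counts(self):
        repeats = [make_repeat(cls="A", fam="")] * 5 + [make_repeat(cls="B", fam="")] * 5
        ratio, rendered = class_count_ratio(repeats, "A", "B")
        assert (ratio, rendered) == (1.0, "1:1")

    def test_absent_denominator(self):
        with pytest.raises(ZeroDivisionError):
            class_count_ratio([make_repeat(cls="A", fam="")], "A", "B")


class TestWindowCoverage:
    def test_full_window(self):
        rows = window_coverage(
            [GenomicInterval("c", 0, 100)], {"c": 100}, window=100
        )
        assert rows == [("c", 0, 100, 1.0)]

    def test_empty_window(self):
        rows = window_coverage([], {"c": 50}, window=50)
        assert rows == [("c", 0, 50, 0.0)]

    def test_partial_final_window_normalized_by_own_size(self):
        rows = window_coverage(
            [GenomicInterval("c", 100, 130)], {"c": 130}, window=100
        )
        assert rows[1] == ("c", 100, 130, 1.0)

    def test_oracle_equivalence(self, rng):
        for _ in range(50):
            length = int(rng.integers(50, 400))
            feats = []
            for _ in range(int(rng.integers(0, 12))):
                s = int(rng.integers(0, length - 1))
                e = int(rng.integers(s + 1, length + 1))
                feats.append(GenomicInterval("c", s, e))
            window = int(rng.integers(10, 80))
            rows = window_coverage(feats, {"c": length}, window)
            # per-base brute force
            covered = np.zeros(length, dtype=bool)
            for f in feats:
                covered[f.start : f.end] = True
            for chrom, start, end, frac in rows:
                assert frac == pytest.approx(covered[start:end].mean())
                assert 0.0 <= frac <= 1.0

    def test_merging_first_changes_nothing(self, rng):
        feats = [
            GenomicInterval("c", int(s), int(s) + 30)
            for s in rng.integers(0, 300, size=20)
        ]
        merged = [
            GenomicInterval("c", int(s), int(e))
            for s, e in merge_intervals(feats)["c"]
        ]
        assert window_coverage(feats, {"c": 330}, 50) == window_coverage(
            merged, {"c": 330}, 50
        )
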