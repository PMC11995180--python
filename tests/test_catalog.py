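"""Candidate parsing and junction/genomic classification."""

import itertools

import pandas as pd
import pytest

from chimerakit.annotation_io import AnnotationIndex, GeneModel
from chimerakit.catalog import (
    ChimeraCandidate,
    Partner,
    classify_all,
    classify_genomic,
    classify_junction,
    parse_candidates,
)
from chimerakit.errors import ClassificationError, FormatError
from chimerakit.synthetic import plant_chimeras, simulate_genome_and_annotation
from tests.conftest import small_config

JUNK = "ACGT" * 15


def _frame(rows):
    cols = [
        "sample_id", "gene_5p", "contig_5p", "strand_5p", "breakpoint_5p",
        "gene_3p", "contig_3p", "strand_3p", "breakpoint_3p", "junction_seq", "score",
    ]
    return pd.DataFrame(rows, columns=cols)


def _row(g5="GA", g3="GB", bp5=200, bp3=1001, sample="P1_T"):
    return [sample, g5, "chr1", "+", bp5, g3, "chr1", "+", bp3, JUNK, 0.9]


class TestParse:
    def test_well_formed_rows(self, toy_index, tmp_path):
        p = tmp_path / "c.tsv"
        _frame([_row(), _row(sample="P2_T"), _row(sample="P3_T")]).to_csv(p, sep="\t", index=False)
        cands, dropped = parse_candidates(p, toy_index)
        assert len(cands) == 3 and dropped == 0

    def test_unknown_gene_dropped_and_counted(self, toy_index, tmp_path):
        p = tmp_path / "c.tsv"
        _frame([_row(), _row(g5="NOPE")]).to_csv(p, sep="\t", index=False)
        cands, dropped = parse_candidates(p, toy_index)
        assert len(cands) == 1 and dropped == 1

    def test_self_fusion_dropped(self, toy_index, tmp_path):
        p = tmp_path / "c.tsv"
        _frame([_row(g5="GA", g3="GA")]).to_csv(p, sep="\t", index=False)
        cands, dropped = parse_candidates(p, toy_index)
        assert len(cands) == 0 and dropped == 1

    def test_breakpoint_one_based_conversion(self, toy_index, tmp_path):
        p = tmp_path / "c.tsv"
        _frame([_row(bp5=1001, bp3=1100)]).to_csv(p, sep="\t", index=False)
        cands, _ = parse_candidates(p, toy_index)
        assert cands[0].five.breakpoint == 1000
        assert cands[0].three.breakpoint == 1099

    def test_missing_column_rejected(self, toy_index, tmp_path):
        p = tmp_path / "c.tsv"
        _frame([_row()]).drop(columns=["junction_seq"]).to_csv(p, sep="\t", index=False)
        with pytest.raises(FormatError, match="junction_seq"):
            parse_candidates(p, toy_index)


def _cand(toy, g5, bp5, g3, bp3):
    a, b = toy.get(g5), toy.get(g3)
    return ChimeraCandidate(
        five=Partner(g5, a.contig, a.strand, bp5),
        three=Partner(g3, b.contig, b.strand, bp3),
        junction_seq=JUNK,
        sample_id="P1_T",
    )


class TestJunctionClass:
    # GA '+' exons (100,200),(300,400),(500,700); GC '-' exons (5000,5200),(5400,5600)
    @pytest.mark.parametrize(
        "g5, bp5, g3, bp3, expected",
        [
            ("GA", 199, "GB", 1400, "E/E"),   # donor at exon end, acceptor at exon start
            ("GA", 199, "GB", 1450, "E/M"),
            ("GA", 150, "GB", 1400, "M/E"),
            ("GA", 150, "GB", 1450, "M/M"),
            # minus-strand 5' partner: donor edge is the genomic exon start
            ("GC", 5400, "GB", 1400, "E/E"),
            ("GC", 5401, "GB", 1400, "M/E"),
            # minus-strand 3' partner: acceptor edge is the genomic exon end
            ("GA", 199, "GC", 5199, "E/E"),
            ("GA", 199, "GC", 5150, "E/M"),
        ],
    )
    def test_rule_table(self, toy_index, g5, bp5, g3, bp3, expected):
        assert classify_junction(_cand(toy_index, g5, bp5, g3, bp3), toy_index) == expected

    def test_breakpoint_outside_span(self, toy_index):
        with pytest.raises(ClassificationError):
            classify_junction(_cand(toy_index, "GA", 50, "GB", 1400), toy_index)

    def test_boundary_tolerance(self, toy_index):
        c = _cand(toy_index, "GA", 197, "GB", 1400)  # donor edge 198, 2 off the boundary
        assert classify_junction(c, toy_index) == "M/E"
        assert classify_junction(c, toy_index, tolerance=2) == "E/E"


class TestGenomicClass:
    def test_rule_table_enumeration(self):
        """All strand/order/gap combinations against a hand-written oracle."""
        for s5, s3, order, gap in itertools.product(
            "+-", "+-", ("5first", "3first"), (500, 200_000)
        ):
            a = (1000, 2000)
            b = (2000 + gap, 3000 + gap)
            span5, span3 = (a, b) if order == "5first" else (b, a)
            genes = [
                GeneModel("F", "chr1", s5, [span5]),
                GeneModel("T", "chr1", s3, [span3]),
            ]
            index = AnnotationIndex(genes)
            cand = ChimeraCandidate(
                five=Partner("F", "chr1", s5, span5[0] + 10),
                three=Partner("T", "chr1", s3, span3[0] + 10),
                junction_seq=JUNK,
                sample_id="S",
            )
            got = classify_genomic(cand, index, readthrough_max_gap=100_000)
            # oracle: same strand, 5' transcriptionally upstream, gap <= limit
            if s5 != s3 or gap > 100_000:
                expected = "intra-chromosomal"
            elif s5 == "+":
                expected = "read-through" if order == "5first" else "intra-chromosomal"
            else:
                expected = "read-through" if order == "3first" else "intra-chromosomal"
            assert got == expected, (s5, s3, order, gap)

    def test_inter_chromosomal(self, toy_index):
        assert classify_genomic(_cand(toy_index, "GA", 150, "GD", 250), toy_index) == \
            "inter-chromosomal"

    def test_gap_threshold_is_configurable(self, toy_index):
        c = _cand(toy_index, "GA", 150, "GB", 1100)  # gap 1000-700 = 300
        assert classify_genomic(c, toy_index) == "read-through"
        assert classify_genomic(c, toy_index, readthrough_max_gap=100) == "intra-chromosomal"


class TestTruthAgreement:
    def test_planted_labels_recovered_exactly(self):
        cfg = small_config(seed=31)
        genome, index = simulate_genome_and_annotation(cfg)
        truth = plant_chimeras(cfg, index, genome)
        for t in truth:
            cand = ChimeraCandidate(
                five=Partner(t.gene_5p, t.contig_5p, t.strand_5p, t.breakpoint_5p),
                three=Partner(t.gene_3p, t.contig_3p, t.strand_3p, t.breakpoint_3p),
                junction_seq=t.transcript[t.junction_offset - 25 : t.junction_offset + 25],
                sample_id="P001_T",
            )
            assert classify_junction(cand, index) == t.junction_class
            assert classify_genomic(cand, index) == t.genomic_class

    def test_order_independence(self, toy_index):
        cands = [
            _cand(toy_index, "GA", 199, "GB", 1400),
            _cand(toy_index, "GA", 150, "GD", 250),
            _cand(toy_index, "GC", 5400, "GB", 1450),
        ]
        fwd = classify_all(cands, toy_index)
        rev = classify_all(cands[::-1], toy_index)[::-1]
        assert [(c.junction_class, c.genomic_class) for c in fwd] == [
            (c.junction_class, c.genomic_class) for c in rev
        ]
        # total function: every candidate got both labels
        assert all(c.junction_class and c.genomic_class for c in fwd)
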