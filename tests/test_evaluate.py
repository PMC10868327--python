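"""Isoform assignment categories, the barcode "fixed" filter, and scoring."""

import numpy as np
import pytest

from cloudasm.evaluate import (Assignment, ReferenceSet, assign_contig,
                               fixed_filter, score_assembly)
from cloudasm.seq import random_dna
from cloudasm.simulate import CloudTruth, GeneModel, make_gene


@pytest.fixture(scope="module")
def reference():
    """Two genes; G0 has two isoforms sharing their first two exons."""
    rng = np.random.default_rng(12)
    seq = random_dna(rng, 2000)
    exons = ((0, 250), (400, 650), (800, 1050), (1200, 1450))
    g0 = GeneModel("G0", seq, exons,
                   (("G0.i00", (0, 1, 3)), ("G0.i01", (0, 1, 2, 3))))
    seq1 = random_dna(rng, 1200)
    g1 = GeneModel("G1", seq1, ((0, 300), (500, 800)),
                   (("G1.i00", (0, 1)),))
    return ReferenceSet([g0, g1])


class TestAssign:
    def test_exact_transcript_is_unique(self, reference):
        t = reference.transcripts["G0.i00"][1]
        a = assign_contig(t, "B1", reference)
        assert a.category == "unique"
        assert a.isoform_id == "G0.i00" and a.gene_id == "G0"

    def test_shared_exon_fragment_is_ambiguous(self, reference):
        # first two exons + their junction occur in both G0 isoforms
        t = reference.transcripts["G0.i01"][1]
        frag = t[:450]  # exon0 (250) + most of exon1, junction included
        a = assign_contig(frag, "B1", reference)
        assert a.category == "ambiguous"
        assert a.gene_id == "G0" and a.isoform_id is None

    def test_random_sequence_is_intergenic(self, reference):
        a = assign_contig(random_dna(np.random.default_rng(5), 500),
                          "B1", reference)
        assert a.category == "intergenic"
        assert a.gene_id is None

    def test_short_aligned_span_is_non_informative(self, reference):
        t = reference.transcripts["G0.i00"][1]
        a = assign_contig(t[:250], "B1", reference)
        assert a.category == "non_informative"

    def test_small_terminal_truncation_is_unique_minor(self, reference):
        t = reference.transcripts["G0.i00"][1]
        a = assign_contig(t[60:], "B1", reference)
        assert a.category == "unique_minor"
        assert a.isoform_id == "G0.i00"

    def test_empty_contig_rejected(self, reference):
        with pytest.raises(ValueError):
            assign_contig("", "B1", reference)

    def test_mono_isoform_gene_full_match_unique(self, reference):
        t = reference.transcripts["G1.i00"][1]
        a = assign_contig(t, "B1", reference)
        assert a.category == "unique" and a.isoform_id == "G1.i00"


def A(contig, bc, gene, iso, cat):
    return Assignment(contig, bc, gene, iso, cat)


class TestFixedFilter:
    def test_double_assignment_same_gene_removed(self):
        assigns = [A("c1", "B1", "G0", "G0.i00", "unique"),
                   A("c2", "B1", "G0", None, "ambiguous"),
                   A("c3", "B2", "G0", "G0.i01", "unique")]
        kept = fixed_filter(assigns, mode="per_gene")
        assert [a.contig_id for a in kept] == ["c3"]

    def test_single_contig_barcode_kept(self):
        assigns = [A("c1", "B1", "G0", "G0.i00", "unique")]
        assert fixed_filter(assigns) == assigns

    def test_counting_oracle_seven_survive(self):
        # 10 assignments; one barcode puts 3 contigs on one gene
        assigns = [A(f"c{i}", f"B{i}", "G0", "G0.i00", "unique")
                   for i in range(7)]
        assigns += [A(f"x{i}", "B9", "G1", "G1.i00", "unique")
                    for i in range(3)]
        kept = fixed_filter(assigns, mode="per_gene")
        assert len(kept) == 7
        assert all(a.barcode != "B9" for a in kept)

    def test_per_barcode_mode_counts_across_genes(self):
        assigns = [A("c1", "B1", "G0", "G0.i00", "unique"),
                   A("c2", "B1", "G1", "G1.i00", "unique")]
        assert len(fixed_filter(assigns, mode="per_gene")) == 2
        assert len(fixed_filter(assigns, mode="per_barcode")) == 0

    def test_unassigned_categories_never_removed(self):
        assigns = [A("c1", "B1", "G0", "G0.i00", "unique"),
                   A("c2", "B1", "G0", None, "inconsistent"),
                   A("c3", "B1", None, None, "intergenic")]
        kept = fixed_filter(assigns, mode="per_gene")
        assert [a.contig_id for a in kept] == ["c3"]


def truth(bc, iso, n=10):
    return CloudTruth(bc, [("G0", iso)], n, 1.0)


class TestScore:
    def test_hand_computed_confusion_counts(self):
        truths = [truth(f"B{i}", "G0.i00") for i in range(10)]
        assigns = [A(f"c{i}", f"B{i}", "G0", "G0.i00", "unique")
                   for i in range(8)]
        assigns.append(A("c8", "B8", "G0", "G0.i01", "unique"))  # wrong
        # B9 unassembled
        m = score_assembly(assigns, truths)
        assert m.precision == pytest.approx(8 / 9)
        assert m.recall == pytest.approx(0.8)

    def test_all_correct_gives_unit_scores(self):
        truths = [truth(f"B{i}", "G0.i00") for i in range(5)]
        assigns = [A(f"c{i}", f"B{i}", "G0", "G0.i00", "unique")
                   for i in range(5)]
        m = score_assembly(assigns, truths)
        assert (m.precision, m.recall, m.fixed_recall) == (1.0, 1.0, 1.0)

    def test_precision_invariant_to_uninformative_assignments(self):
        truths = [truth(f"B{i}", "G0.i00") for i in range(4)]
        assigns = [A(f"c{i}", f"B{i}", "G0", "G0.i00", "unique")
                   for i in range(3)]
        base = score_assembly(assigns, truths).precision
        assigns += [A("n1", "B3", None, None, "non_informative"),
                    A("n2", "B3", None, None, "intergenic")]
        assert score_assembly(assigns, truths).precision == base

    def test_category_counts_sum_to_contigs(self):
        truths = [truth("B0", "G0.i00")]
        assigns = [A("c0", "B0", "G0", "G0.i00", "unique"),
                   A("c1", "B0", None, None, "intergenic")]
        m = score_assembly(assigns, truths)
        assert sum(m.category_counts.values()) == 2

    def test_fixed_recall_drops_split_clouds_from_denominator(self):
        truths = [truth(f"B{i}", "G0.i00") for i in range(4)]
        assigns = [A(f"c{i}", f"B{i}", "G0", "G0.i00", "unique")
                   for i in range(2)]
        # B2: fragmented cloud, two assignments, neither full-length
        assigns += [A("f1", "B2", "G0", None, "inconsistent"),
                    A("f2", "B2", "G0", None, "ambiguous")]
        m = score_assembly(assigns, truths)
        assert m.recall == pytest.approx(0.5)   # 2 of 4
        assert m.fixed_recall == pytest.approx(2 / 3)  # B2 leaves the pool
        assert m.fixed_recall >= m.recall

    def test_min_reads_denominator(self):
        truths = [truth("B0", "G0.i00", n=10), truth("B1", "G0.i00", n=1)]
        assigns = [A("c0", "B0", "G0", "G0.i00", "unique")]
        m = score_assembly(assigns, truths, denominator=("min_reads", 5))
        assert m.recall == 1.0

    def test_empty_denominator_raises(self):
        with pytest.raises(ValueError):
            score_assembly([], [], denominator="all")
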