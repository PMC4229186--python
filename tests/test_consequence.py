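"""Consequence classification: codon logic, splice sites, strand symmetry."""

import pytest
from Bio.Seq import Seq

from extremevar.cohort_io import VariantKey
from extremevar.consequence import (GeneModel, ReferenceMismatchError,
                                    annotate_cohort, classify_variant,
                                    protein_altering_by_gene, reverse_complement)
from tests.conftest import make_single_exon_gene


def classify(ref, model, chrom, pos, r, a):
    return classify_variant(VariantKey(chrom, pos, r, a), model, ref)


class TestCodingSnvs:
    def test_missense_at_codon_321(self):
        """A CGG->TGG change at codon 321 is an arginine-to-tryptophan
        missense, mirroring the canonical R321W example."""
        codons = ["ATG"] + ["GCT"] * 319 + ["CGG"] + ["GCT"] * 9 + ["TAA"]
        ref, model = make_single_exon_gene(codons)
        pos = 10 + 320 * 3 + 1  # genomic 1-based of codon 321 base 1
        call = classify(ref, model, "chrT", pos, "C", "T")
        assert call.category == "missense"
        assert (call.aa_position, call.aa_ref, call.aa_alt) == (321, "R", "W")

    def test_stopgain_and_stoploss(self):
        codons = ["ATG", "CAG", "GCT", "TAA"]
        ref, model = make_single_exon_gene(codons)
        # CAG (Q) -> TAG (stop)
        call = classify(ref, model, "chrT", 10 + 3 + 1, "C", "T")
        assert call.category == "stopgain" and call.aa_alt == "*"
        # TAA (stop) -> CAA (Q)
        call = classify(ref, model, "chrT", 10 + 9 + 1, "T", "C")
        assert call.category == "stoploss" and call.aa_ref == "*"

    def test_synonymous_is_not_protein_altering(self):
        codons = ["ATG", "CTG", "TAA"]  # CTG (L) -> CTA (L)
        ref, model = make_single_exon_gene(codons)
        call = classify(ref, model, "chrT", 10 + 5 + 1, "G", "A")
        assert call.category == "non_protein_altering"

    def test_start_codon_snv_without_stop_is_missense(self):
        codons = ["ATG", "GCT", "TAA"]
        ref, model = make_single_exon_gene(codons)
        call = classify(ref, model, "chrT", 11, "A", "G")  # ATG -> GTG
        assert call.category == "missense"


class TestIndels:
    @pytest.mark.parametrize("ndel,category", [
        (1, "frameshift"), (2, "frameshift"), (3, "nonframeshift_indel"),
        (4, "frameshift"), (5, "frameshift"), (6, "nonframeshift_indel"),
    ])
    def test_frame_decided_by_length_mod_three(self, ndel, category):
        codons = ["ATG"] + ["GCT"] * 10 + ["TAA"]
        ref, model = make_single_exon_gene(codons)
        seq = ref["chrT"]
        start = 14  # 0-based, inside CDS
        key = VariantKey("chrT", start + 1, seq[start:start + ndel + 1],
                         seq[start])
        assert classify_variant(key, model, ref).category == category

    def test_insertion_frameshift(self):
        codons = ["ATG"] + ["GCT"] * 10 + ["TAA"]
        ref, model = make_single_exon_gene(codons)
        seq = ref["chrT"]
        key = VariantKey("chrT", 15, seq[14], seq[14] + "GG")
        assert classify_variant(key, model, ref).category == "frameshift"


def two_exon_gene(strand="+"):
    """ATG GCT | GCA TAA with a canonical GT..AG intron (on the + strand)."""
    exon1, exon2, intron = "ATGGCT", "GCATAA", "GT" + "C" * 8 + "AG"
    sense = exon1 + intron + exon2
    offset = 10
    seq = "T" * offset + sense + "T" * 10
    exons = ((offset, offset + 6), (offset + 18, offset + 24))
    if strand == "-":
        seq = "T" * offset + reverse_complement(sense) + "T" * 10
        exons = ((offset, offset + 6), (offset + 18, offset + 24))
    model = GeneModel("TOY2", "chrT", strand, exons, offset, offset + 24, "t")
    return {"chrT": seq}, model


class TestSpliceSites:
    def test_acceptor_minus_two_snv(self):
        """An SNV at the -2 intronic base of an exon's acceptor site
        disrupts the canonical AG dinucleotide."""
        ref, model = two_exon_gene()
        # acceptor = last two intron bases, 0-based 26,27 -> AG
        assert ref["chrT"][26:28] == "AG"
        call = classify(ref, model, "chrT", 27, "A", "G")
        assert call.category == "splice_site"

    def test_donor_snv(self):
        ref, model = two_exon_gene()
        assert ref["chrT"][16:18] == "GT"
        call = classify(ref, model, "chrT", 17, "G", "A")
        assert call.category == "splice_site"

    def test_deep_intronic_snv_is_not_altering(self):
        ref, model = two_exon_gene()
        call = classify(ref, model, "chrT", 21, ref["chrT"][20], "A"
                        if ref["chrT"][20] != "A" else "G")
        assert call.category == "non_protein_altering"

    def test_indel_touching_cds_and_splice_is_frame_called(self):
        """Precedence: an indel spanning the exon end and the donor GT is
        classified by its frame effect, not as splice_site."""
        ref, model = two_exon_gene()
        seq = ref["chrT"]
        key = VariantKey("chrT", 15, seq[14:17], seq[14])  # deletes CDS+G of GT
        assert classify_variant(key, model, ref).category == "frameshift"

    def test_intronic_indel_in_splice_region(self):
        ref, model = two_exon_gene()
        seq = ref["chrT"]
        key = VariantKey("chrT", 17, seq[16:18], seq[16])  # deletes the T of GT
        assert classify_variant(key, model, ref).category == "splice_site"


class TestErrors:
    def test_reference_mismatch(self):
        ref, model = make_single_exon_gene(["ATG", "GCT", "TAA"])
        with pytest.raises(ReferenceMismatchError):
            classify(ref, model, "chrT", 11, "C", "T")

    def test_outside_transcript_span(self):
        ref, model = make_single_exon_gene(["ATG", "GCT", "TAA"])
        with pytest.raises(ValueError, match="outside transcript"):
            classify(ref, model, "chrT", 1, "T", "A")

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            GeneModel("BAD", "chr1", "+", ((0, 10),), 0, 10, "t")
        with pytest.raises(ValueError, match="overlap"):
            GeneModel("BAD", "chr1", "+", ((0, 9), (5, 12)), 0, 12, "t")


class TestStrandSymmetry:
    def test_mirrored_gene_gives_identical_categories(self):
        """A gene model and its reverse-complement mirror on the other
        strand classify mirrored variants identically."""
        codons = ["ATG", "CAG", "CGG", "CTG", "TAA"]
        fwd_ref, fwd = make_single_exon_gene(codons, strand="+")
        L = len(fwd_ref["chrT"])
        rev_ref = {"chrT": reverse_complement(fwd_ref["chrT"])}
        rev = GeneModel("TOY", "chrT", "-",
                        ((L - fwd.cds_end, L - fwd.cds_start),),
                        L - fwd.cds_end, L - fwd.cds_start, "TOY.t1")
        for off in range(15):  # every CDS base
            g = 10 + off
            base = fwd_ref["chrT"][g]
            for alt in "ACGT":
                if alt == base:
                    continue
                f = classify(fwd_ref, fwd, "chrT", g + 1, base, alt)
                # mirrored genomic coordinate and complemented alleles
                mg = L - 1 - g
                mbase = rev_ref["chrT"][mg]
                malt = reverse_complement(alt)
                r = classify(rev_ref, rev, "chrT", mg + 1, mbase, malt)
                assert f.category == r.category
                assert f.aa_position == r.aa_position


class TestTranslationOracle:
    def test_every_cds_snv_agrees_with_full_translation(self):
        """Brute-force oracle: mutate the genome, rebuild the CDS from
        coordinates, translate both full proteins with biopython, and
        derive the category from the first amino-acid difference."""
        codons = ["ATG"] + ["CAG", "CGG", "TGC", "CTG", "GAT", "TGG",
                            "TAC", "AAA"] * 3 + ["TAA"]
        for strand in ("+", "-"):
            ref, model = make_single_exon_gene(codons, strand=strand)
            seq = ref["chrT"]
            for g in range(model.cds_start, model.cds_end):
                base = seq[g]
                for alt in "ACGT":
                    if alt == base:
                        continue
                    call = classify(ref, model, "chrT", g + 1, base, alt)
                    mutated = {"chrT": seq[:g] + alt + seq[g + 1:]}
                    p_ref = str(Seq(model.cds_sequence(ref)).translate())
                    p_alt = str(Seq(model.cds_sequence(mutated)).translate())
                    diffs = [i for i, (x, y) in enumerate(zip(p_ref, p_alt))
                             if x != y]
                    if not diffs:
                        expected = "non_protein_altering"
                    else:
                        i = diffs[0]
                        if p_ref[i] != "*" and p_alt[i] == "*":
                            expected = "stopgain"
                        elif p_ref[i] == "*" and p_alt[i] != "*":
                            expected = "stoploss"
                        else:
                            expected = "missense"
                    assert call.category == expected, (strand, g, base, alt)


class TestSyntheticGenomeTruth:
    def test_planted_variants_classify_to_truth(self, sim_bundle):
        genome = sim_bundle["genome"]
        truth = genome.truth_variants
        assert len(truth) >= 20
        for pv in truth:
            call = classify_variant(pv.variant, genome.model(pv.gene),
                                    genome.sequences)
            assert call.category == pv.category, pv


class TestAnnotateCohort:
    def test_any_transcript_rule(self):
        """A variant missense on one transcript and non-altering on the
        other still flags the gene as protein-altering."""
        codons = ["ATG", "CAG", "GCT", "TAA"]
        ref, m1 = make_single_exon_gene(codons, symbol="G1")
        # second transcript: same exon, shorter CDS (tail is untranslated)
        m2 = GeneModel("G1", "chrT", "+", ((10, 22),), 10, 16, "G1.t2")
        from tests.conftest import make_cohort
        v = VariantKey("chrT", 18, "C", "G")  # GCT -> GGT on t1; 3'UTR on t2
        cohort = make_cohort([[1]], [[0]], variants=[v])
        calls = annotate_cohort(cohort, [m1, m2], ref)
        cats = {c.transcript_id: c.category for c in calls}
        assert cats["G1.t1"] == "missense"
        assert cats["G1.t2"] == "non_protein_altering"
        index = protein_altering_by_gene(calls)
        assert v in index["G1"]

    def test_no_overlap_yields_no_calls(self):
        ref, model = make_single_exon_gene(["ATG", "GCT", "TAA"])
        from tests.conftest import make_cohort
        v = VariantKey("chrT", 35, "T", "A")
        cohort = make_cohort([[1]], [[0]], variants=[v])
        assert annotate_cohort(cohort, [model], ref) == []
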