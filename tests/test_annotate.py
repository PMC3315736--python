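"""Feature classification and coding-effect calls against translation
oracles."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from pooldiver import annotate, simulate
from pooldiver.annotate import GeneModel
from pooldiver.errors import DataError, StructureError


def translate_cds_oracle(model, seq):
    """Independent full-CDS translation: concatenate CDS in genomic order,
    reverse-complement for minus strand, translate with Biopython."""
    cds = "".join(seq[s:e] for s, e in model.cds)
    if model.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return str(Seq(cds).translate())


def apply_snp(seq, pos, alt):
    return seq[: pos - 1] + alt + seq[pos:]


@pytest.fixture()
def plus_gene():
    # 5'flank[0:20) exon1 = UTR5(20:26) + CDS(26:38), intron (38:48),
    # exon2 = CDS(48:54) + UTR3(54:60)
    seq = ("A" * 20 + "TTTTTT" + "ATGGCAGAAACC" + "G" * 10
           + "TGCTAA" + "CCCCCC" + "T" * 20)
    model = GeneModel("g1", "t1", "chrX", "+",
                      exons=[(20, 38), (48, 60)],
                      cds=[(26, 38), (48, 54)], flank=15)
    return model, seq


class TestClassifyFeature:
    def test_cds_position_is_exonic(self, plus_gene):
        model, _ = plus_gene
        cls, tid = annotate.classify_feature("chrX", 27, [model])
        assert cls == "exonic_coding" and tid == "t1"

    def test_utr_sides_follow_strand(self, plus_gene):
        model, _ = plus_gene
        assert annotate.classify_feature("chrX", 21, [model])[0] == \
            "five_prime_utr"
        assert annotate.classify_feature("chrX", 55, [model])[0] == \
            "three_prime_utr"
        minus = GeneModel("g1", "t1", "chrX", "-",
                          exons=model.exons, cds=model.cds, flank=15)
        assert annotate.classify_feature("chrX", 21, [minus])[0] == \
            "three_prime_utr"
        assert annotate.classify_feature("chrX", 55, [minus])[0] == \
            "five_prime_utr"

    def test_intron_and_intergenic(self, plus_gene):
        model, _ = plus_gene
        assert annotate.classify_feature("chrX", 40, [model])[0] == \
            "intronic"
        assert annotate.classify_feature("chrX", 3, [model])[0] == \
            "intergenic"

    def test_flank_boundary_at_configured_width(self):
        model = GeneModel("g", "t", "chr1", "+",
                          exons=[(5000, 5300)], cds=[(5000, 5300)],
                          flank=3000)
        # 2999 bases upstream of the transcript start -> flank
        assert annotate.classify_feature("chr1", 5001 - 2999, [model])[0] \
            == "five_flank"
        # 3001 bases upstream -> intergenic
        assert annotate.classify_feature("chr1", 5001 - 3001, [model])[0] \
            == "intergenic"

    def test_unknown_chromosome_is_intergenic(self, plus_gene):
        model, _ = plus_gene
        assert annotate.classify_feature("chrZ", 27, [model]) == \
            ("intergenic", None)

    def test_precedence_coding_beats_utr(self, plus_gene):
        model, _ = plus_gene
        other = GeneModel("g2", "t2", "chrX", "+",
                          exons=[(20, 60)], cds=[], flank=15)
        cls, tid = annotate.classify_feature("chrX", 27, [model, other])
        assert cls == "exonic_coding" and tid == "t1"


class TestCodingEffect:
    def test_synonymous_third_position(self, plus_gene):
        model, seq = plus_gene
        # codon 2 is GCA (Ala); GCA->GCG stays Ala
        ce = annotate.coding_effect("chrX", 32, "A", "G", model, seq)
        assert (ce.ref_codon, ce.alt_codon) == ("GCA", "GCG")
        assert ce.effect == "synonymous"

    def test_nonsynonymous_second_position(self, plus_gene):
        model, seq = plus_gene
        # codon 2 GCA -> GAA is Ala -> Glu
        ce = annotate.coding_effect("chrX", 31, "C", "A", model, seq)
        assert (ce.ref_aa, ce.alt_aa) == ("A", "E")
        assert ce.effect == "non_synonymous"
        assert ce.aa_change == "A2E"

    def test_minus_strand_hand_case(self):
        # genomic TTACTCCAT on - strand codes ATGGAGTAA; genomic C->T at
        # offset 3 turns GAG into GAA: Glu->Glu, synonymous
        seq = "AAAA" + "TTACTCCAT" + "AAAA"
        model = GeneModel("g", "t", "chrM", "-",
                          exons=[(4, 13)], cds=[(4, 13)], flank=2)
        ce = annotate.coding_effect("chrM", 8, "C", "T", model, seq)
        assert (ce.ref_codon, ce.alt_codon) == ("GAG", "GAA")
        assert ce.effect == "synonymous"
        assert ce.codon_number == 2

    def test_ref_mismatch_raises(self, plus_gene):
        model, seq = plus_gene
        with pytest.raises(DataError, match="mismatch"):
            annotate.coding_effect("chrX", 32, "T", "G", model, seq)

    def test_frame_broken_transcript_refused(self):
        seq = "A" * 30
        model = GeneModel("g", "t", "chr1", "+",
                          exons=[(5, 15)], cds=[(5, 15)])  # length 10
        with pytest.raises(StructureError, match="multiple of 3"):
            annotate.coding_effect("chr1", 7, "A", "G", model, seq)

    def test_matches_full_cds_retranslation(self, toy_genome):
        # every planted coding SNP: mutate the chromosome, re-translate the
        # whole CDS independently, and compare the called effect
        models = {m.transcript_id: m for m in toy_genome.models}
        coding = toy_genome.variants.query(
            "kind == 'snp' and true_class == 'exonic_coding'")
        assert len(coding) >= 2
        for v in coding.itertuples():
            model = models[v.transcript_id]
            seq = toy_genome.sequences[v.chrom]
            ce = annotate.coding_effect(v.chrom, v.pos, v.ref, v.alt,
                                        model, seq)
            before = translate_cds_oracle(model, seq)
            after = translate_cds_oracle(model,
                                         apply_snp(seq, v.pos, v.alt))
            oracle = "synonymous" if before == after else "non_synonymous"
            assert ce.effect == oracle == v.effect

    def test_strand_involution(self, plus_gene):
        # mirror the chromosome: reverse-complement sequence, flip strand,
        # map coordinates; classes and effects must be preserved
        model, seq = plus_gene
        L = len(seq)
        mirror_seq = str(Seq(seq).reverse_complement())

        def flip(iv):
            return (L - iv[1], L - iv[0])

        mirror = GeneModel("g1", "t1", "chrX", "-",
                           exons=[flip(iv) for iv in model.exons],
                           cds=[flip(iv) for iv in model.cds],
                           flank=model.flank)
        for pos, ref, alt in [(32, "A", "G"), (31, "C", "A")]:
            ce = annotate.coding_effect("chrX", pos, ref, alt, model, seq)
            mpos = L - pos + 1
            mref = str(Seq(ref).complement())
            malt = str(Seq(alt).complement())
            mce = annotate.coding_effect("chrX", mpos, mref, malt,
                                         mirror, mirror_seq)
            assert mce.effect == ce.effect
            assert mce.aa_change == ce.aa_change
        for pos in (21, 27, 40, 55):
            cls = annotate.classify_feature("chrX", pos, [model])[0]
            mcls = annotate.classify_feature("chrX", L - pos + 1,
                                             [mirror])[0]
            assert mcls == cls


class TestAnnotateTable:
    def test_partition_every_variant_one_class(self, toy_genome):
        ann = annotate.annotate_variants(
            toy_genome.variants, toy_genome.models, toy_genome.sequences)
        assert len(ann) == len(toy_genome.variants)
        assert ann["feature_class"].isin(annotate.FEATURE_CLASSES).all()
        # planted labels reproduced exactly (cross-module soundness)
        assert (ann["feature_class"].to_numpy() ==
                toy_genome.variants["true_class"].to_numpy()).all()

    def test_determinism(self, toy_genome):
        a = annotate.annotate_variants(
            toy_genome.variants, toy_genome.models, toy_genome.sequences)
        b = annotate.annotate_variants(
            toy_genome.variants, toy_genome.models, toy_genome.sequences)
        pd.testing.assert_frame_equal(a, b)


class TestCategorySummary:
    def _calls(self, variants, alt_low, alt_high):
        calls = variants[["chrom", "pos", "ref", "alt"]].copy()
        calls["alt_low"] = alt_low
        calls["alt_high"] = alt_high
        return calls

    def test_sharing_rules(self, toy_genome):
        v = toy_genome.variants
        rng = np.random.default_rng(5)
        alt_low = rng.integers(0, 3, len(v))
        alt_high = rng.integers(0, 3, len(v))
        ann = annotate.annotate_variants(v, toy_genome.models,
                                         toy_genome.sequences)
        summary = annotate.summarize_categories(
            ann, self._calls(v, alt_low, alt_high))
        # planted-truth oracle: recompute the cross-tab by hand
        share = np.select(
            [(alt_low > 0) & (alt_high == 0),
             (alt_high > 0) & (alt_low == 0)],
            ["unique_low", "unique_high"], "shared")
        for row in summary.itertuples():
            mask = ((v["true_class"] == row.feature_class)
                    & (share == row.sharing))
            kinds = v.loc[mask, "kind"]
            assert row.snp == (kinds == "snp").sum()
            assert row.indel == (kinds == "indel").sum()
        total = summary["snp"].sum() + summary["indel"].sum()
        assert total == len(v)

    def test_table_view_merges_utr_and_flanks(self, toy_genome):
        v = toy_genome.variants
        ann = annotate.annotate_variants(v, toy_genome.models,
                                         toy_genome.sequences)
        summary = annotate.summarize_categories(
            ann, self._calls(v, 1, 1))
        merged = annotate.table2_view(summary)
        utr = merged[merged["category"] == "utr"]
        flank_classes = ["five_prime_utr", "three_prime_utr",
                         "five_flank", "three_flank"]
        expect = summary[summary["feature_class"].isin(flank_classes)]
        assert utr["snp"].sum() == expect["snp"].sum()
        unmerged = annotate.table2_view(summary, merge_flanks=False)
        assert "flank" in set(unmerged["category"])
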