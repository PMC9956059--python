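from __future__ import annotations

import pytest

from crossscreen import effect_annotation as ea
from crossscreen.errors import (
    GeneModelError,
    HgvsParseError,
    JoinError,
    ReferenceMismatchError,
)
from crossscreen.formats_io import VariantSite
from crossscreen.mendelian_screen import ScreenDecision


class TestHgvsParsers:
    @pytest.mark.parametrize("text,pos,ref,alt", [
        ("c.652A > G", 652, "A", "G"),   # spaced spelling
        ("c.349G>T", 349, "G", "T"),     # compact spelling
        ("c.1A>C", 1, "A", "C"),
    ])
    def test_coding_substitutions_parse(self, text, pos, ref, alt):
        c = ea.parse_hgvs_c(text)
        assert (c.pos, c.ref, c.alt) == (pos, ref, alt)

    @pytest.mark.parametrize("text", [
        "c.652A > A",      # ref == alt
        "c.652del",        # not a substitution
        "g.652A>G",        # wrong prefix
        "c.0A>G",          # bad position
        "c.12N>G",         # bad base
    ])
    def test_malformed_coding_text_rejected(self, text):
        with pytest.raises(HgvsParseError):
            ea.parse_hgvs_c(text)

    @pytest.mark.parametrize("text,residue,ref,alt,effect", [
        ("Thr218Ala", 218, "Thr", "Ala", "missense"),
        ("Ter287Ter", 287, "Ter", "Ter", "stop_retained"),
        ("Gly114Asp", 114, "Gly", "Asp", "missense"),
        ("Arg97Ter", 97, "Arg", "Ter", "stop_gained"),
        ("Ter12Gln", 12, "Ter", "Gln", "stop_lost"),
        ("Leu50Leu", 50, "Leu", "Leu", "synonymous"),
        ("Met1Val", 1, "Met", "Val", "start_lost"),
    ])
    def test_protein_changes_parse_and_classify(self, text, residue, ref, alt, effect):
        p = ea.parse_protein_change(text)
        assert (p.residue, p.ref, p.alt, p.effect) == (residue, ref, alt, effect)

    def test_unknown_residue_code_rejected(self):
        with pytest.raises(HgvsParseError):
            ea.parse_protein_change("Xyz10Ala")


class TestConsistency:
    @pytest.mark.parametrize("cpos,residue,ok", [
        (652, 218, True),
        (912, 304, True),
        (652, 217, False),
        (1, 1, True),
        (3, 1, True),
        (4, 2, True),
    ])
    def test_codon_arithmetic(self, cpos, residue, ok):
        coding = ea.CodingChange(cpos, "A", "G")
        protein = ea.ProteinChange(residue, "Thr", "Ala")
        assert ea.check_consistency(coding, protein)[0] is ok


class TestGeneModel:
    def test_cds_length_must_be_codon_multiple(self):
        with pytest.raises(GeneModelError):
            ea.GeneModel("g", "t", "chr1", "+", ((1, 10),))

    def test_intervals_must_be_ordered_disjoint(self):
        with pytest.raises(GeneModelError):
            ea.GeneModel("g", "t", "chr1", "+", ((10, 18), (5, 7)))

    def test_minus_strand_coordinate_mapping(self):
        model = ea.GeneModel("g", "t", "chr1", "-", ((11, 19),))
        # genomic 19 is the first coding base on the minus strand
        assert model.genomic_to_cds(19) == 1
        assert model.genomic_to_cds(11) == 9
        assert model.genomic_to_cds(10) is None

    def test_spliced_cds_joins_intervals_in_transcript_order(self):
        #            123456789012345
        reference = {"chr1": "TTATGGCGTAACCGG"}
        plus = ea.GeneModel("g", "t", "chr1", "+", ((3, 8), (12, 14)))
        assert plus.spliced_cds(reference) == "ATGGCGCCG"


def _one_codon_world():
    """A 15 bp scaffold with a single 9-codon-free CDS for exact checks."""
    #                  pos: 123456789...
    # CDS (+): ATG GCT ACC  -> Met Ala Thr
    reference = {"chr1": "ATGGCTACCTTTTTT"}
    model = ea.GeneModel("gene1", "tx1", "chr1", "+", ((1, 9),))
    return reference, model


class TestAnnotateVariant:
    def test_missense_at_second_codon(self):
        reference, model = _one_codon_world()
        site = VariantSite("chr1", 4, "G", ("A",))
        rec = ea.annotate_variant(site, [model], reference)
        assert rec.region == "CDS"
        assert rec.coding_change == "c.4G>A"
        assert rec.codon_change == "GCT>ACT"
        assert rec.protein_change == "Ala2Thr"
        assert rec.effect == "missense"

    def test_synonymous_third_position(self):
        reference, model = _one_codon_world()
        site = VariantSite("chr1", 6, "T", ("C",))  # GCT -> GCC, both Ala
        rec = ea.annotate_variant(site, [model], reference)
        assert rec.protein_change == "Ala2Ala" and rec.effect == "synonymous"

    def test_stop_gained(self):
        reference, model = _one_codon_world()
        site = VariantSite("chr1", 7, "A", ("T",))  # ACC -> TCC? no: pos7 A>T gives TCC (Ser)
        rec = ea.annotate_variant(site, [model], reference)
        assert rec.effect == "missense"
        site = VariantSite("chr1", 8, "C", ("G",))  # ACC -> AGC (Ser), still missense
        rec = ea.annotate_variant(site, [model], reference)
        assert rec.protein_change == "Thr3Ser"

    def test_start_lost(self):
        reference, model = _one_codon_world()
        site = VariantSite("chr1", 2, "T", ("C",))  # ATG -> ACG
        rec = ea.annotate_variant(site, [model], reference)
        assert rec.effect == "start_lost"

    def test_intergenic_site(self):
        reference, model = _one_codon_world()
        site = VariantSite("chr1", 12, "T", ("A",))
        rec = ea.annotate_variant(site, [model], reference)
        assert rec.region == "intergenic" and rec.protein_change is None

    def test_non_coding_between_cds_intervals(self):
        reference = {"chr1": "ATGGCTACCTTTTTT"}
        model = ea.GeneModel("g", "t", "chr1", "+", ((1, 6), (10, 12)))
        site = VariantSite("chr1", 8, "C", ("A",))
        rec = ea.annotate_variant(site, [model], reference)
        assert rec.region == "non_coding"

    def test_reference_mismatch_raises(self):
        reference, model = _one_codon_world()
        site = VariantSite("chr1", 4, "T", ("A",))  # reference has G at 4
        with pytest.raises(ReferenceMismatchError):
            ea.annotate_variant(site, [model], reference)

    def test_minus_strand_equals_reverse_complement_mirror(self):
        """Annotating on '-' must equal annotating the revcomp genome on '+'."""
        reference, plus_model = _one_codon_world()
        seq = reference["chr1"]
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        minus_model = ea.GeneModel("gene1", "tx1", "chr1", "-",
                                   ((len(seq) - 9 + 1, len(seq)),))
        for plus_pos, ref, alt in ((4, "G", "A"), (6, "T", "C"), (2, "T", "C")):
            minus_pos = len(seq) - plus_pos + 1
            plus_rec = ea.annotate_variant(
                VariantSite("chr1", plus_pos, ref, (alt,)),
                [plus_model], reference)
            minus_rec = ea.annotate_variant(
                VariantSite("chr1", minus_pos, ref.translate(comp),
                            (alt.translate(comp),)),
                [minus_model], {"chr1": rc})
            assert plus_rec.coding_change == minus_rec.coding_change
            assert plus_rec.protein_change == minus_rec.protein_change
            assert plus_rec.effect == minus_rec.effect


class TestSimulatorRoundTrip:
    def test_emitted_hgvs_reparses_consistently(self, small_dataset):
        models = [
            ea.GeneModel(g, t, c, s, ((start, end),))
            for g, t, c, s, start, end in small_dataset.gene_models
        ]
        effects = ea.annotate_all(small_dataset.sites, models,
                                  small_dataset.reference)
        cds = [e for e in effects if e.region == "CDS"]
        assert cds, "expected some CDS sites"
        for rec in cds:
            coding = ea.parse_hgvs_c(rec.coding_change)
            protein = ea.parse_protein_change(rec.protein_change)
            assert ea.check_consistency(coding, protein)[0]
            assert protein.effect == rec.effect


def _mk_decision(chrom, pos, passed):
    return ScreenDecision(chrom, pos, passed, "A" if passed else None,
                          "PASS" if passed else "FOUNDER_NOT_HOMOZYGOUS")


def _mk_effect(chrom, pos, region, effect=None):
    return ea.EffectRecord(chrom, pos, region, effect=effect)


class TestNarrow:
    def test_stage_sets_narrow_monotonically(self):
        decisions = [_mk_decision("c", i, i < 6) for i in range(1, 11)]
        effects = (
            [_mk_effect("c", i, "CDS", "missense") for i in range(1, 3)]
            + [_mk_effect("c", i, "CDS", "synonymous") for i in range(3, 5)]
            + [_mk_effect("c", i, "intergenic") for i in range(5, 11)]
        )
        res = ea.narrow_candidates(decisions, effects)
        assert res.stage_sizes == (5, 4, 2)
        assert res.effect_tally == {"missense": 2, "synonymous": 2}
        assert res.per_chromosome == {"c": 5}

    def test_no_passes_gives_empty_stages(self):
        decisions = [_mk_decision("c", i, False) for i in range(1, 5)]
        effects = [_mk_effect("c", i, "intergenic") for i in range(1, 5)]
        res = ea.narrow_candidates(decisions, effects)
        assert res.stage_sizes == (0, 0, 0)

    def test_orphan_keys_raise_join_error(self):
        decisions = [_mk_decision("c", 1, True)]
        with pytest.raises(JoinError):
            ea.narrow_candidates(decisions, [])
        effects = [_mk_effect("c", 1, "CDS", "missense"),
                   _mk_effect("c", 99, "CDS", "missense")]
        with pytest.raises(JoinError):
            ea.narrow_candidates(decisions, effects)


class TestPrintedTableRegression:
    def test_all_39_rows_parse_and_are_internally_consistent(self, table3_records):
        for rec in table3_records:
            coding = ea.parse_hgvs_c(rec.coding_change)
            protein = ea.parse_protein_change(rec.protein_change)
            ok, msg = ea.check_consistency(coding, protein)
            assert ok, f"{rec.snp_id}: {msg}"

    def test_exactly_one_row_is_not_strictly_missense(self, table3_records):
        """One record is a stop-retained change, not a missense substitution."""
        effects = [ea.parse_protein_change(r.protein_change).effect
                   for r in table3_records]
        non_missense = [r.snp_id for r, e in zip(table3_records, effects)
                        if e != "missense"]
        assert non_missense == ["SNP 12"]
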