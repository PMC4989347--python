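"""Genetic-code enumeration invariants and consequence-caller equivalence."""

from __future__ import annotations

import pytest
from Bio.Seq import Seq

from somaphyl.coding_impact import (
    CODING_CONSEQUENCES,
    CODONS,
    ReferenceMismatchError,
    TranscriptModel,
    annotate_consequences,
    call_consequence,
    consequence_fractions,
    enumerate_codon_changes,
    load_transcripts_gff3,
    standard_codon_map,
    synonymous_fraction,
    write_transcripts_gff3,
)
from somaphyl.spectra import CLASSES, COMPLEMENT
from somaphyl.variant_io import Variant


@pytest.fixture(scope="module")
def code():
    return standard_codon_map()


@pytest.fixture(scope="module")
def cct(code):
    return enumerate_codon_changes(code)


class TestCodonTable:
    def test_sixty_four_codons_twenty_amino_acids_plus_stop(self, code):
        assert len(code) == 64
        symbols = set(code.values())
        assert "*" in symbols
        assert len(symbols - {"*"}) == 20

    def test_agrees_with_independent_translation(self, code):
        for codon in CODONS:
            expected = str(Seq(codon).translate())
            assert code[codon] == expected


class TestEnumeration:
    def test_table_shape(self, cct):
        assert len(cct) == 576
        assert (cct.groupby("class_label").size() == 96).all()
        assert (cct.groupby("directed").size() == 48).all()
        assert set(cct["class_label"]) == set(CLASSES)

    def test_consequences_partition_every_class(self, cct):
        fractions = consequence_fractions(cct)
        assert fractions.sum(axis=1).round(12).eq(1.0).all()
        assert set(cct["consequence"]) <= set(CODING_CONSEQUENCES)

    def test_exact_synonymous_counts_per_pooled_class(self, cct):
        """Independent brute-force translation oracle, frozen counts out of 96."""
        from collections import Counter

        syn = Counter()
        for codon in CODONS:
            for i in range(3):
                for alt in "ACGT":
                    if alt == codon[i]:
                        continue
                    mut = codon[:i] + alt + codon[i + 1 :]
                    if str(Seq(mut).translate()) == str(Seq(codon).translate()):
                        ref = codon[i]
                        label = (
                            f"{ref}>{alt}"
                            if ref in "CT"
                            else f"{COMPLEMENT[ref]}>{COMPLEMENT[alt]}"
                        )
                        syn[label] += 1
        for label in CLASSES:
            assert synonymous_fraction(cct, label) == pytest.approx(syn[label] / 96)
        # the two classes whose contrast drives the deleteriousness argument
        assert syn["C>T"] == 33
        assert syn["C>A"] == 19

    def test_position_three_c_to_t_always_synonymous(self, cct):
        rows = cct[(cct.directed == "C>T") & (cct.position == 3)]
        assert len(rows) == 16  # the 16 NNC codons
        assert (rows.consequence == "synonymous").all()

    def test_transitions_more_degenerate_than_every_transversion(self, cct):
        transitions = {"C>T", "T>C"}
        tr = min(synonymous_fraction(cct, c) for c in transitions)
        tv = max(synonymous_fraction(cct, c) for c in CLASSES if c not in transitions)
        assert tr > tv

    def test_stop_to_stop_is_synonymous(self, cct):
        row = cct[(cct.codon == "TAA") & (cct.alt_codon == "TGA")].iloc[0]
        assert row.consequence == "synonymous"

    def test_directed_fractions_available_unpooled(self, cct):
        pooled = synonymous_fraction(cct, "C>T", pooled=True)
        directed = synonymous_fraction(cct, "G>A", pooled=False)
        assert 0 <= directed <= 1
        # pooled value is the average of the two directed halves
        other = synonymous_fraction(cct, "C>T", pooled=False)
        assert pooled == pytest.approx((directed + other) / 2)


class TestTranscriptModel:
    def test_cds_length_must_be_codon_multiple(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            TranscriptModel("t", "1", "+", cds=[(1, 4)])

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError):
            TranscriptModel("t", "1", "+", cds=[(1, 6), (4, 9)])

    def test_minus_strand_positions_reverse(self):
        tm = TranscriptModel("t", "1", "-", cds=[(10, 12)])
        assert tm.genomic_positions() == [12, 11, 10]


class TestCallConsequence:
    def test_stopgain_tgg_to_tga(self):
        seq = "TGGAAA"
        tm = TranscriptModel("1", "1", "+", cds=[(1, 6)])
        v = Variant(chrom="1", pos=3, ref="G", alt="A")  # TGG -> TGA
        assert call_consequence(v, tm, seq) == "stopgain"

    def test_synonymous_fourfold_site(self):
        seq = "GCCAAA"
        tm = TranscriptModel("1", "1", "+", cds=[(1, 6)])
        v = Variant(chrom="1", pos=3, ref="C", alt="T")  # GCC -> GCT (Ala)
        assert call_consequence(v, tm, seq) == "synonymous"

    def test_outside_cds_is_noncoding(self):
        seq = "GCCAAATTT"
        tm = TranscriptModel("1", "1", "+", cds=[(1, 6)])
        v = Variant(chrom="1", pos=8, ref="T", alt="A")
        assert call_consequence(v, tm, seq) == "noncoding"

    def test_reference_mismatch_is_fatal(self):
        tm = TranscriptModel("1", "1", "+", cds=[(1, 6)])
        v = Variant(chrom="1", pos=1, ref="A", alt="T")
        with pytest.raises(ReferenceMismatchError):
            call_consequence(v, tm, "GCCAAA")

    def test_caller_matches_enumeration_on_all_changes_both_strands(self, cct, code):
        """Every one of the 576 single-codon changes, embedded in a 1-codon CDS
        on each strand, is labelled identically by the caller and the table."""
        revcomp = lambda s: "".join(COMPLEMENT[b] for b in reversed(s))
        for row in cct.itertuples():
            # plus strand: genome is the codon itself
            tm = TranscriptModel("t", "1", "+", cds=[(1, 3)])
            v = Variant(chrom="1", pos=row.position, ref=row.ref_base, alt=row.alt_base)
            assert call_consequence(v, tm, row.codon, codon_map=code) == row.consequence
            # minus strand: genome is the reverse complement
            tm_m = TranscriptModel("t", "1", "-", cds=[(1, 3)])
            pos = 4 - row.position
            v_m = Variant(
                chrom="1",
                pos=pos,
                ref=COMPLEMENT[row.ref_base],
                alt=COMPLEMENT[row.alt_base],
            )
            assert (
                call_consequence(v_m, tm_m, revcomp(row.codon), codon_map=code)
                == row.consequence
            )


class TestAnnotateAndGff:
    def test_gff3_round_trip(self, tmp_path):
        tms = [
            TranscriptModel("tx1", "chr1", "+", cds=[(5, 10), (20, 25)], gene="GENEA"),
            TranscriptModel("tx2", "chr1", "-", cds=[(40, 45)], gene="GENEB"),
        ]
        path = tmp_path / "t.gff3"
        write_transcripts_gff3(tms, path)
        back = sorted(load_transcripts_gff3(path), key=lambda t: t.transcript_id)
        assert [(t.transcript_id, t.chrom, t.strand, t.cds, t.gene) for t in back] == [
            (t.transcript_id, t.chrom, t.strand, t.cds, t.gene) for t in tms
        ]

    def test_annotate_sets_consequence_and_gene(self, small_sim):
        from somaphyl.variant_io import VariantSet

        patient = small_sim.patients[0]
        source = patient.samples["PTC"]
        clone = VariantSet(
            "c",
            "PTC",
            [
                Variant(chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt)
                for v in source
            ],
        )
        annotate_consequences(
            clone, small_sim.genome.transcripts, small_sim.genome.sequences
        )
        for v in source:
            c = clone.get(v.key)
            assert c.consequence == v.consequence
            assert c.gene == v.gene
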