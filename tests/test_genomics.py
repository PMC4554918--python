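"""Sequence I/O, gene-model coordinates, splicing and translation."""

import numpy as np
import pytest

import slimsplice as ss
from slimsplice.genomics import (
    AlphabetError,
    Exon,
    GeneModel,
    SequenceRecord,
    cds_to_genomic,
    exon_sense_sequence,
    retained_segments,
    reverse_complement,
)

# independent standard-code oracle, written out by hand for the translation test
_CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class TestReadSequences:
    def test_case_normalized_single_record(self, tmp_path):
        p = tmp_path / "one.fa"
        p.write_text(">a\nacgt\n")
        recs = ss.read_sequences(p)
        assert [(r.id, r.seq) for r in recs] == [("a", "ACGT")]

    def test_order_preserved(self, tmp_path):
        p = tmp_path / "three.fa"
        p.write_text(">z\nAA\n>m\nCC\n>a\nGG\n")
        assert [r.id for r in ss.read_sequences(p)] == ["z", "m", "a"]

    def test_illegal_character_names_record_and_position(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">rec1\nACJGT\n")
        with pytest.raises(AlphabetError, match="rec1.*position 2"):
            ss.read_sequences(p)

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(ValueError):
            ss.read_sequences(p)

    def test_rna_normalization_flag(self, tmp_path):
        p = tmp_path / "rna.fa"
        p.write_text(">r\nacgu\n")
        assert ss.read_sequences(p, rna_to_dna=True)[0].seq == "ACGT"


class TestGeneModelIO:
    def test_gff3_coordinates_convert_to_half_open(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "c\tx\tgene\t4\t9\t.\t+\t.\tID=g1\n"
            "c\tx\tmRNA\t4\t9\t.\t+\t.\tID=g1.t1;Parent=g1\n"
            "c\tx\texon\t4\t9\t.\t+\t.\tParent=g1.t1;label=e1\n"
        )
        gene = ss.read_gene_models(p)[0]
        assert (gene.exons[0].start, gene.exons[0].end) == (3, 9)

    def test_minus_strand_exons_in_transcription_order(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "c\tx\tgene\t1\t30\t.\t-\t.\tID=g1\n"
            "c\tx\tmRNA\t1\t30\t.\t-\t.\tID=g1.t1;Parent=g1\n"
            "c\tx\texon\t1\t10\t.\t-\t.\tParent=g1.t1;label=b\n"
            "c\tx\texon\t21\t30\t.\t-\t.\tParent=g1.t1;label=a\n"
        )
        gene = ss.read_gene_models(p)[0]
        assert [e.label for e in gene.exons] == ["a", "b"]
        assert gene.exons[0].start > gene.exons[1].start

    def test_overlapping_exons_rejected(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "c\tx\tgene\t1\t30\t.\t+\t.\tID=g1\n"
            "c\tx\texon\t1\t10\t.\t+\t.\tParent=g1;label=a\n"
            "c\tx\texon\t8\t20\t.\t+\t.\tParent=g1;label=b\n"
        )
        with pytest.raises(ValueError, match="overlap"):
            ss.read_gene_models(p)

    def test_round_trip_preserves_model(self, tmp_path, locus):
        out = tmp_path / "rt.gff3"
        ss.write_gene_models([locus.gene], out)
        back = ss.read_gene_models(out)
        assert back == [locus.gene]

    def test_sidecar_tsv_supplies_internal_donors(self, tmp_path, locus):
        out = tmp_path / "g.gff3"
        stripped = GeneModel(
            gene_id=locus.gene.gene_id, contig=locus.gene.contig,
            strand=locus.gene.strand,
            exons=[Exon(e.label, e.start, e.end) for e in locus.gene.exons],
            cds_start_phase=locus.gene.cds_start_phase,
        )
        ss.write_gene_models([stripped], out)
        sidecar = tmp_path / "donors.tsv"
        sidecar.write_text(
            "gene_id\texon_label\tcut_index\n"
            f"{locus.gene.gene_id}\t37\t105\n"
        )
        gene = ss.read_gene_models(out, donors_tsv=sidecar)[0]
        assert gene.exon("37").internal_donors == [105]


class TestSplicedCds:
    def test_no_events_concatenates_full_exons(self, locus):
        expected = "".join(
            exon_sense_sequence(locus.genome, locus.gene, e) for e in locus.gene.exons
        )
        assert ss.spliced_cds(locus.gene, locus.genome) == expected

    def test_frame_preserving_internal_donor_keeps_downstream_peptide(self, locus):
        ev = next(e for e in locus.events if e.kind == "alternative_internal_donor")
        full = ss.spliced_cds(locus.gene, locus.genome)
        short = ss.spliced_cds(locus.gene, locus.genome, locus.events,
                               {ev.event_id: "short"})
        removed = len(full) - len(short)
        assert removed % 3 == 0
        pep_full, _ = ss.translate(full)
        pep_short, _ = ss.translate(short)
        exon = locus.gene.exon(ev.exon_label)
        cut_aa = (sum(
            len(e) for e in locus.gene.exons[: locus.gene.exons.index(exon)]
        ) + ev.cut_index) // 3
        # outside the excised peptide the two translations are identical
        assert pep_short[:cut_aa] == pep_full[:cut_aa]
        assert pep_short[cut_aa:] == pep_full[cut_aa + removed // 3:]

    def test_minus_strand_palindrome_matches_plus_strand(self):
        seq = "ACGCGT" * 4  # reverse-complement palindrome
        assert reverse_complement(seq) == seq
        genome = SequenceRecord(id="c", seq=seq)
        plus = GeneModel("g+", "c", "+", [Exon("1", 0, len(seq))])
        minus = GeneModel("g-", "c", "-", [Exon("1", 0, len(seq))])
        assert ss.spliced_cds(plus, genome) == ss.spliced_cds(minus, genome)

    def test_minus_strand_locus_has_same_sense_cds(self):
        cfg_plus = ss.default_config()
        cfg_minus = ss.default_config()
        cfg_minus["strand"] = "-"
        a = ss.simulate_locus(cfg_plus, seed=4)
        b = ss.simulate_locus(cfg_minus, seed=4)
        assert ss.spliced_cds(a.gene, a.genome) == ss.spliced_cds(b.gene, b.genome)

    def test_unknown_event_key_rejected(self, locus):
        with pytest.raises(KeyError, match="nope"):
            ss.spliced_cds(locus.gene, locus.genome, locus.events, {"nope": "short"})

    def test_length_equals_sum_of_retained_segments(self, locus):
        ev_ids = [e.event_id for e in locus.events]
        choices = {ev_ids[0]: "short", ev_ids[1]: "excluded"}
        segs = retained_segments(locus.gene, locus.events, choices)
        cds = ss.spliced_cds(locus.gene, locus.genome, locus.events, choices)
        assert len(cds) == sum(cut for _, cut in segs)

    def test_cds_to_genomic_partitions_interval(self, locus):
        total = len(ss.spliced_cds(locus.gene, locus.genome))
        segs = cds_to_genomic(locus.gene, 10, total - 10)
        assert sum(e - s for _, s, e in segs) == total - 20


class TestTranslate:
    @pytest.mark.parametrize(
        "cds,peptide,stop",
        [("ATGAAATAA", "MK", True), ("ATGAAA", "MK", False)],
    )
    def test_examples(self, cds, peptide, stop):
        assert ss.translate(cds) == (peptide, stop)

    def test_partial_codon_needs_flag(self):
        with pytest.raises(ValueError):
            ss.translate("ATGAA")
        assert ss.translate("ATGAA", allow_partial=True) == ("M", False)

    def test_matches_codon_table_oracle_on_random_sequences(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            cds = "".join(rng.choice(list("ACGT"), size=300))
            expected = ""
            stop = False
            for i in range(0, 300, 3):
                aa = _CODONS[cds[i : i + 3]]
                if aa == "*":
                    stop = True
                    break
                expected += aa
            assert ss.translate(cds) == (expected, stop)

    def test_translation_invariant_under_exon_relabeling(self, locus):
        relabeled = GeneModel(
            gene_id=locus.gene.gene_id, contig=locus.gene.contig,
            strand=locus.gene.strand,
            exons=[Exon(f"x{i}", e.start, e.end, list(e.internal_donors))
                   for i, e in enumerate(locus.gene.exons)],
            cds_start_phase=locus.gene.cds_start_phase,
        )
        assert ss.translate(ss.spliced_cds(relabeled, locus.genome)) == ss.translate(
            ss.spliced_cds(locus.gene, locus.genome)
        )
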