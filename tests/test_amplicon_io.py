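"""Read filtering, demultiplexing, SNP calling and format round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mistransevo.amplicon_io import (
    Reference,
    call_snps,
    classify_snp_effect,
    demultiplex,
    filter_reads,
    read_barcode_map,
    reads_from_fastq,
    reads_from_sam,
    snp_frequency_table,
    write_snp_tsv,
    write_snp_vcf,
)

from conftest import TOY_CDS, make_population, make_read


class TestReference:
    def test_rejects_length_not_multiple_of_three(self):
        with pytest.raises(ValueError):
            Reference("bad", "ATGAAATA")

    def test_rejects_missing_terminal_stop(self):
        with pytest.raises(ValueError):
            Reference("bad", "ATGAAACCC")

    def test_rejects_internal_stop(self):
        with pytest.raises(ValueError):
            Reference("bad", "ATGTAACCCTAA")

    def test_numbering_map_labels(self, toy_reference):
        ref = Reference("toy", TOY_CDS, numbering_map={2: "104"})
        assert ref.codon_label(2) == "104"
        assert ref.codon_label(3) == "3"


class TestDemultiplex:
    def test_exact_match_assigned(self):
        reads = [make_read(TOY_CDS, barcode="ACGTAC")]
        assigned, unassigned, counts = demultiplex(reads, {"ACGTAC": "s1"})
        assert len(assigned["s1"]) == 1 and not unassigned
        assert counts["assigned"] == 1

    def test_one_mismatch_is_not_rescued(self):
        reads = [make_read(TOY_CDS, barcode="ACGTAA")]
        assigned, unassigned, counts = demultiplex(reads, {"ACGTAC": "s1"})
        assert not assigned["s1"] and len(unassigned) == 1

    def test_empty_input(self):
        assigned, unassigned, counts = demultiplex([], {"ACGTAC": "s1"})
        assert assigned == {"s1": []} and not unassigned and counts["input"] == 0

    def test_missing_barcode_routed_to_unassigned(self):
        reads = [make_read(TOY_CDS)]
        _, unassigned, _ = demultiplex(reads, {"ACGTAC": "s1"})
        assert len(unassigned) == 1


class TestFilterReads:
    LEN_RANGE = (20, 40)

    def test_reference_identical_read_passes(self, toy_reference):
        passed, rep = filter_reads(
            [make_read(TOY_CDS, 30)], toy_reference, len_range=self.LEN_RANGE
        )
        assert len(passed) == 1 and rep.n_passed == 1

    def test_mean_quality_threshold_is_strict(self, toy_reference):
        read = make_read(TOY_CDS, 20)  # mean exactly 20 -> fails ">20"
        passed, rep = filter_reads([read], toy_reference, len_range=self.LEN_RANGE)
        assert not passed and rep.removed["quality"] == 1

    def test_gapped_read_fails_span(self, toy_reference):
        read = make_read("---" + TOY_CDS[3:], 30)
        passed, rep = filter_reads([read], toy_reference, len_range=self.LEN_RANGE)
        assert not passed and rep.removed["span"] == 1

    def test_premature_stop_removed(self, toy_reference, mutate):
        # codon 6 GCT -> TCT keeps sense; GCT -> TGA needs 2 changes, so use
        # codon 9 TGG -> TGA by a single change at position 27
        seq = mutate(TOY_CDS, 27, "A")
        passed, rep = filter_reads([make_read(seq, 30)], toy_reference,
                                   len_range=self.LEN_RANGE)
        assert not passed and rep.removed["stop_codon"] == 1

    def test_length_window(self, toy_reference):
        passed, rep = filter_reads(
            [make_read(TOY_CDS, 30)], toy_reference, len_range=(31, 40)
        )
        assert not passed and rep.removed["length"] == 1

    def test_first_failing_rule_attribution(self, toy_reference):
        # both too short (after gaps) and low quality: length comes first
        read = make_read("---" + TOY_CDS[3:], 10)
        _, rep = filter_reads([read], toy_reference, len_range=(28, 40))
        assert rep.removed == {"length": 1}

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_report_conserves_read_count(self, data):
        toy_reference = Reference("toy", TOY_CDS)
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        reads = []
        for i in range(data.draw(st.integers(0, 20))):
            seq = list(TOY_CDS)
            for j in range(len(seq)):
                r = rng.random()
                if r < 0.05:
                    seq[j] = "-"
                elif r < 0.1:
                    seq[j] = "ACGT"[rng.integers(4)]
            reads.append(make_read("".join(seq), int(rng.integers(5, 41)), f"r{i}"))
        _, rep = filter_reads(reads, toy_reference, len_range=(25, 35))
        assert rep.n_input == rep.n_passed + sum(rep.removed.values())


class TestCallSnps:
    def test_identity_read_has_no_calls(self, toy_reference):
        assert call_snps(make_read(TOY_CDS, 30), toy_reference) == []

    def test_single_high_quality_mismatch(self, toy_reference, mutate):
        read = make_read(mutate(TOY_CDS, 4, "G"), 30)
        assert call_snps(read, toy_reference) == [(4, "G")]

    def test_low_quality_mismatch_suppressed(self, toy_reference, mutate):
        quals = np.full(len(TOY_CDS), 30)
        quals[3] = 18
        read = make_read(mutate(TOY_CDS, 4, "G"), quals)
        assert call_snps(read, toy_reference) == []

    def test_gap_and_n_never_called(self, toy_reference):
        seq = "N" + "-" + TOY_CDS[2:]
        assert call_snps(make_read(seq, 30), toy_reference) == []

    def test_monotone_in_quality_threshold(self, toy_reference, mutate):
        rng = np.random.default_rng(0)
        seq = mutate(mutate(TOY_CDS, 4, "G"), 10, "A")
        read = make_read(seq, rng.integers(5, 41, size=len(TOY_CDS)))
        counts = [len(call_snps(read, toy_reference, q)) for q in (0, 10, 20, 30, 40)]
        assert counts == sorted(counts, reverse=True)


class TestClassifyEffect:
    def test_synonymous_third_position(self, toy_reference):
        # codon 3 CCC -> CCT
        effect, label = classify_snp_effect(9, "T", toy_reference)
        assert effect == "synonymous" and label == "P3P"

    def test_nonsynonymous_with_label(self, toy_reference):
        # codon 2 AAA (K) -> GAA (E)
        effect, label = classify_snp_effect(4, "G", toy_reference)
        assert effect == "nonsynonymous" and label == "K2E"

    def test_nonsense(self, toy_reference):
        # codon 9 TGG -> TGA
        effect, label = classify_snp_effect(27, "A", toy_reference)
        assert effect == "nonsense" and label == "W9*"

    def test_position_out_of_range(self, toy_reference):
        with pytest.raises(ValueError):
            classify_snp_effect(0, "A", toy_reference)


class TestSnpFrequencyTable:
    def test_simple_frequency(self, toy_reference, mutate):
        seqs = [mutate(TOY_CDS, 4, "G")] * 10 + [TOY_CDS] * 90
        table = snp_frequency_table(make_population(seqs), toy_reference)
        assert len(table) == 1
        rec = table.records[0]
        assert (rec.position, rec.alt_base) == (4, "G")
        assert rec.frequency == pytest.approx(0.10)
        assert rec.count == 10 and rec.depth == 100

    def test_all_reference_population_gives_empty_table(self, toy_reference):
        table = snp_frequency_table(make_population([TOY_CDS] * 5), toy_reference)
        assert len(table) == 0
        assert (table.site_depth == 5).all()

    def test_gapped_read_excluded_from_depth(self, toy_reference, mutate):
        # hand enumeration of a 5-read toy set: 2 mutant, 2 reference,
        # 1 gapped at the site -> count 2, depth 4, frequency 1/2
        mut = mutate(TOY_CDS, 4, "G")
        gapped = TOY_CDS[:3] + "-" + TOY_CDS[4:]
        table = snp_frequency_table(
            make_population([mut, mut, TOY_CDS, TOY_CDS, gapped]), toy_reference
        )
        rec = table.records[0]
        assert rec.count == 2 and rec.depth == 4
        assert rec.frequency == pytest.approx(0.5)

    def test_frequencies_are_exact_integer_ratios(self, toy_reference, mutate):
        rng = np.random.default_rng(7)
        seqs = []
        for _ in range(40):
            s = TOY_CDS
            for _ in range(rng.integers(0, 3)):
                s = mutate(s, int(rng.integers(1, len(TOY_CDS) + 1)),
                           "ACGT"[rng.integers(4)])
            seqs.append(s)
        table = snp_frequency_table(make_population(seqs), toy_reference)
        for rec in table.records:
            assert 0.0 <= rec.frequency <= 1.0
            assert rec.frequency == rec.count / rec.depth


class TestFormatsRoundTrip:
    def test_fastq_round_trip(self, tmp_path, toy_reference, mutate):
        from mistransevo.evo_sim import write_fastq

        seq = mutate(TOY_CDS, 4, "G")
        records = [("read0", "ACGTAC" + seq, np.full(6 + len(seq), 38))]
        path = tmp_path / "toy.fastq"
        write_fastq(records, path)
        reads = reads_from_fastq(path, toy_reference)
        assert reads[0].barcode == "ACGTAC"
        assert reads[0].aligned_seq == seq
        assert reads[0].qualities[0] == 38

    def test_sam_projection(self, tmp_path, toy_reference):
        # r1 full match; r2 insertion dropped; r3 deletion becomes gaps and
        # soft clip ignored; secondary record skipped
        L = len(TOY_CDS)
        sam = tmp_path / "toy.sam"
        body = TOY_CDS
        ins = body[:10] + "GG" + body[10:]
        dele = body[:10] + body[13:]
        lines = [
            "@HD\tVN:1.6",
            f"@SQ\tSN:toy\tLN:{L}",
            f"r1\t0\ttoy\t1\t60\t{L}M\t*\t0\t0\t{body}\t{'I' * L}",
            f"r2\t0\ttoy\t1\t60\t10M2I{L - 10}M\t*\t0\t0\t{ins}\t{'I' * (L + 2)}",
            f"r3\t0\ttoy\t1\t60\t10M3D{L - 13}M\t*\t0\t0\t{dele}\t{'I' * (L - 3)}",
            f"r1\t256\ttoy\t1\t60\t{L}M\t*\t0\t0\t{body}\t{'I' * L}",
        ]
        sam.write_text("\n".join(lines) + "\n")
        reads = reads_from_sam(sam, toy_reference)
        assert [r.read_id for r in reads] == ["r1", "r2", "r3"]
        assert reads[0].aligned_seq == TOY_CDS
        assert reads[1].aligned_seq == TOY_CDS  # insertion dropped
        assert reads[2].aligned_seq == TOY_CDS[:10] + "---" + TOY_CDS[13:]
        assert reads[2].qualities[11] == -1

    def test_vcf_and_tsv_export(self, tmp_path, toy_reference, mutate):
        seqs = [mutate(TOY_CDS, 4, "G")] * 2 + [TOY_CDS] * 2
        table = snp_frequency_table(make_population(seqs), toy_reference)
        vcf = tmp_path / "out.vcf"
        tsv = tmp_path / "out.tsv"
        write_snp_vcf(table, toy_reference, vcf)
        write_snp_tsv(table, tsv)
        data_lines = [
            l for l in vcf.read_text().splitlines() if not l.startswith("#")
        ]
        assert data_lines == ["toy\t4\t.\tA\tG\t.\tPASS\tAF=0.5;DP=4"]
        assert "aa_change" in tsv.read_text().splitlines()[0]

    def test_barcode_map_rejects_duplicates(self, tmp_path):
        path = tmp_path / "bc.tsv"
        path.write_text("ACGTAC\ts1\nACGTAC\ts2\n")
        with pytest.raises(ValueError):
            read_barcode_map(path)


def test_numbering_map_file_gives_display_labels(tmp_path, toy_reference):
    from mistransevo.amplicon_io import read_numbering_map

    path = tmp_path / "numbering.tsv"
    path.write_text("2\t104\n3\t182\n")
    nmap = read_numbering_map(path)
    ref = Reference("toy", TOY_CDS, numbering_map=nmap)
    _, label = classify_snp_effect(4, "G", ref)
    assert label == "K104E"
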