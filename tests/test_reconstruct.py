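"""Reconstruction stages: embedding, screening, assembly, annotation."""

import numpy as np
import pandas as pd
import pytest

from tcrkit.align import revcomp
from tcrkit.reconstruct import (
    Contig,
    ReadRecord,
    annotate_contig,
    assemble_cell,
    assemble_exhaustive,
    embed_barcodes,
    embed_read_id,
    filter_cdr3_validity,
    group_by_barcode,
    parse_embedded_id,
    read_fastq,
    screen_tcr_reads,
)
from tcrkit.simulate import SimConfig, recombine_vdj, simulate_repertoire


class TestEmbedding:
    def test_id_format_rule(self):
        assert embed_read_id("AAACGG", "TTT", "r7") == "AAACGG:TTT:r7"

    def test_parse_back_is_lossless_with_colons_in_original_id(self):
        rid = embed_read_id("AAACGG", "TTT", "machine:1:lane2")
        assert parse_embedded_id(rid) == ("AAACGG", "TTT", "machine:1:lane2")

    def test_paired_embedding_keeps_pairs_synchronized(self, tmp_path):
        n = 100
        rng = np.random.default_rng(2)
        r1 = tmp_path / "r1.fastq"
        r2 = tmp_path / "r2.fastq"
        with r1.open("w") as f1, r2.open("w") as f2:
            for i in range(n):
                bc = "".join(rng.choice(list("ACGT"), size=6))
                f1.write(f"@p{i}\n{bc}TTT\n+\n{'I' * 9}\n")
                f2.write(f"@p{i}\nACGTACGTACGT\n+\n{'I' * 12}\n")
        out2 = tmp_path / "out2.fastq"
        out1 = tmp_path / "out1.fastq"
        counts = embed_barcodes(r1, r2, out2, barcode_length=6, umi_length=3,
                                out_r1_path=out1)
        assert counts["input"] == counts["embedded"] == n
        ids1 = [line[1:] for line in out1.read_text().splitlines()[::4]]
        ids2 = [line[1:] for line in out2.read_text().splitlines()[::4]]
        assert ids1 == ids2
        assert all(parse_embedded_id(i)[2] == f"p{k}" for k, i in enumerate(ids2))

    def test_unreadable_barcodes_dropped_and_counted(self, tmp_path):
        r1 = tmp_path / "r1.fastq"
        r1.write_text("@a\nNNNNTTTACGT\n+\nIIIIIIIIIII\n@b\nACGTTTTACGT\n+\nIIIIIIIIIII\n")
        out = tmp_path / "out.fastq"
        counts = embed_barcodes(r1, None, out, barcode_length=4, umi_length=3)
        assert counts == {"input": 2, "embedded": 1, "dropped": 1, "out": str(out)}

    def test_desynchronized_mates_raise(self, tmp_path):
        r1 = tmp_path / "r1.fastq"
        r2 = tmp_path / "r2.fastq"
        r1.write_text("@a\nACGTACGT\n+\nIIIIIIII\n")
        r2.write_text("@b\nACGTACGT\n+\nIIIIIIII\n")
        with pytest.raises(ValueError, match="desynchronized"):
            embed_barcodes(r1, r2, tmp_path / "o.fastq", 4, 2)

    def test_simulator_round_trip_recovers_all_barcodes(
        self, small_sim_config, reference, tmp_path
    ):
        """Embed-then-parse over simulator output recovers (barcode,
        UMI) for 100% of reads when barcode bases are error-free."""
        out = simulate_repertoire(small_sim_config, reference, tmp_path)
        samples = pd.read_csv(out["samples"], sep="\t")
        truth = pd.read_csv(out["truth"], sep="\t")
        row = samples.iloc[0]
        embedded = tmp_path / "embedded.fastq"
        counts = embed_barcodes(
            tmp_path / row.fastq_r1, tmp_path / row.fastq_r2, embedded,
            small_sim_config.barcode_length, small_sim_config.umi_length,
        )
        assert counts["dropped"] == 0
        cells = set(truth.loc[truth.sample_id == row.sample_id, "cell_id"])
        seen = {read.barcode for read in read_fastq(embedded)}
        assert seen == cells


class TestGrouping:
    def test_partition_by_barcode(self):
        reads = [
            ReadRecord(embed_read_id(bc, "T", f"r{i}"), "ACGT")
            for i, bc in enumerate(["A"] * 4 + ["C"] * 2)
        ]
        groups, dropped = group_by_barcode(reads)
        assert {k: len(v) for k, v in groups.items()} == {"A": 4, "C": 2}
        assert dropped == 0
        assert sum(map(len, groups.values())) + dropped == len(reads)

    def test_empty_input(self):
        assert group_by_barcode([]) == ({}, 0)

    def test_unparseable_ids_dropped_or_abort(self):
        reads = [ReadRecord("noprefix", "ACGT")]
        groups, dropped = group_by_barcode(reads)
        assert groups == {} and dropped == 1
        with pytest.raises(ValueError):
            group_by_barcode([ReadRecord("noprefix", "ACGT")], on_error="abort")


class TestScreen:
    def test_exact_tcr_read_retained_with_locus_hint(self, reference):
        seg = reference.by_type("V", "TRB")[0]
        reads = [ReadRecord("r1", seg.sequence[:60])]
        kept = list(screen_tcr_reads(reads, reference, min_score=25))
        assert len(kept) == 1
        assert kept[0].locus_hint == "TRB"

    def test_unrelated_read_dropped(self, reference):
        """Housekeeping-like random read sharing no 15-mer with the
        reference is dropped (brute-force confirms sub-threshold)."""
        rng = np.random.default_rng(99)
        k = reference.k
        ref_words = {
            seg.sequence[i : i + k]
            for seg in reference.segments.values()
            for i in range(len(seg.sequence) - k + 1)
        }
        while True:
            read = "".join(rng.choice(list("ACGT"), size=60))
            words = {
                s[i : i + k]
                for s in (read, revcomp(read))
                for i in range(len(s) - k + 1)
            }
            if not words & ref_words:
                break
        assert list(screen_tcr_reads([ReadRecord("r", read)], reference, 25)) == []

    def test_zero_threshold_reduces_to_candidacy(self, reference):
        seg = reference.by_type("J", "TRA")[0]
        reads = [ReadRecord("r1", seg.sequence[:20] + "A" * 40)]
        assert len(list(screen_tcr_reads(reads, reference, min_score=0))) == 1


class TestAssembly:
    def test_single_forced_merge(self):
        rng = np.random.default_rng(1)
        full = "".join(rng.choice(list("ACGT"), size=90))
        reads = [full[:60], full[30:]]
        contigs = assemble_cell(reads, min_overlap=30, max_mismatch=0,
                                min_contig_len=60, cell_barcode="BC")
        assert len(contigs) == 1
        assert contigs[0].sequence == full
        assert contigs[0].support == 2
        assert contigs[0].contig_id == "BC_1"

    def test_no_overlap_returns_deduplicated_reads(self):
        rng = np.random.default_rng(2)
        a = "".join(rng.choice(list("ACGT"), size=70))
        b = "".join(rng.choice(list("ACGT"), size=70))
        contigs = assemble_cell([a, a, b], min_overlap=30, max_mismatch=0,
                                min_contig_len=60)
        assert sorted(c.sequence for c in contigs) == sorted([a, b])
        supports = {c.sequence: c.support for c in contigs}
        assert supports[a] == 2 and supports[b] == 1

    def test_reverse_complement_reads_merge(self):
        rng = np.random.default_rng(3)
        full = "".join(rng.choice(list("ACGT"), size=90))
        contigs = assemble_cell([full[:60], revcomp(full[30:])],
                                min_overlap=30, max_mismatch=0, min_contig_len=60)
        assert len(contigs) == 1
        assert contigs[0].sequence in (full, revcomp(full))

    def test_result_is_input_order_independent(self):
        rng = np.random.default_rng(4)
        full = "".join(rng.choice(list("ACGT"), size=120))
        reads = [full[i : i + 60] for i in (0, 20, 40, 60)]
        a = assemble_cell(reads, 30, 0, 60)
        b = assemble_cell(reads[::-1], 30, 0, 60)
        assert [c.sequence for c in a] == [c.sequence for c in b]

    def test_short_fragments_filtered_by_min_contig_len(self):
        contigs = assemble_cell(["ACGTACGT"], min_overlap=5, max_mismatch=0,
                                min_contig_len=60)
        assert contigs == []

    @pytest.mark.parametrize("seed", range(8))
    def test_greedy_matches_exhaustive_oracle_on_tiny_instances(self, seed):
        """For <= 8 reads tiled with unique exact overlaps, greedy
        assembly reaches the same maximal contig as exhaustive
        merge-order search."""
        rng = np.random.default_rng(seed)
        full = "".join(rng.choice(list("ACGT"), size=150))
        n_reads = int(rng.integers(4, 9))  # spacing <= 30 keeps overlaps >= min_overlap
        starts = np.round(np.linspace(0, 90, n_reads)).astype(int)
        reads = [full[s : s + 60] for s in starts]
        oracle = assemble_exhaustive(reads, min_overlap=20)
        greedy = assemble_cell(reads, min_overlap=20, max_mismatch=0, min_contig_len=60)
        longest = max((c.sequence for c in greedy), key=len)
        assert longest in oracle or revcomp(longest) in oracle


class TestAnnotation:
    def _contig(self, seq, barcode="BC"):
        return Contig(cell_barcode=barcode, contig_id=f"{barcode}_1",
                      sequence=seq, support=1)

    def test_simulator_round_trip_annotation(self, reference):
        """A full transcript from the recombination model annotates back
        to its own V/J calls and exact junction."""
        rng = np.random.default_rng(21)
        config = SimConfig(seed=0)
        for locus in ("TRA", "TRB", "TRG", "TRD"):
            clone = recombine_vdj(reference, locus, rng, config)
            ann = annotate_contig(self._contig(clone.transcript), reference)
            assert ann.v_call == clone.v_id
            assert ann.j_call == clone.j_id
            assert ann.cdr3_nt == clone.junction_nt
            assert ann.cdr3_aa == clone.junction_aa
            assert ann.productive

    def test_reverse_complement_contig_is_reoriented(self, reference):
        clone = recombine_vdj(reference, "TRB", np.random.default_rng(8), SimConfig())
        ann = annotate_contig(self._contig(revcomp(clone.transcript)), reference)
        assert ann.productive
        assert ann.cdr3_nt == clone.junction_nt
        assert ann.sequence == clone.transcript

    def test_v_only_contig_fails_no_j(self, reference):
        seg = reference.by_type("V", "TRB")[0]
        ann = annotate_contig(self._contig(seg.sequence), reference)
        assert ann.fail_reasons == ["no_j"]
        assert not ann.productive

    def test_no_v_hit_fails_no_v(self, reference):
        rng = np.random.default_rng(31)
        ann = annotate_contig(
            self._contig("".join(rng.choice(list("ACGT"), size=80))), reference
        )
        assert ann.fail_reasons == ["no_v"]

    def test_engineered_stop_codon_marks_unproductive(self, toy_reference):
        v = toy_reference.segments["TRBV90*01"]
        j = toy_reference.segments["TRBJ90*01"]
        # insert an in-frame TAA between the V end and the J start
        seq = v.sequence + "TAA" + j.sequence
        ann = annotate_contig(self._contig(seq), toy_reference)
        assert not ann.productive
        assert "stop_codon" in ann.fail_reasons


class TestCdr3Filter:
    # the printed chain-specific rule set, one row per clause
    CASES = [
        ("CAVRDSNYQLIW", "TRA", True, None),
        ("CAVRDSNYQLIF", "TRA", True, None),
        ("AAVRDSNYQLIW", "TRA", False, "start_not_cysteine"),
        ("CAVRDSNYQLIL", "TRA", False, "terminal_residue"),
        ("CASSLGQAYEQYF", "TRB", True, None),
        ("CSARDPGLAGGF", "TRB", False, "missing_cass_motif"),
        ("CASSLGQAYEQYW", "TRB", False, "terminal_residue"),
        ("CASS*GQAYEQYF", "TRB", False, "stop_codon"),
        ("CAVRDSNYQLIW", "TRG", True, None),
        ("CAVRDSNYQLIL", "TRG", False, "terminal_residue"),
        ("CASSDTDKLIF", "TRD", True, None),
        ("CADTDKLIF", "TRD", False, "missing_cass_motif"),
    ]

    @pytest.mark.parametrize("cdr3,locus,valid,reason", CASES)
    def test_rule_table(self, cdr3, locus, valid, reason):
        assert filter_cdr3_validity(cdr3, locus) == (valid, reason)

    def test_relaxed_mode_drops_cass_requirement(self):
        assert filter_cdr3_validity("CADTDKLIF", "TRD", relaxed=True) == (True, None)
        assert filter_cdr3_validity("AADTDKLIF", "TRD", relaxed=True) == (
            False,
            "start_not_cysteine",
        )

    def test_empty_string_raises(self):
        with pytest.raises(ValueError):
            filter_cdr3_validity("", "TRA")
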