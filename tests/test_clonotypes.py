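"""Clonotype calling, sharing classes and repertoire summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrkit.clonotypes import (
    call_clonotypes,
    cdr3_length_distribution,
    classify_sharing,
    positional_frequency_matrix,
    read_repertoire,
    select_top_shared,
    sharing_summary,
    strip_allele,
    vj_pairing_matrix,
    write_repertoire,
)

LOG2_20 = math.log2(20)


def make_samples(rows):
    return pd.DataFrame(rows, columns=["sample_id", "patient", "group", "tissue", "timepoint"])


SAMPLES = make_samples(
    [
        ("S1", "P1", "MSS", "blood", "Pre"),
        ("S2", "P4", "MSI", "tumor", "Pre"),
        ("S3", "P6", "MSI", "normal", "Pre"),
    ]
)


def ann_row(sample, cell, locus="TRB", v="TRBV27*01", j="TRBJ2-3*01", cdr3="CASSLGQAYEQYF"):
    return {
        "sample_id": sample,
        "cell_id": cell,
        "locus": locus,
        "v_call": v,
        "j_call": j,
        "cdr3_aa": cdr3,
        "productive": "T",
    }


class TestCallClonotypes:
    def test_identical_keys_aggregate(self):
        ann = pd.DataFrame([ann_row("S1", f"c{i}") for i in range(3)])
        table = call_clonotypes(ann, SAMPLES)
        assert len(table.records) == 1
        assert table.records["total_cells"].iloc[0] == 3

    def test_different_v_gene_splits_keys(self):
        ann = pd.DataFrame(
            [ann_row("S1", "c1"), ann_row("S1", "c2", v="TRBV6-5*01")]
        )
        table = call_clonotypes(ann, SAMPLES)
        assert len(table.records) == 2

    def test_allele_stripping_merges_keys(self):
        """Same gene, different alleles: one clonotype."""
        ann = pd.DataFrame(
            [ann_row("S1", "c1", v="TRBV27*01"), ann_row("S1", "c2", v="TRBV27*02")]
        )
        table = call_clonotypes(ann, SAMPLES)
        assert len(table.records) == 1
        assert table.records["v_gene"].iloc[0] == "TRBV27"

    def test_duplicate_contigs_per_cell_count_once(self):
        ann = pd.DataFrame([ann_row("S1", "c1"), ann_row("S1", "c1")])
        table = call_clonotypes(ann, SAMPLES)
        assert table.records["total_cells"].iloc[0] == 1

    def test_unproductive_records_excluded(self):
        rows = [ann_row("S1", "c1"), {**ann_row("S1", "c2"), "productive": "F"}]
        table = call_clonotypes(pd.DataFrame(rows), SAMPLES)
        assert table.records["total_cells"].iloc[0] == 1

    def test_unknown_sample_id_raises(self):
        ann = pd.DataFrame([ann_row("S9", "c1")])
        with pytest.raises(ValueError, match="missing from metadata"):
            call_clonotypes(ann, SAMPLES)

    def test_simulator_truth_round_trip(self, pipeline_run):
        """Clonotype keys called from truth equal keys called from the
        reconstruction output of the same error-free run."""
        truth, samples = pipeline_run["truth"], pipeline_run["samples"]
        rec = pipeline_run["annotations"]
        t_table = call_clonotypes(truth, samples)
        r_table = call_clonotypes(rec[rec["productive"] == "T"], samples)
        t_keys = set(map(tuple, t_table.records[["locus", "v_gene", "cdr3_aa"]].values))
        r_keys = set(map(tuple, r_table.records[["locus", "v_gene", "cdr3_aa"]].values))
        assert t_keys == r_keys


class TestSharing:
    def _table(self, patient_sets):
        rows = []
        for i, patients in enumerate(patient_sets):
            for p in patients:
                sample = {"P1": "S1", "P4": "S2", "P6": "S3"}[p]
                rows.append(ann_row(sample, f"c{i}", cdr3=f"CASSLGQ{chr(65 + i)}YF"))
        return call_clonotypes(pd.DataFrame(rows), SAMPLES)

    def test_three_way_classification(self):
        table = classify_sharing(
            self._table([{"P1"}, {"P4", "P6"}, {"P1", "P4"}]),
            {"P1": "MSS", "P4": "MSI", "P6": "MSI"},
        )
        assert list(table.records["sharing_class"]) == [
            "private",
            "intra_group",
            "inter_group",
        ]

    def test_classes_partition_the_table(self):
        table = classify_sharing(self._table([{"P1"}, {"P4"}, {"P1", "P4", "P6"}]))
        assert sharing_summary(table).sum() == len(table.records)

    def test_unmapped_patient_raises(self):
        with pytest.raises(ValueError, match="missing from group map"):
            classify_sharing(self._table([{"P1"}]), {"P4": "MSI"})


class TestCdr3Lengths:
    def test_mode_with_tie_to_smaller(self):
        hist, mode = cdr3_length_distribution(["A" * 12, "B" * 12, "C" * 13, "D" * 13])
        assert hist == {12: 2, 13: 2}
        assert mode == 12

    def test_single_record(self):
        assert cdr3_length_distribution(["CASSLGQYF"]) == ({9: 1}, 9)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cdr3_length_distribution([])


class TestPositionalFrequencies:
    def test_fully_conserved_columns(self):
        matrix, ic = positional_frequency_matrix(["CASSF", "CASSF"])
        assert np.allclose(matrix.max(axis=1), 1.0)
        assert np.allclose(ic, LOG2_20)

    def test_uniform_column_has_zero_information(self):
        seqs = [aa for aa in "ACDEFGHIKLMNPQRSTVWY"]
        matrix, ic = positional_frequency_matrix(seqs)
        assert np.allclose(matrix.iloc[0], 0.05)
        assert abs(ic[0]) < 1e-12

    def test_two_residue_column_closed_form(self):
        _, ic = positional_frequency_matrix(["A", "C"])
        assert math.isclose(ic[0], LOG2_20 - 1.0)

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            positional_frequency_matrix(["CAS", "CASS"])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=6, max_size=6),
            min_size=1,
            max_size=30,
        )
    )
    def test_rows_sum_to_one_and_ic_in_range(self, seqs):
        matrix, ic = positional_frequency_matrix(seqs)
        assert np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(ic >= -1e-9) and np.all(ic <= LOG2_20 + 1e-9)


class TestVjPairing:
    def test_pair_counts(self):
        records = pd.DataFrame(
            {"v_gene": ["V1", "V1", "V1"], "j_gene": ["J1", "J1", "J2"]}
        )
        pairs = vj_pairing_matrix(records)
        assert pairs.iloc[0].tolist() == ["V1", "J1", 2]
        assert pairs.iloc[1].tolist() == ["V1", "J2", 1]

    def test_empty_selection(self):
        assert vj_pairing_matrix(pd.DataFrame(columns=["v_gene", "j_gene"])).empty

    def test_top_n_restriction(self):
        records = pd.DataFrame(
            {"v_gene": ["V1"] * 3 + ["V2"] * 2 + ["V3"], "j_gene": ["J1"] * 6}
        )
        pairs = vj_pairing_matrix(records, top_n=2)
        assert set(pairs["v_gene"]) == {"V1", "V2"}

    def test_simulated_dominant_pair_is_argmax(self, reference, tmp_path):
        """Usage weights forcing one (V, J) pair make it the most
        frequent pairing in the called repertoire."""
        from tcrkit.simulate import SimConfig, simulate_repertoire

        config = SimConfig(
            seed=13,
            n_patients=2,
            n_clonotypes_per_sample=25,
            tissues=("blood",),
            timepoints=("Pre",),
            loci=("TRA",),
            locus_weights=(1.0,),
            usage_weights={
                ("TRA", "V"): (0.85, 0.05, 0.05, 0.05),
                ("TRA", "J"): (0.9, 0.05, 0.05),
            },
            clone_size_law="constant",
            clone_size_param=1,
            shared_clone_fraction=0.0,
        )
        out = simulate_repertoire(config, reference, tmp_path)
        truth = pd.read_csv(out["truth"], sep="\t")
        samples = pd.read_csv(out["samples"], sep="\t")
        table = call_clonotypes(truth, samples)
        pairs = vj_pairing_matrix(table.records)
        v1 = strip_allele(reference.by_type("V", "TRA")[0].segment_id)
        j1 = strip_allele(reference.by_type("J", "TRA")[0].segment_id)
        assert pairs.iloc[0][["v_gene", "j_gene"]].tolist() == [v1, j1]


class TestTopShared:
    def _rich_table(self):
        rows = []
        # clonotype A: 3 patients, normal+tumor; B: 2 patients; C: tumor only
        for p, s in [("P1", "S1"), ("P4", "S2"), ("P6", "S3")]:
            rows.append(ann_row(s, f"{p}_c1", cdr3="CASSAAAAYF"))
        for s in ["S2", "S3"]:
            rows.append(ann_row(s, f"{s}_c2", cdr3="CASSBBBBYF"))
        rows.append(ann_row("S2", "c3", cdr3="CASSCCCCYF"))
        return classify_sharing(call_clonotypes(pd.DataFrame(rows), SAMPLES))

    def test_rank_by_patient_count(self):
        ranked, _ = select_top_shared(self._rich_table(), n=3)
        assert list(ranked["cdr3_aa"])[:2] == ["CASSAAAAYF", "CASSBBBBYF"]

    def test_normal_tumor_scope_excludes_tumor_only(self):
        ranked, _ = select_top_shared(
            self._rich_table(), n=10, scope="normal_tumor_shared"
        )
        assert "CASSCCCCYF" not in set(ranked["cdr3_aa"])

    def test_n_larger_than_available_returns_all(self):
        ranked, _ = select_top_shared(self._rich_table(), n=100)
        assert len(ranked) == 3

    def test_invalid_n_raises(self):
        with pytest.raises(ValueError):
            select_top_shared(self._rich_table(), n=0)

    def test_sankey_edges_cover_selected_clonotypes(self):
        ranked, edges = select_top_shared(self._rich_table(), n=2)
        assert set(edges["clonotype_id"]) <= set(ranked.index)
        assert {"group", "tissue", "patients", "cells"} <= set(edges.columns)


def test_repertoire_tsv_round_trip(pipeline_run, tmp_path):
    table = classify_sharing(
        call_clonotypes(pipeline_run["truth"], pipeline_run["samples"])
    )
    paths = [tmp_path / f"{n}.tsv" for n in ("records", "counts", "samples")]
    write_repertoire(table, *paths)
    back = read_repertoire(*paths)
    assert back.records["sharing_class"].equals(table.records["sharing_class"])
    assert back.counts["cells"].sum() == table.counts["cells"].sum()
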