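import numpy as np
import pandas as pd
import pytest

from tcrkit.pipeline import RunConfig, run_end_to_end
from tcrkit.reference import SegmentRecord, build_reference
from tcrkit.simulate import SimConfig, synthetic_reference


@pytest.fixture(scope="session")
def reference():
    """Small synthetic germline reference shared across tests."""
    return synthetic_reference(seed=1)


@pytest.fixture(scope="session")
def toy_reference():
    """Hand-built two-locus reference with known anchors.

    TRB V carries CASS at its 2nd-CYS anchor; junction built with zero
    trims and insertions is stop-free by construction.
    """
    rng = np.random.default_rng(11)
    nt = np.array(list("ACGT"))

    def random_nt(n):
        return "".join(rng.choice(nt, size=n))

    head_v = random_nt(60)
    trbv = head_v + "TGT" + "GCTAGTTCA" + "GGA"  # ...C A S S G
    trbj = "GCAGAAACTCAA" + "TTTGGTCAAGGC" + "ACCGAGCTC"  # anchor F at 12
    trav = random_nt(60) + "TGT" + "GCAGTGAGA"  # ...C A V R
    traj = "AACTATCAG" + "TGGGGCCGAGGC" + "ACT"  # anchor W at 9
    return build_reference(
        [
            SegmentRecord("TRBV90*01", "TRB", "V", trbv, 60),
            SegmentRecord("TRBJ90*01", "TRB", "J", trbj, 12),
            SegmentRecord("TRAV90*01", "TRA", "V", trav, 60),
            SegmentRecord("TRAJ90*01", "TRA", "J", traj, 9),
        ],
        k=15,
    )


@pytest.fixture(scope="session")
def small_sim_config():
    """Error-free single-cell-per-clonotype design for bookkeeping tests."""
    return SimConfig(
        seed=5,
        n_patients=2,
        n_clonotypes_per_sample=10,
        tissues=("blood",),
        timepoints=("Pre",),
        clone_size_law="constant",
        clone_size_param=1,
        reads_per_cell_chain=5,
        error_rate=0.0,
    )


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full error-free pipeline run reused by round-trip tests.

    Study design: 2 patients x 3 tissues x 2 timepoints, 20 clonotypes
    per sample, >= 5 tiling reads per chain, no sequencing error.
    """
    outdir = tmp_path_factory.mktemp("e2e")
    config = RunConfig(
        outdir=str(outdir),
        seed=42,
        sim=SimConfig(
            seed=42,
            n_patients=2,
            n_clonotypes_per_sample=20,
            clone_size_law="constant",
            clone_size_param=1,
            reads_per_cell_chain=6,
            error_rate=0.0,
        ),
    )
    manifest = run_end_to_end(config)
    return {
        "config": config,
        "manifest": manifest,
        "outdir": outdir,
        "truth": pd.read_csv(outdir / "sim" / "truth.airr.tsv", sep="\t"),
        "annotations": pd.read_csv(outdir / "annotations.airr.tsv", sep="\t"),
        "benchmark": pd.read_csv(outdir / "benchmark.tsv", sep="\t"),
        "metrics": pd.read_csv(outdir / "sample_metrics.tsv", sep="\t"),
        "samples": pd.read_csv(outdir / "sim" / "samples.tsv", sep="\t"),
    }
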