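"""End-to-end orchestration: simulate -> embed -> screen -> group ->
assemble -> annotate -> clonotype -> metrics -> benchmark.

Every run writes a JSON manifest listing each artifact with a sha256
checksum; identical config + seed reproduces identical checksums.
Stage counts (input / retained / dropped) are logged as JSON lines so
conservation checks are assertable from the log alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import clonotypes as ct
from .benchmark import MATCH_MODES, benchmark_report
from .benchmark import benchmark as run_benchmark
from . import metrics as mx
from . import reconstruct as rc
from .reference import ReferenceSet, load_reference
from .simulate import AIRR_COLUMNS, SimConfig, simulate_repertoire, synthetic_reference

ANNOTATION_COLUMNS = [
    "cell_id",
    "sample_id",
    "contig_id",
    "locus",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_aa",
    "productive",
    "duplicate_count",
    "ambiguous_locus",
    "fail_reasons",
]


@dataclass
class RunConfig:
    """Flat parameter set for one pipeline run."""

    outdir: str = "tcrkit_run"
    seed: int = 0
    reference_fasta: str | None = None  # None -> bundled synthetic reference
    k: int = 15
    min_score: float = rc.DEFAULT_MIN_SCORE
    min_overlap: int = rc.DEFAULT_MIN_OVERLAP
    max_mismatch: int = rc.DEFAULT_MAX_MISMATCH
    min_contig_len: int = rc.DEFAULT_MIN_CONTIG_LEN
    locus_margin: float = rc.DEFAULT_LOCUS_MARGIN
    relaxed_filter: bool = False
    match_modes: tuple[str, ...] = MATCH_MODES
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)

    def to_file(self, path: str | Path) -> None:
        flat = dataclasses.asdict(self)
        sim = flat.pop("sim")
        if sim.get("usage_weights"):
            sim["usage_weights"] = {
                f"{locus}:{seg_type}": list(w)
                for (locus, seg_type), w in sim["usage_weights"].items()
            }
        with Path(path).open("w") as fh:
            for key, value in flat.items():
                fh.write(f"{key}={json.dumps(value)}\n")
            for key, value in sim.items():
                fh.write(f"sim.{key}={json.dumps(value)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        top: dict = {}
        sim: dict = {}
        with Path(path).open() as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, raw = line.partition("=")
                value = json.loads(raw)
                if key.startswith("sim."):
                    sim[key[4:]] = value
                else:
                    top[key] = value
        for tup_field in ("match_modes",):
            if tup_field in top and isinstance(top[tup_field], list):
                top[tup_field] = tuple(top[tup_field])
        for tup_field in ("tissues", "timepoints", "loci", "locus_weights"):
            if tup_field in sim and isinstance(sim[tup_field], list):
                sim[tup_field] = tuple(sim[tup_field])
        if sim.get("usage_weights"):
            sim["usage_weights"] = {
                tuple(key.split(":")): tuple(w)
                for key, w in sim["usage_weights"].items()
            }
        return cls(sim=SimConfig(**sim), **top)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, counts: dict, cause: Exception):
        super().__init__(f"stage {stage!r} failed after counts {counts}: {cause}")
        self.stage = stage
        self.counts = counts


def _resolve(path: str, base: Path) -> Path:
    p = Path(path)
    return p if p.is_absolute() else base / p


def reconstruct_sample(
    sample_row: dict,
    reference: ReferenceSet,
    config: RunConfig,
    workdir: Path,
    log_rows: list[dict],
    fastq_dir: Path | None = None,
) -> pd.DataFrame:
    """Run embed -> screen -> group -> assemble -> annotate for one sample."""
    sample_id = sample_row["sample_id"]
    fastq_dir = fastq_dir or Path(".")
    embedded = workdir / f"{sample_id}.embedded.fastq"
    if "fastq" in sample_row and isinstance(sample_row.get("fastq"), str):
        # pre-embedded single-end input: IDs already carry barcode:umi
        embedded = _resolve(sample_row["fastq"], fastq_dir)
        n_input = sum(1 for _ in rc.read_fastq(embedded))
        embed_counts = {"input": n_input, "embedded": n_input, "dropped": 0}
    else:
        embed_counts = rc.embed_barcodes(
            _resolve(sample_row["fastq_r1"], fastq_dir),
            _resolve(sample_row["fastq_r2"], fastq_dir),
            embedded,
            barcode_length=config.sim.barcode_length,
            umi_length=config.sim.umi_length,
        )
    screened = list(
        rc.screen_tcr_reads(rc.read_fastq(embedded), reference, config.min_score)
    )
    groups, dropped = rc.group_by_barcode(screened)
    annotations = []
    n_contigs = 0
    for barcode in sorted(groups):
        contigs = rc.assemble_cell(
            groups[barcode],
            min_overlap=config.min_overlap,
            max_mismatch=config.max_mismatch,
            min_contig_len=config.min_contig_len,
            cell_barcode=barcode,
        )
        n_contigs += len(contigs)
        for contig in contigs:
            ann = rc.annotate_contig(
                contig,
                reference,
                min_score=config.min_score,
                locus_margin=config.locus_margin,
                relaxed_filter=config.relaxed_filter,
            )
            annotations.append(
                {
                    "cell_id": ann.cell_barcode,
                    "sample_id": sample_id,
                    "contig_id": ann.contig_id,
                    "locus": ann.locus or "",
                    "v_call": ann.v_call or "",
                    "d_call": "",
                    "j_call": ann.j_call or "",
                    "junction": ann.cdr3_nt,
                    "junction_aa": ann.cdr3_aa,
                    "productive": "T" if ann.productive else "F",
                    "duplicate_count": contig.support,
                    "ambiguous_locus": ann.ambiguous_locus,
                    "fail_reasons": ";".join(ann.fail_reasons),
                }
            )
    df = pd.DataFrame(annotations, columns=ANNOTATION_COLUMNS)
    log_rows.append(
        {
            "stage": "reconstruct",
            "sample_id": sample_id,
            "input": embed_counts["input"],
            "embedded": embed_counts["embedded"],
            "embed_dropped": embed_counts["dropped"],
            "screened": len(screened),
            "cells": len(groups),
            "group_dropped": dropped,
            "contigs": n_contigs,
            "productive": int((df["productive"] == "T").sum()),
        }
    )
    return df


def run_end_to_end(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_rows: list[dict] = []
    artifacts: dict[str, Path] = {}
    stage = "reference"
    try:
        if config.reference_fasta:
            reference = load_reference(config.reference_fasta, k=config.k)
        else:
            reference = synthetic_reference(seed=config.sim.seed, k=config.k)
        ref_path = outdir / "reference.fasta"
        reference.to_fasta(ref_path)
        artifacts["reference"] = ref_path

        stage = "simulate"
        truth = None
        if config.simulate:
            sim_out = simulate_repertoire(config.sim, reference, outdir / "sim")
            truth = pd.read_csv(sim_out["truth"], sep="\t")
            samples = pd.read_csv(sim_out["samples"], sep="\t")
            fastq_dir = Path(sim_out["outdir"])
            artifacts["truth"] = Path(sim_out["truth"])
            artifacts["samples"] = Path(sim_out["samples"])
            log_rows.append({"stage": "simulate", **{k: v for k, v in sim_out.items() if k.startswith("n_")}})
        else:
            samples = pd.read_csv(outdir / "samples.tsv", sep="\t")
            fastq_dir = outdir

        stage = "reconstruct"
        per_sample = []
        workdir = outdir / "work"
        workdir.mkdir(exist_ok=True)
        for _, row in samples.iterrows():
            per_sample.append(
                reconstruct_sample(
                    row.to_dict(), reference, config, workdir, log_rows, fastq_dir
                )
            )
        annotations = pd.concat(per_sample, ignore_index=True)
        ann_path = outdir / "annotations.airr.tsv"
        annotations.to_csv(ann_path, sep="\t", index=False)
        artifacts["annotations"] = ann_path

        stage = "clonotype"
        table = ct.call_clonotypes(annotations, samples)
        table = ct.classify_sharing(table)
        ct.write_repertoire(
            table,
            outdir / "clonotypes.tsv",
            outdir / "clonotype_counts.tsv",
            outdir / "clonotype_samples.tsv",
        )
        artifacts["clonotypes"] = outdir / "clonotypes.tsv"
        artifacts["clonotype_counts"] = outdir / "clonotype_counts.tsv"
        artifacts["clonotype_samples"] = outdir / "clonotype_samples.tsv"
        log_rows.append(
            {
                "stage": "clonotype",
                "records": len(table.records),
                **ct.sharing_summary(table).to_dict(),
            }
        )

        stage = "metrics"
        metrics_df = mx.sample_metrics(table)
        metrics_path = outdir / "sample_metrics.tsv"
        metrics_df.to_csv(metrics_path, sep="\t", index=False)
        artifacts["sample_metrics"] = metrics_path

        stage = "benchmark"
        if truth is not None:
            results = run_benchmark(
                annotations[annotations["productive"] == "T"], truth, config.match_modes
            )
            report = benchmark_report(results)
            bench_path = outdir / "benchmark.tsv"
            report.to_csv(bench_path, sep="\t", index=False)
            artifacts["benchmark"] = bench_path

        stage = "manifest"
        config_path = outdir / "run_config.txt"
        config.to_file(config_path)
        artifacts["run_config"] = config_path
        log_path = outdir / "stages.jsonl"
        with log_path.open("w") as fh:
            for row in log_rows:
                fh.write(json.dumps(row) + "\n")
        artifacts["stage_log"] = log_path
        manifest = {
            "seed": config.seed,
            "artifacts": {
                name: {"path": str(path), "sha256": _sha256(path)}
                for name, path in sorted(artifacts.items())
            },
        }
        with (outdir / "manifest.json").open("w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest
    except StageError:
        raise
    except Exception as exc:  # annotate failures with stage context
        counts = log_rows[-1] if log_rows else {}
        raise StageError(stage, counts, exc) from exc
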