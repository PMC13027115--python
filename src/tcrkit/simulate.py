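"""Synthetic multi-sample single-cell V(D)J repertoire generator.

Emulates the study design the downstream analytics expect: several
patients split into MSI / MSS groups, each sampled in blood, adjacent
normal and tumor tissue before and after treatment, with skewed clone
sizes, biased V/J usage, junctional N-insertions and exonuclease
trimming, a cross-patient public clone pool, and substitution
sequencing error.  Every emitted read is traceable to a ground-truth
clonotype, so the whole reconstruction pipeline is testable offline.

Reads are emitted as synchronized paired FASTQ: mate 1 carries the cell
barcode + UMI, mate 2 the cDNA fragment.  A flag instead emits
single-end FASTQ with the barcode already embedded in the read ID.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import ReferenceSet, SegmentRecord, build_reference, translate_nt
from .reconstruct import filter_cdr3_validity

NT = np.array(list("ACGT"))

AIRR_COLUMNS = [
    "cell_id",
    "sample_id",
    "patient",
    "group",
    "tissue",
    "timepoint",
    "locus",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_aa",
    "productive",
    "duplicate_count",
]


# ---------------------------------------------------------------------------
# synthetic germline reference
# ---------------------------------------------------------------------------

_STOP_CODONS = {"TAA", "TAG", "TGA"}


def _random_codon(rng: np.random.Generator, exclude_stop: bool = True) -> str:
    while True:
        codon = "".join(rng.choice(NT, size=3))
        if not (exclude_stop and codon in _STOP_CODONS):
            return codon


def synthetic_reference(
    seed: int = 0,
    loci: tuple[str, ...] = ("TRA", "TRB", "TRG", "TRD"),
    n_v: int = 4,
    n_j: int = 3,
    n_d: int = 2,
    v_length: int = 150,
    j_length: int = 60,
    d_length: int = 16,
    k: int = 15,
) -> ReferenceSet:
    """Build an in-memory germline reference with valid anchors.

    V segments end in five in-frame codons starting at the 2nd-CYS
    anchor; TRB/TRD V segments encode C-A-S-S there so that junctions
    built from them carry the conserved CASS motif.  J segments place
    the anchor Phe/Trp at a fixed offset followed by the G-x-G of the
    canonical [FW]-G-x-G junction-closing motif.
    """
    rng = np.random.default_rng(seed)
    records: list[SegmentRecord] = []
    for locus in loci:
        for vi in range(1, n_v + 1):
            anchor = v_length - 15
            head = "".join(rng.choice(NT, size=anchor))
            if locus in ("TRB", "TRD"):
                # C A S S + one spare codon: the motif the beta/delta
                # chain filter requires at the junction start
                tail = "TGT" + "GCT" + "AGT" + "TCA" + _random_codon(rng)
            else:
                tail = "TGT" + "".join(_random_codon(rng) for _ in range(4))
            records.append(
                SegmentRecord(f"{locus}V{vi}*01", locus, "V", head + tail, anchor)
            )
        for ji in range(1, n_j + 1):
            anchor = 30
            head_codons = "".join(_random_codon(rng) for _ in range(anchor // 3))
            if locus in ("TRB", "TRD"):
                fw = "TTT"  # beta/delta J regions close on Phe
            else:
                fw = "TTT" if rng.random() < 0.7 else "TGG"  # Phe or Trp anchor
            motif = fw + "GGT" + _random_codon(rng) + "GGC"  # [FW] G x G
            tail_len = j_length - anchor - 12
            tail = "".join(
                _random_codon(rng) for _ in range(tail_len // 3)
            )
            records.append(
                SegmentRecord(
                    f"{locus}J{ji}*01", locus, "J", head_codons + motif + tail, anchor
                )
            )
        if locus in ("TRB", "TRD"):
            for di in range(1, n_d + 1):
                seq = "".join(rng.choice(NT, size=d_length))
                records.append(SegmentRecord(f"{locus}D{di}*01", locus, "D", seq, None))
    return build_reference(records, k=k)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Study-design and read-level parameters of the simulator.

    Defaults mirror a six-patient two-arm design (three MSI, three MSS)
    sampled in blood, normal and tumor tissue pre- and post-treatment.
    """

    seed: int = 0
    n_patients: int = 6
    groups: dict[str, str] = field(default_factory=dict)  # patient -> MSI/MSS
    tissues: tuple[str, ...] = ("blood", "normal", "tumor")
    timepoints: tuple[str, ...] = ("Pre", "Post")
    loci: tuple[str, ...] = ("TRA", "TRB", "TRG", "TRD")
    locus_weights: tuple[float, ...] = (0.35, 0.45, 0.1, 0.1)
    n_clonotypes_per_sample: int = 20
    clone_size_law: str = "geometric"  # geometric | power_law | constant
    clone_size_param: float = 0.6  # geometric p / zipf a / constant size
    usage_bias_strength: float = 1.5  # Dirichlet-like skew on V/J usage
    insertion_mean: float = 4.0  # Poisson mean of junctional N-insertions
    max_v_trim: int = 3
    max_j_trim: int = 3
    shared_clone_fraction: float = 0.1
    # explicit per-(locus, segment_type) usage weights, ordered by
    # segment_id; None -> skewed weights drawn once per run
    usage_weights: dict[tuple[str, str], tuple[float, ...]] | None = None
    reads_per_cell_chain: int = 6
    read_length: int = 90
    error_rate: float = 0.001
    barcode_length: int = 12
    umi_length: int = 8
    embed_in_read_id: bool = False  # emit single-end FASTQ, barcode in ID
    max_recombination_retries: int = 500

    def __post_init__(self):
        if not self.groups:
            self.groups = {
                f"P{i + 1}": ("MSI" if i < (self.n_patients + 1) // 2 else "MSS")
                for i in range(self.n_patients)
            }
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0,1]")
        if not 0.0 <= self.shared_clone_fraction <= 1.0:
            raise ValueError("shared_clone_fraction must be in [0,1]")
        if self.reads_per_cell_chain < 1:
            raise ValueError("reads_per_cell_chain must be >= 1")
        if len(self.locus_weights) != len(self.loci):
            raise ValueError("locus_weights must match loci")
        if self.clone_size_law not in ("geometric", "power_law", "constant"):
            raise ValueError(f"unknown clone_size_law {self.clone_size_law!r}")

    def patients(self) -> list[str]:
        return sorted(self.groups)


@dataclass
class GroundTruthClonotype:
    """One simulated rearrangement with full provenance."""

    clonotype_id: str
    locus: str
    v_id: str
    d_id: str | None
    j_id: str
    junction_nt: str  # V 2nd-CYS codon .. J anchor codon, inclusive
    junction_aa: str
    transcript: str  # full V..J sequence reads are drawn from
    public_pool: bool = False


# ---------------------------------------------------------------------------
# V(D)J recombination
# ---------------------------------------------------------------------------


def _usage_weights(rng: np.random.Generator, n: int, strength: float) -> np.ndarray:
    """Skewed segment-usage weights (normalised Dirichlet draw)."""
    w = rng.dirichlet(np.full(n, 1.0 / max(strength, 1e-6)))
    return w / w.sum()


class _SegmentSampler:
    """Per-locus biased V/(D)/J choice, fixed for one simulation run."""

    def __init__(self, reference: ReferenceSet, config: SimConfig, rng: np.random.Generator):
        self.reference = reference
        self.config = config
        self.weights: dict[tuple[str, str], np.ndarray] = {}
        self.segments: dict[tuple[str, str], list[SegmentRecord]] = {}
        for locus in config.loci:
            for seg_type in ("V", "D", "J"):
                segs = reference.by_type(seg_type, locus)
                if not segs:
                    continue
                self.segments[(locus, seg_type)] = segs
                explicit = (config.usage_weights or {}).get((locus, seg_type))
                if explicit is not None:
                    w = np.asarray(explicit, dtype=float)
                    if w.size != len(segs) or (w < 0).any() or w.sum() <= 0:
                        raise ValueError(
                            f"bad usage weights for {(locus, seg_type)}"
                        )
                    self.weights[(locus, seg_type)] = w / w.sum()
                else:
                    self.weights[(locus, seg_type)] = _usage_weights(
                        rng, len(segs), config.usage_bias_strength
                    )

    def pick(self, rng: np.random.Generator, locus: str, seg_type: str) -> SegmentRecord | None:
        key = (locus, seg_type)
        if key not in self.segments:
            return None
        idx = rng.choice(len(self.segments[key]), p=self.weights[key])
        return self.segments[key][idx]


def recombine_vdj(
    reference: ReferenceSet,
    locus: str,
    rng: np.random.Generator,
    config: SimConfig | None = None,
    sampler: _SegmentSampler | None = None,
    clonotype_id: str = "clone",
) -> GroundTruthClonotype:
    """Simulate one productive V(D)J rearrangement.

    Segment ends are trimmed, random N-nucleotides inserted, and the
    draw repeated until the junction (V anchor codon through J anchor
    codon) is in-frame, stop-free and passes the chain-specific CDR3
    motif filter — productive by construction.
    """
    config = config or SimConfig()
    if sampler is None:
        sampler = _SegmentSampler(reference, config, rng)
    if not reference.by_type("V", locus) or not reference.by_type("J", locus):
        raise ValueError(f"reference lacks V or J segments for locus {locus}")
    for _ in range(config.max_recombination_retries):
        v = sampler.pick(rng, locus, "V")
        j = sampler.pick(rng, locus, "J")
        d = sampler.pick(rng, locus, "D") if locus in ("TRB", "TRD") else None
        v_trim = int(rng.integers(0, config.max_v_trim + 1))
        j_trim = int(rng.integers(0, config.max_j_trim + 1))
        n1 = "".join(rng.choice(NT, size=rng.poisson(config.insertion_mean)))
        d_frag = ""
        n2 = ""
        if d is not None:
            d_start = int(rng.integers(0, max(1, len(d.sequence) // 2)))
            d_end = int(rng.integers(d_start + 1, len(d.sequence) + 1))
            d_frag = d.sequence[d_start:d_end]
            n2 = "".join(rng.choice(NT, size=rng.poisson(config.insertion_mean)))
        v_part = v.sequence[: len(v.sequence) - v_trim]
        j_part = j.sequence[j_trim:]
        j_anchor_in_part = j.anchor_offset - j_trim
        if j_anchor_in_part < 0:
            continue
        junction = (
            v_part[v.anchor_offset :]
            + n1
            + d_frag
            + n2
            + j_part[: j_anchor_in_part + 3]
        )
        if len(junction) % 3 != 0:
            continue
        junction_aa = translate_nt(junction)
        if "*" in junction_aa:
            continue
        valid, _ = filter_cdr3_validity(junction_aa, locus)
        if not valid:
            continue
        transcript = v_part + n1 + d_frag + n2 + j_part
        return GroundTruthClonotype(
            clonotype_id=clonotype_id,
            locus=locus,
            v_id=v.segment_id,
            d_id=d.segment_id if d is not None else None,
            j_id=j.segment_id,
            junction_nt=junction,
            junction_aa=junction_aa,
            transcript=transcript,
        )
    raise RuntimeError(
        f"no productive junction for locus {locus} after "
        f"{config.max_recombination_retries} retries (seed-dependent)"
    )


# ---------------------------------------------------------------------------
# full repertoire simulation
# ---------------------------------------------------------------------------


def _clone_sizes(rng: np.random.Generator, n: int, law: str, param: float) -> np.ndarray:
    if law == "geometric":
        return rng.geometric(param, size=n)
    if law == "power_law":
        return rng.zipf(max(param, 1.01), size=n)
    return np.full(n, max(int(param), 1))


def _random_barcode(rng: np.random.Generator, length: int, used: set[str]) -> str:
    while True:
        bc = "".join(rng.choice(NT, size=length))
        if bc not in used:
            used.add(bc)
            return bc


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < error_rate
    for i in np.nonzero(hit)[0]:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _tile_offsets(transcript_len: int, read_len: int, n_reads: int) -> np.ndarray:
    """Evenly spaced read start positions covering the transcript."""
    span = max(transcript_len - read_len, 0)
    if n_reads == 1:
        return np.array([span // 2])
    return np.round(np.linspace(0, span, n_reads)).astype(int)


def simulate_repertoire(
    config: SimConfig, reference: ReferenceSet, outdir: str | Path
) -> dict:
    """Generate per-sample FASTQ, a ground-truth table and a sample sheet.

    Returns a manifest dict with the emitted paths plus bookkeeping
    counts.  Identical config + seed gives byte-identical output files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sampler = _SegmentSampler(reference, config, rng)
    locus_p = np.asarray(config.locus_weights, dtype=float)
    locus_p = locus_p / locus_p.sum()

    # cross-patient public pool: identical V/J + junction reused across
    # patients (and groups) to create intra-/inter-group sharing
    n_pool = max(1, int(round(config.shared_clone_fraction * config.n_clonotypes_per_sample * 2)))
    pool: list[GroundTruthClonotype] = []
    if config.shared_clone_fraction > 0:
        for i in range(n_pool):
            locus = str(rng.choice(config.loci, p=locus_p))
            clone = recombine_vdj(
                reference, locus, rng, config, sampler, clonotype_id=f"public{i + 1}"
            )
            clone.public_pool = True
            pool.append(clone)

    truth_rows: list[dict] = []
    sheet_rows: list[dict] = []
    n_read_pairs = 0
    quality_line = None

    for patient in config.patients():
        group = config.groups[patient]
        for tissue in config.tissues:
            for timepoint in config.timepoints:
                sample_id = f"{patient}_{tissue}_{timepoint}"
                used_barcodes: set[str] = set()
                sizes = _clone_sizes(
                    rng,
                    config.n_clonotypes_per_sample,
                    config.clone_size_law,
                    config.clone_size_param,
                )
                clones: list[GroundTruthClonotype] = []
                for ci in range(config.n_clonotypes_per_sample):
                    if pool and rng.random() < config.shared_clone_fraction:
                        src = pool[int(rng.integers(0, len(pool)))]
                        clones.append(dataclasses.replace(src))
                    else:
                        locus = str(rng.choice(config.loci, p=locus_p))
                        clones.append(
                            recombine_vdj(
                                reference,
                                locus,
                                rng,
                                config,
                                sampler,
                                clonotype_id=f"{sample_id}_c{ci + 1}",
                            )
                        )
                if config.embed_in_read_id:
                    se_path = outdir / f"{sample_id}.fastq"
                    handles = [se_path.open("w")]
                else:
                    r1_path = outdir / f"{sample_id}_R1.fastq"
                    r2_path = outdir / f"{sample_id}_R2.fastq"
                    handles = [r1_path.open("w"), r2_path.open("w")]
                try:
                    for ci, (clone, size) in enumerate(zip(clones, sizes)):
                        barcodes = []
                        for _cell in range(int(size)):
                            bc = _random_barcode(rng, config.barcode_length, used_barcodes)
                            umi = "".join(rng.choice(NT, size=config.umi_length))
                            barcodes.append(bc)
                            offsets = _tile_offsets(
                                len(clone.transcript),
                                config.read_length,
                                config.reads_per_cell_chain,
                            )
                            for ri, off in enumerate(offsets):
                                frag = clone.transcript[off : off + config.read_length]
                                frag = _mutate(rng, frag, config.error_rate)
                                rid = f"{sample_id}.{bc}.r{ri + 1}"
                                qual = "I" * len(frag)
                                if config.embed_in_read_id:
                                    handles[0].write(
                                        f"@{bc}:{umi}:{rid}\n{frag}\n+\n{qual}\n"
                                    )
                                else:
                                    m1 = bc + umi
                                    handles[0].write(
                                        f"@{rid}\n{m1}\n+\n{'I' * len(m1)}\n"
                                    )
                                    handles[1].write(f"@{rid}\n{frag}\n+\n{qual}\n")
                                n_read_pairs += 1
                        truth_rows.extend(
                            {
                                "cell_id": bc,
                                "sample_id": sample_id,
                                "patient": patient,
                                "group": group,
                                "tissue": tissue,
                                "timepoint": timepoint,
                                "locus": clone.locus,
                                "v_call": clone.v_id,
                                "d_call": clone.d_id or "",
                                "j_call": clone.j_id,
                                "junction": clone.junction_nt,
                                "junction_aa": clone.junction_aa,
                                "productive": "T",
                                "duplicate_count": len(offsets),
                            }
                            for bc in barcodes
                        )
                finally:
                    for h in handles:
                        h.close()
                row = {
                    "sample_id": sample_id,
                    "patient": patient,
                    "group": group,
                    "tissue": tissue,
                    "timepoint": timepoint,
                }
                # file names relative to the sheet keep outputs
                # byte-identical regardless of the output directory
                if config.embed_in_read_id:
                    row["fastq"] = f"{sample_id}.fastq"
                else:
                    row["fastq_r1"] = f"{sample_id}_R1.fastq"
                    row["fastq_r2"] = f"{sample_id}_R2.fastq"
                sheet_rows.append(row)

    truth = pd.DataFrame(truth_rows, columns=AIRR_COLUMNS)
    truth_path = outdir / "truth.airr.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    sheet = pd.DataFrame(sheet_rows)
    sheet_path = outdir / "samples.tsv"
    sheet.to_csv(sheet_path, sep="\t", index=False)
    return {
        "truth": str(truth_path),
        "samples": str(sheet_path),
        "n_samples": len(sheet_rows),
        "n_cells": len(truth_rows),
        "n_read_pairs": n_read_pairs,
        "outdir": str(outdir),
    }
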