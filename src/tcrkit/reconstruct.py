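"""Per-cell TCR reconstruction: screen, demultiplex, assemble, annotate.

The pipeline mirrors the standard shape of receptor-reconstruction
tools: reads are screened for TCR origin against the germline k-mer
index plus a local alignment, the cell barcode and UMI are embedded
into read IDs (``<barcode>:<umi>:<original_id>``) so reads can be
clustered per cell, each cell's reads are assembled by greedy
overlap-consensus, and contigs are annotated with V/J calls and the
CDR3 junction projected from the germline anchor codons.

Chain-specific CDR3 validity rules: TRA/TRG junctions must start with
cysteine and end with phenylalanine or tryptophan; TRB/TRD junctions
must start with the conserved CASS motif and end with phenylalanine.
A relaxed mode applies the C...F rule to beta/delta chains instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .align import best_local_hit, make_aligner, revcomp
from .reference import ReferenceSet, translate_nt

log = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 25
DEFAULT_MIN_OVERLAP = 20
DEFAULT_MAX_MISMATCH = 2
DEFAULT_MIN_CONTIG_LEN = 60
DEFAULT_LOCUS_MARGIN = 5


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    barcode: str | None = None
    umi: str | None = None
    mate: str = "single"
    locus_hint: str | None = None


@dataclass
class Contig:
    cell_barcode: str
    contig_id: str
    sequence: str
    support: int


@dataclass
class ChainAnnotation:
    contig_id: str
    cell_barcode: str
    locus: str | None = None
    v_call: str | None = None
    j_call: str | None = None
    d_call: str | None = None
    v_score: float = 0.0
    j_score: float = 0.0
    cdr3_nt: str = ""
    cdr3_aa: str = ""
    productive: bool = False
    ambiguous_locus: bool = False
    fail_reasons: list[str] = field(default_factory=list)
    sequence: str = ""


# ---------------------------------------------------------------------------
# CDR3 validity filter
# ---------------------------------------------------------------------------


def filter_cdr3_validity(
    cdr3_aa: str, locus: str, relaxed: bool = False
) -> tuple[bool, str | None]:
    """Chain-specific CDR3 amino-acid validity rules.

    TRA/TRG: first residue C, last residue W or F.  TRB/TRD: first four
    residues CASS, last residue F (relaxed mode: C...F).  Any stop
    codon ('*') is invalid regardless of locus.
    """
    if not cdr3_aa:
        raise ValueError("empty CDR3 amino-acid string")
    if "*" in cdr3_aa:
        return False, "stop_codon"
    if locus in ("TRA", "TRG"):
        if cdr3_aa[0] != "C":
            return False, "start_not_cysteine"
        if cdr3_aa[-1] not in ("W", "F"):
            return False, "terminal_residue"
        return True, None
    if locus in ("TRB", "TRD"):
        if relaxed:
            if cdr3_aa[0] != "C":
                return False, "start_not_cysteine"
        elif not cdr3_aa.startswith("CASS"):
            return False, "missing_cass_motif"
        if cdr3_aa[-1] != "F":
            return False, "terminal_residue"
        return True, None
    raise ValueError(f"unknown locus {locus!r}")


# ---------------------------------------------------------------------------
# barcode embedding / demultiplexing
# ---------------------------------------------------------------------------


def embed_read_id(barcode: str, umi: str, original_id: str) -> str:
    return f"{barcode}:{umi}:{original_id}"


def parse_embedded_id(read_id: str) -> tuple[str, str, str]:
    """Invert :func:`embed_read_id`; original IDs may contain ':'."""
    parts = read_id.split(":", 2)
    if len(parts) != 3 or not parts[0] or not parts[1]:
        raise ValueError(f"read id {read_id!r} is not barcode-embedded")
    return parts[0], parts[1], parts[2]


def embed_barcodes(
    r1_path: str | Path,
    r2_path: str | Path | None,
    out_path: str | Path,
    barcode_length: int,
    umi_length: int,
    out_r1_path: str | Path | None = None,
) -> dict:
    """Embed barcode+UMI from mate 1 into read IDs.

    Paired layout: mate 1 carries barcode then UMI at its 5' end; both
    mates of a pair receive the identical ``<barcode>:<umi>:`` prefix.
    The cDNA mate (mate 2) is written to ``out_path``; the tag mate is
    re-emitted only when ``out_r1_path`` is given.  Single-end layout
    (``r2_path`` None): the read itself carries barcode+UMI+cDNA.
    Reads whose barcode region contains N (or is truncated) are dropped
    and counted.
    """
    n_in = n_out = n_dropped = 0
    tag_len = barcode_length + umi_length
    out_path = Path(out_path)
    out1 = Path(out_r1_path).open("w") if out_r1_path else None
    with out_path.open("w") as out:
        if r2_path is None:
            with open(r1_path) as fh:
                for rid, seq, qual in FastqGeneralIterator(fh):
                    n_in += 1
                    tag = seq[:tag_len]
                    if len(tag) < tag_len or "N" in tag[:barcode_length]:
                        n_dropped += 1
                        continue
                    barcode = tag[:barcode_length]
                    umi = tag[barcode_length:]
                    new_id = embed_read_id(barcode, umi, rid.split()[0])
                    out.write(f"@{new_id}\n{seq[tag_len:]}\n+\n{qual[tag_len:]}\n")
                    n_out += 1
        else:
            with open(r1_path) as fh1, open(r2_path) as fh2:
                it1 = FastqGeneralIterator(fh1)
                it2 = FastqGeneralIterator(fh2)
                for (rid1, seq1, qual1), (rid2, seq2, qual2) in zip(it1, it2):
                    n_in += 1
                    id1 = rid1.split()[0]
                    id2 = rid2.split()[0]
                    if id1 != id2:
                        raise ValueError(
                            f"desynchronized mates: {id1!r} vs {id2!r}"
                        )
                    if len(seq1) < tag_len or "N" in seq1[:barcode_length]:
                        n_dropped += 1
                        continue
                    barcode = seq1[:barcode_length]
                    umi = seq1[barcode_length:tag_len]
                    new_id = embed_read_id(barcode, umi, id1)
                    out.write(f"@{new_id}\n{seq2}\n+\n{qual2}\n")
                    if out1 is not None:
                        out1.write(f"@{new_id}\n{seq1}\n+\n{qual1}\n")
                    n_out += 1
                for leftover in (it1, it2):
                    for _ in leftover:
                        raise ValueError("desynchronized mates: unequal file lengths")
    if out1 is not None:
        out1.close()
    return {"input": n_in, "embedded": n_out, "dropped": n_dropped, "out": str(out_path)}


def read_fastq(path: str | Path, parse_ids: bool = True) -> Iterator[ReadRecord]:
    """Stream a FASTQ of barcode-embedded reads as ReadRecords."""
    with open(path) as fh:
        for rid, seq, _qual in FastqGeneralIterator(fh):
            rid = rid.split()[0]
            barcode = umi = None
            if parse_ids:
                barcode, umi, _ = parse_embedded_id(rid)
            yield ReadRecord(read_id=rid, sequence=seq.upper(), barcode=barcode, umi=umi)


def group_by_barcode(
    reads: Iterable[ReadRecord], on_error: str = "drop"
) -> tuple[dict[str, list[ReadRecord]], int]:
    """Partition embedded reads by cell barcode.

    Returns (groups, n_dropped).  Unparseable IDs are dropped and
    counted, or abort when ``on_error='abort'``.
    """
    groups: dict[str, list[ReadRecord]] = {}
    dropped = 0
    for read in reads:
        barcode = read.barcode
        if barcode is None:
            try:
                barcode, umi, _ = parse_embedded_id(read.read_id)
                read.barcode, read.umi = barcode, umi
            except ValueError:
                if on_error == "abort":
                    raise
                dropped += 1
                continue
        groups.setdefault(barcode, []).append(read)
    return groups, dropped


# ---------------------------------------------------------------------------
# read screen
# ---------------------------------------------------------------------------


def screen_tcr_reads(
    reads: Iterable[ReadRecord],
    reference: ReferenceSet,
    min_score: float = DEFAULT_MIN_SCORE,
) -> Iterator[ReadRecord]:
    """Keep reads whose best local alignment to a candidate germline
    segment (either strand) scores >= min_score; candidates come from
    the shared-k-mer index.  Retained reads carry a best-locus hint.
    """
    aligner = make_aligner()
    for read in reads:
        if len(read.sequence) < reference.k:
            continue
        candidates = reference.kmer_candidates(read.sequence)
        if not candidates:
            continue
        best_score = -1.0
        best_locus = None
        for seg_id in sorted(candidates):
            seg = reference.segments[seg_id]
            for strand_seq in (read.sequence, revcomp(read.sequence)):
                hit = best_local_hit(aligner, strand_seq, seg.sequence)
                if hit is not None and hit.score > best_score:
                    best_score = hit.score
                    best_locus = seg.locus
        if best_score >= min_score:
            read.locus_hint = best_locus
            yield read


# ---------------------------------------------------------------------------
# greedy overlap-consensus assembly
# ---------------------------------------------------------------------------


def _best_overlap(s1: str, s2: str, min_overlap: int, max_mismatch: int) -> int:
    """Longest suffix(s1)/prefix(s2) overlap with <= max_mismatch
    mismatches, or 0 if none reaches min_overlap."""
    limit = min(len(s1), len(s2))
    for ov in range(limit, min_overlap - 1, -1):
        mism = 0
        tail = s1[len(s1) - ov :]
        head = s2[:ov]
        ok = True
        for a, b in zip(tail, head):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    ok = False
                    break
        if ok:
            return ov
    return 0


def _merge(
    s1: str, sup1: int, s2: str, sup2: int, ov: int
) -> tuple[str, int]:
    """Merge s1 into s2 over an overlap of ov bases, consensus by the
    higher-support sequence at mismatching positions."""
    tail = s1[len(s1) - ov :]
    head = s2[:ov]
    if sup2 > sup1:
        consensus = head
    else:
        consensus = tail  # ties go to the first (lexicographically earlier) seq
    return s1[: len(s1) - ov] + consensus + s2[ov:], sup1 + sup2


def assemble_cell(
    reads: Iterable[ReadRecord | str],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_contig_len: int = DEFAULT_MIN_CONTIG_LEN,
    cell_barcode: str = "",
    dedup: bool = True,
) -> list[Contig]:
    """Greedy overlap-consensus assembly of one cell's reads.

    Exact duplicates are collapsed first (support = copy number); the
    pair with the longest suffix-prefix overlap (both orientations of
    the incoming sequence considered) is merged repeatedly until no
    overlap >= min_overlap remains.  Reads are processed in lexicographic
    sequence order, making the result independent of input order.
    """
    seqs: list[str] = []
    for r in reads:
        seqs.append(r.sequence if isinstance(r, ReadRecord) else str(r))
    if dedup:
        counts: dict[str, int] = {}
        for s in seqs:
            counts[s] = counts.get(s, 0) + 1
        items = sorted(counts.items())
    else:
        items = sorted((s, 1) for s in seqs)
    pool: list[tuple[str, int]] = [(s, c) for s, c in items]

    while len(pool) > 1:
        best = None  # (ov, i, j, oriented_s2)
        for i, (s1, _c1) in enumerate(pool):
            for j, (s2, _c2) in enumerate(pool):
                if i == j:
                    continue
                for s2o in (s2, revcomp(s2)):
                    if s2o != s1 and s2o in s1:
                        ov = len(s2o)  # containment: absorb outright
                    else:
                        ov = _best_overlap(s1, s2o, min_overlap, max_mismatch)
                    if ov >= min_overlap or (ov == len(s2o) and ov > 0):
                        cand = (ov, s1, s2o, i, j)
                        if best is None or (cand[0], cand[1], cand[2]) > (
                            best[0],
                            best[1],
                            best[2],
                        ):
                            best = cand
        if best is None:
            break
        ov, s1, s2o, i, j = best
        c1 = pool[i][1]
        c2 = pool[j][1]
        if s2o in s1:
            merged, support = s1, c1 + c2
        else:
            merged, support = _merge(s1, c1, s2o, c2, ov)
        keep = [pool[x] for x in range(len(pool)) if x not in (i, j)]
        keep.append((merged, support))
        pool = sorted(keep)

    contigs = []
    n = 0
    for seq, support in sorted(pool, key=lambda t: (-len(t[0]), t[0])):
        if len(seq) >= min_contig_len:
            n += 1
            contigs.append(
                Contig(
                    cell_barcode=cell_barcode,
                    contig_id=f"{cell_barcode}_{n}" if cell_barcode else f"contig_{n}",
                    sequence=seq,
                    support=support,
                )
            )
    return contigs


def assemble_exhaustive(
    reads: list[str], min_overlap: int, max_mismatch: int = 0
) -> set[str]:
    """Exhaustive merge-order search oracle for tiny read sets (<= 8).

    Explores every merge order and returns the set of maximal contigs
    reachable; used to check the greedy assembler on instances with
    unique exact overlaps.
    """

    def key(pool: tuple[str, ...]) -> tuple[str, ...]:
        return tuple(sorted(pool))

    seen: set[tuple[str, ...]] = set()
    results: set[str] = set()

    def recurse(pool: tuple[str, ...]) -> None:
        k = key(pool)
        if k in seen:
            return
        seen.add(k)
        merged_any = False
        for i in range(len(pool)):
            for j in range(len(pool)):
                if i == j:
                    continue
                for s2o in (pool[j], revcomp(pool[j])):
                    ov = _best_overlap(pool[i], s2o, min_overlap, max_mismatch)
                    if ov >= min_overlap:
                        merged = pool[i] + s2o[ov:]
                        rest = tuple(
                            pool[x] for x in range(len(pool)) if x not in (i, j)
                        )
                        recurse(rest + (merged,))
                        merged_any = True
        if not merged_any:
            results.add(max(pool, key=lambda s: (len(s), s)))

    recurse(tuple(sorted(set(reads))))
    return results


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def _rank_hits(hits: list[tuple[float, float, str]]) -> list[tuple[float, float, str]]:
    """Sort (score, identity, segment_id) hits: score desc, identity
    desc, then lexicographic id — the deterministic tie-break."""
    return sorted(hits, key=lambda h: (-h[0], -h[1], h[2]))


def annotate_contig(
    contig: Contig,
    reference: ReferenceSet,
    min_score: float = DEFAULT_MIN_SCORE,
    locus_margin: float = DEFAULT_LOCUS_MARGIN,
    relaxed_filter: bool = False,
) -> ChainAnnotation:
    """Assign V/J calls and extract the CDR3 from a contig.

    The contig is oriented to the V-forward strand.  When the top V
    hits from different loci score within ``locus_margin`` of each
    other the locus is taken from the J call instead and the record is
    flagged ambiguous (germline V segments of the alpha and delta loci
    in particular cross-align).  CDR3 boundaries are projected from the
    germline anchor codons through the alignments: contig bases from
    the 2nd-CYS codon through the J-anchor codon inclusive.
    """
    aligner = make_aligner()
    ann = ChainAnnotation(contig_id=contig.contig_id, cell_barcode=contig.cell_barcode)

    best_by_strand = {}
    for strand, seq in (("+", contig.sequence), ("-", revcomp(contig.sequence))):
        hits = []
        for seg in reference.by_type("V"):
            hit = best_local_hit(aligner, seq, seg.sequence)
            if hit is not None and hit.score >= min_score:
                hits.append((hit.score, hit.identity, seg.segment_id, hit))
        if hits:
            best_by_strand[strand] = _rank_hits(
                [(s, i, sid) for s, i, sid, _ in hits]
            ), {sid: h for s, i, sid, h in hits}

    if not best_by_strand:
        ann.fail_reasons.append("no_v")
        ann.sequence = contig.sequence
        return ann

    strand = max(
        best_by_strand, key=lambda st: (best_by_strand[st][0][0][0], st == "+")
    )
    oriented = contig.sequence if strand == "+" else revcomp(contig.sequence)
    v_hits, v_map = best_by_strand[strand]
    ann.sequence = oriented

    v_score, _v_ident, v_id = v_hits[0]
    ann.v_call = v_id
    ann.v_score = v_score
    v_locus = reference.segments[v_id].locus

    # locus ambiguity: compare best V score per locus
    best_per_locus: dict[str, float] = {}
    for s, _i, sid in v_hits:
        locus = reference.segments[sid].locus
        best_per_locus.setdefault(locus, s)
    ambiguous = False
    if len(best_per_locus) > 1:
        ranked = sorted(best_per_locus.values(), reverse=True)
        if ranked[0] - ranked[1] < locus_margin:
            ambiguous = True

    j_hits = []
    j_map = {}
    for seg in reference.by_type("J"):
        hit = best_local_hit(aligner, oriented, seg.sequence)
        if hit is not None and hit.score >= min_score:
            j_hits.append((hit.score, hit.identity, seg.segment_id))
            j_map[seg.segment_id] = hit
    if not j_hits:
        ann.locus = v_locus
        ann.fail_reasons.append("no_j")
        return ann
    j_hits = _rank_hits(j_hits)
    j_score, _j_ident, j_id = j_hits[0]
    ann.j_call = j_id
    ann.j_score = j_score
    j_locus = reference.segments[j_id].locus

    ann.ambiguous_locus = ambiguous
    ann.locus = j_locus if ambiguous else v_locus

    v_seg = reference.segments[v_id]
    j_seg = reference.segments[j_id]
    v_pos = v_map[v_id].project(v_seg.anchor_offset)
    j_pos = j_map[j_id].project(j_seg.anchor_offset)
    if v_pos < 0 or j_pos + 3 > len(oriented) or j_pos < v_pos:
        ann.fail_reasons.append("cdr3_bounds")
        return ann
    ann.cdr3_nt = oriented[v_pos : j_pos + 3]
    if len(ann.cdr3_nt) % 3 != 0:
        ann.fail_reasons.append("out_of_frame")
        return ann
    ann.cdr3_aa = translate_nt(ann.cdr3_nt)
    valid, reason = filter_cdr3_validity(ann.cdr3_aa, ann.locus, relaxed=relaxed_filter)
    if not valid:
        ann.fail_reasons.append(reason)
        return ann
    ann.productive = True
    return ann
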