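"""Germline V/D/J segment reference: loading, validation, k-mer indexing.

A reference is a FASTA of germline segments whose headers carry the
locus (TRA/TRB/TRG/TRD), the segment type (V/D/J) and, for V and J
segments, the 0-based offset of the conserved anchor codon: the second
cysteine (2nd-CYS) of the V region, or the J-region phenylalanine /
tryptophan that closes the CDR3 junction.  Two header dialects are
accepted:

* key-value  — ``>TRBV27*01 type=V locus=TRB anchor=285``
* pipe       — ``>TRBV27*01|TRB|V|285`` (anchor field optional)

Records failing anchor validation (V anchor not a Cys codon, J anchor
not Phe/Trp) are excluded and reported rather than silently kept.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

from .align import revcomp

log = logging.getLogger(__name__)

LOCI = ("TRA", "TRB", "TRG", "TRD")
SEGMENT_TYPES = ("V", "D", "J")
DEFAULT_K = 15

_VALID_NT = frozenset("ACGT")


class ReferenceError(ValueError):
    """Raised for unloadable or structurally invalid references."""


def translate_nt(seq: str) -> str:
    """Standard-code translation of an in-frame nucleotide string."""
    trimmed = seq[: len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate())


@dataclass(frozen=True)
class SegmentRecord:
    """One germline segment (e.g. ``TRBV27*01``).

    ``anchor_offset`` is the 0-based position of the first base of the
    conserved anchor codon: 2nd-CYS for V, J-PHE/TRP for J; None for D.
    """

    segment_id: str
    locus: str
    segment_type: str
    sequence: str
    anchor_offset: int | None = None

    @property
    def gene(self) -> str:
        return self.segment_id.split("*")[0]

    @property
    def allele(self) -> str:
        parts = self.segment_id.split("*")
        return parts[1] if len(parts) > 1 else ""

    def anchor_codon(self) -> str | None:
        if self.anchor_offset is None:
            return None
        return self.sequence[self.anchor_offset : self.anchor_offset + 3]

    def validate(self) -> str | None:
        """Return a failure reason, or None if the record is sound."""
        if not self.sequence:
            return "empty_sequence"
        if not set(self.sequence) <= _VALID_NT:
            return "invalid_alphabet"
        if self.locus not in LOCI:
            return "unknown_locus"
        if self.segment_type not in SEGMENT_TYPES:
            return "unknown_segment_type"
        if self.segment_type == "D":
            return None
        if self.anchor_offset is None:
            return "missing_anchor"
        if not 0 <= self.anchor_offset <= len(self.sequence) - 3:
            return "anchor_out_of_range"
        aa = translate_nt(self.anchor_codon())
        if self.segment_type == "V" and aa != "C":
            return "anchor_not_cysteine"
        if self.segment_type == "J" and aa not in ("F", "W"):
            return "anchor_not_phe_trp"
        return None


def infer_j_anchor(sequence: str) -> int | None:
    """Locate the J anchor as the first [FW]-G-x-G motif.

    All three frames are scanned; the frame whose translation has the
    longest stop-free prefix run wins, which makes the inference
    deterministic for any sequence.
    """
    best_frame = None
    best_run = -1
    translations = {}
    for frame in range(3):
        aa = translate_nt(sequence[frame:])
        translations[frame] = aa
        run = len(aa.split("*")[0])
        if run > best_run:
            best_run = run
            best_frame = frame
    order = [best_frame] + [f for f in range(3) if f != best_frame]
    for frame in order:
        aa = translations[frame]
        for i in range(len(aa) - 3):
            if aa[i] in "FW" and aa[i + 1] == "G" and aa[i + 3] == "G":
                return frame + 3 * i
    return None


def _parse_header(header: str, dialect: str) -> tuple[str, str, str, int | None]:
    """Parse a FASTA header into (segment_id, locus, type, anchor)."""
    header = header.strip()
    if dialect == "auto":
        dialect = "pipe" if "|" in header.split()[0] else "keyvalue"
    if dialect == "pipe":
        fields = header.split("|")
        if len(fields) < 3:
            raise ReferenceError(f"unparseable pipe header: {header!r}")
        segment_id = fields[0].strip()
        locus = fields[1].strip().upper()
        seg_type = fields[2].strip().upper()
        anchor = int(fields[3]) if len(fields) > 3 and fields[3].strip() else None
        return segment_id, locus, seg_type, anchor
    if dialect == "keyvalue":
        parts = header.split()
        segment_id = parts[0]
        kv = {}
        for token in parts[1:]:
            if "=" not in token:
                raise ReferenceError(f"unparseable token {token!r} in {header!r}")
            key, value = token.split("=", 1)
            kv[key] = value
        if "type" not in kv or "locus" not in kv:
            raise ReferenceError(f"header missing type/locus: {header!r}")
        anchor = int(kv["anchor"]) if "anchor" in kv else None
        return segment_id, kv["locus"].upper(), kv["type"].upper(), anchor
    raise ReferenceError(f"unknown header dialect {dialect!r}")


@dataclass
class ReferenceSet:
    """Validated germline segments plus a forward-strand k-mer index."""

    segments: dict[str, SegmentRecord] = field(default_factory=dict)
    k: int = DEFAULT_K
    kmer_index: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.segments and not self.kmer_index:
            self.build_index()

    def build_index(self, k: int | None = None) -> None:
        if k is not None:
            self.k = k
        index: dict[str, set[str]] = defaultdict(set)
        for seg in self.segments.values():
            seq = seg.sequence
            for i in range(len(seq) - self.k + 1):
                index[seq[i : i + self.k]].add(seg.segment_id)
        self.kmer_index = {w: frozenset(ids) for w, ids in index.items()}

    # -- queries -----------------------------------------------------

    def by_type(self, segment_type: str, locus: str | None = None) -> list[SegmentRecord]:
        out = [
            s
            for s in self.segments.values()
            if s.segment_type == segment_type and (locus is None or s.locus == locus)
        ]
        return sorted(out, key=lambda s: s.segment_id)

    def loci(self) -> list[str]:
        return sorted({s.locus for s in self.segments.values()})

    def kmer_candidates(self, read_sequence: str, k: int | None = None) -> set[str]:
        """Segments sharing >=1 exact k-mer with the read or its revcomp.

        k-mers containing N (or any non-ACGT base) are skipped.  This is
        a superset guarantee relative to exact alignment: any read with
        >= k consecutive matches to a segment on either strand is hit.
        """
        k = self.k if k is None else k
        if k < 8:
            raise ValueError("k must be >= 8")
        if len(read_sequence) < k:
            raise ValueError(f"read length {len(read_sequence)} < k={k}")
        if k != self.k:
            raise ValueError(f"index built at k={self.k}, queried at k={k}")
        read_sequence = read_sequence.upper()
        hits: set[str] = set()
        for strand_seq in (read_sequence, revcomp(read_sequence)):
            for i in range(len(strand_seq) - k + 1):
                word = strand_seq[i : i + k]
                if not set(word) <= _VALID_NT:
                    continue
                found = self.kmer_index.get(word)
                if found:
                    hits |= found
        return hits

    # -- validation --------------------------------------------------

    def validate_structure(self) -> None:
        """Every locus present must carry at least one V and one J."""
        by_locus: dict[str, set[str]] = defaultdict(set)
        for seg in self.segments.values():
            by_locus[seg.locus].add(seg.segment_type)
        for locus, types in sorted(by_locus.items()):
            if "V" not in types:
                raise ReferenceError(f"locus {locus} has no valid V segment")
            if "J" not in types:
                raise ReferenceError(f"locus {locus} has no valid J segment")

    # -- serialisation -----------------------------------------------

    def to_fasta(self, path: str | Path) -> None:
        """Write the reference back out in the key-value header dialect."""
        path = Path(path)
        with path.open("w") as fh:
            for seg_id in sorted(self.segments):
                seg = self.segments[seg_id]
                anchor = (
                    f" anchor={seg.anchor_offset}" if seg.anchor_offset is not None else ""
                )
                fh.write(
                    f">{seg.segment_id} type={seg.segment_type} "
                    f"locus={seg.locus}{anchor}\n{seg.sequence}\n"
                )

    def write_exclusion_report(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for seg_id, reason in self.excluded:
                fh.write(f"{seg_id}\t{reason}\n")


def build_reference(records: list[SegmentRecord], k: int = DEFAULT_K) -> ReferenceSet:
    """Validate a list of segments into a ReferenceSet.

    Segments failing per-record validation are excluded (and recorded);
    a J segment without an anchor gets one inferred from the [FW]-G-x-G
    junction-closing motif before validation.
    """
    kept: dict[str, SegmentRecord] = {}
    excluded: list[tuple[str, str]] = []
    for rec in records:
        if rec.segment_id in kept:
            raise ReferenceError(f"duplicate segment id {rec.segment_id}")
        if rec.segment_type == "J" and rec.anchor_offset is None:
            inferred = infer_j_anchor(rec.sequence)
            if inferred is not None:
                rec = SegmentRecord(
                    rec.segment_id, rec.locus, rec.segment_type, rec.sequence, inferred
                )
        reason = rec.validate()
        if reason is not None:
            excluded.append((rec.segment_id, reason))
            log.warning("excluding segment %s: %s", rec.segment_id, reason)
            continue
        kept[rec.segment_id] = rec
    ref = ReferenceSet(segments=kept, k=k, excluded=excluded)
    ref.validate_structure()
    return ref


def load_reference(
    fasta_path: str | Path, header_dialect: str = "auto", k: int = DEFAULT_K
) -> ReferenceSet:
    """Load and validate a germline segment reference from FASTA."""
    fasta_path = Path(fasta_path)
    raw = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        segment_id, locus, seg_type, anchor = _parse_header(rec.description, header_dialect)
        raw.append(
            SegmentRecord(
                segment_id=segment_id,
                locus=locus,
                segment_type=seg_type,
                sequence=str(rec.seq).upper(),
                anchor_offset=anchor,
            )
        )
    if not raw:
        raise ReferenceError(f"no FASTA records in {fasta_path}")
    return build_reference(raw, k=k)
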