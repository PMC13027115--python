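"""Local alignment helpers shared by the read screen and the annotator.

Scoring is fixed at match +1 / mismatch -1 / gap -2, the classic
unit-cost Smith-Waterman parameterisation used for short-read screens.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_SCORE = -2


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_SCORE
    aligner.extend_gap_score = GAP_SCORE
    return aligner


@dataclass
class LocalHit:
    """Best local alignment of a query segment against a target sequence."""

    score: float
    identity: float
    strand: str  # strand of the *target* the query matched ('+' or '-')
    # aligned blocks as (target_start, target_end, query_start, query_end)
    blocks: tuple[tuple[int, int, int, int], ...]

    def project(self, query_pos: int) -> int:
        """Map a query coordinate onto the target through the alignment.

        Positions outside the aligned region are extrapolated colinearly
        from the nearest aligned block, which is exact whenever the
        unaligned flank is gap-free.
        """
        if not self.blocks:
            raise ValueError("empty alignment")
        for tstart, tend, qstart, qend in self.blocks:
            if qstart <= query_pos < qend:
                return tstart + (query_pos - qstart)
        first = self.blocks[0]
        last = self.blocks[-1]
        if query_pos < first[2]:
            return first[0] - (first[2] - query_pos)
        return last[1] + (query_pos - last[3])


def best_local_hit(
    aligner: Align.PairwiseAligner, target: str, query: str
) -> LocalHit | None:
    """Best local alignment of ``query`` within ``target`` (forward strand).

    Returns None when no positive-scoring alignment exists.
    """
    try:
        alignments = aligner.align(target, query)
        if len(alignments) == 0:
            return None
        aln = alignments[0]
    except (OverflowError, ValueError):
        return None
    if aln.score <= 0:
        return None
    tblocks, qblocks = aln.aligned
    blocks = tuple(
        (int(tb[0]), int(tb[1]), int(qb[0]), int(qb[1]))
        for tb, qb in zip(tblocks, qblocks)
    )
    matches = 0
    total = 0
    for tstart, tend, qstart, qend in blocks:
        for t, q in zip(target[tstart:tend], query[qstart:qend]):
            total += 1
            if t == q:
                matches += 1
    identity = matches / total if total else 0.0
    return LocalHit(score=float(aln.score), identity=identity, strand="+", blocks=blocks)
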