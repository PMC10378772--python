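"""Affine-gap pairwise alignment helpers shared by the scanning and subfamily stages.

Wraps :class:`Bio.Align.PairwiseAligner` (exact affine Smith-Waterman /
Needleman-Wunsch in C).  Scoring convention: a gap of length L costs
``-(gap_open) - (L - 1) * -(gap_extend)`` -- i.e. ``gap_open`` is the score of
the first gapped position and ``gap_extend`` of each further position.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align


@dataclass(frozen=True)
class AlnStats:
    """One pairwise alignment of a consensus (query) against a genomic segment."""

    score: float
    target_start: int
    target_end: int
    query_start: int
    query_end: int
    identities: int
    mismatches: int
    gap_events: int
    gap_bases: int

    @property
    def pct_div(self) -> float:
        """Mismatches + indel events per aligned query (consensus) position, x100."""
        span = self.query_end - self.query_start
        if span <= 0:
            return 0.0
        return 100.0 * (self.mismatches + self.gap_events) / span


def make_aligner(match: int, mismatch: int, gap_open: int, gap_extend: int,
                 mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_stats(aligner: Align.PairwiseAligner, target: str, query: str) -> AlnStats | None:
    """Best alignment of ``query`` against ``target``; None if nothing aligns."""
    alignments = aligner.align(target, query)
    try:
        aln = alignments[0]
    except IndexError:  # pragma: no cover - empty input
        return None
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return None
    counts = aln.counts()
    gap_events = 0
    gap_bases = 0
    for i in range(1, len(t_blocks)):
        t_jump = t_blocks[i][0] - t_blocks[i - 1][1]
        q_jump = q_blocks[i][0] - q_blocks[i - 1][1]
        if t_jump > 0:
            gap_events += 1
            gap_bases += t_jump
        if q_jump > 0:
            gap_events += 1
            gap_bases += q_jump
    return AlnStats(
        score=float(aln.score),
        target_start=int(t_blocks[0][0]),
        target_end=int(t_blocks[-1][1]),
        query_start=int(q_blocks[0][0]),
        query_end=int(q_blocks[-1][1]),
        identities=int(counts.identities),
        mismatches=int(counts.mismatches),
        gap_events=gap_events,
        gap_bases=gap_bases,
    )
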