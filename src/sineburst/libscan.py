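"""Consensus-library genome scanning with a full-length filter.

A seed-and-extend stand-in for the RepeatMasker stage: candidate windows are
located by exact k-mer seeding of each subfamily consensus against the genome
(both strands), then scored with an exact affine Smith-Waterman alignment.
Overlapping hits from different subfamilies are resolved best-hit-wins.
Percent divergence counts mismatches plus indel events per aligned consensus
position (the 3' A-tail lies outside the consensus and is excluded by
construction).
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field

from ._align import align_stats, make_aligner
from ._seq import revcomp


@dataclass
class ScanParams:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -1
    min_score: int = 60
    max_start: int = 4          # consensus-start tolerance for the full-length filter
    min_end: int = 103          # consensus-end requirement (0-based half-open)
    end_tolerance: int = 2      # slack from the consensus 3' end for short consensuses
    min_end_overrides: dict[str, int] = field(default_factory=dict)
    tail_trim: bool = True
    k: int = 12
    window_pad: int = 60
    overlap_frac: float = 0.5
    diag_slack: int = 15

    def validate(self) -> None:
        if not self.match > 0 > self.mismatch:
            raise ValueError("require match > 0 > mismatch")
        if not self.gap_open <= self.gap_extend < 0:
            raise ValueError("require gap_open <= gap_extend < 0")
        if not 0 <= self.max_start < self.min_end:
            raise ValueError("require 0 <= max_start < min_end")


@dataclass(frozen=True)
class Annotation:
    """One library hit on a genome (0-based half-open forward-strand coords)."""

    genome_id: str
    contig: str
    start: int
    end: int
    strand: str
    subfamily: str
    consensus_start: int
    consensus_end: int
    sw_score: float
    pct_div: float


def _check_alphabet(contig: str, seq: str) -> None:
    allowed = set("ACGTN")
    for i, ch in enumerate(seq):
        if ch not in allowed:
            raise ValueError(f"non-ACGTN character {ch!r} in contig {contig} at position {i}")


def _seed_windows(contig_index: dict[str, list[int]], query: str, k: int,
                  diag_slack: int, pad: int, contig_len: int) -> list[tuple[int, int]]:
    """Diagonal-clustered k-mer seed hits -> merged candidate windows."""
    hits: list[tuple[int, int]] = []  # (diag, tpos - qpos pairs)
    for q in range(0, len(query) - k + 1):
        kmer = query[q:q + k]
        for t in contig_index.get(kmer, ()):
            hits.append((t - q, t, q))
    if not hits:
        return []
    hits.sort()
    qlen = len(query)
    clusters: list[list[tuple[int, int, int]]] = []
    for h in hits:
        placed = False
        if clusters:
            last = clusters[-1][-1]
            if abs(h[0] - last[0]) <= diag_slack and abs(h[1] - last[1]) <= qlen + pad:
                clusters[-1].append(h)
                placed = True
        if not placed:
            clusters.append([h])
    windows = []
    for cl in clusters:
        lo = min(t - q for _, t, q in cl) - pad
        hi = max(t + (qlen - q) for _, t, q in cl) + pad
        windows.append((max(0, lo), min(contig_len, hi)))
    windows.sort()
    merged = [list(windows[0])]
    for lo, hi in windows[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def _index_contig(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = collections.defaultdict(list)
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" not in kmer:
            index[kmer].append(i)
    return index


def _align_window(aligner, genome_id, contig, window_seq, window_start, query,
                  qlen, strand, name, min_score, out: list[Annotation]) -> None:
    """Best local hit in a window, then recurse left/right of it."""
    if len(window_seq) < 20:
        return
    stats = align_stats(aligner, window_seq, query)
    if stats is None or stats.score < min_score:
        return
    if strand == "+":
        cons_start, cons_end = stats.query_start, stats.query_end
    else:  # query was the reverse complement of the consensus
        cons_start, cons_end = qlen - stats.query_end, qlen - stats.query_start
    out.append(Annotation(
        genome_id=genome_id, contig=contig,
        start=window_start + stats.target_start,
        end=window_start + stats.target_end,
        strand=strand, subfamily=name,
        consensus_start=cons_start, consensus_end=cons_end,
        sw_score=stats.score, pct_div=round(stats.pct_div, 4),
    ))
    _align_window(aligner, genome_id, contig, window_seq[:stats.target_start],
                  window_start, query, qlen, strand, name, min_score, out)
    _align_window(aligner, genome_id, contig, window_seq[stats.target_end:],
                  window_start + stats.target_end, query, qlen, strand, name,
                  min_score, out)


def scan_genome(genome: dict[str, str], library: dict[str, str],
                params: ScanParams | None = None,
                genome_id: str = "genome") -> list[Annotation]:
    """Scan all contigs against all library consensuses, both strands.

    Returns overlap-resolved annotations sorted by (contig, start).
    """
    params = params or ScanParams()
    params.validate()
    if not genome or not library:
        raise ValueError("genome and library must be non-empty")
    sequences = getattr(library, "sequences", library)
    aligner = make_aligner(params.match, params.mismatch, params.gap_open,
                           params.gap_extend, mode="local")
    raw: list[Annotation] = []
    for contig, seq in genome.items():
        _check_alphabet(contig, seq)
        index = _index_contig(seq, params.k)
        for name, consensus in sequences.items():
            for strand in "+-":
                query = consensus if strand == "+" else revcomp(consensus)
                windows = _seed_windows(index, query, params.k, params.diag_slack,
                                        params.window_pad, len(seq))
                for lo, hi in windows:
                    _align_window(aligner, genome_id, contig, seq[lo:hi], lo,
                                  query, len(consensus), strand, name,
                                  params.min_score, raw)
    return _resolve_overlaps(raw, params)


def _resolve_overlaps(hits: list[Annotation], params: ScanParams) -> list[Annotation]:
    """Best-hit-wins on >overlap_frac overlap (of the shorter hit)."""
    ordered = sorted(hits, key=lambda a: (-a.sw_score, a.subfamily, a.contig, a.start))
    accepted: list[Annotation] = []
    by_contig: dict[str, list[Annotation]] = collections.defaultdict(list)
    for h in ordered:
        keep = True
        for other in by_contig[h.contig]:
            ov = min(h.end, other.end) - max(h.start, other.start)
            shorter = min(h.end - h.start, other.end - other.start)
            if ov > params.overlap_frac * shorter:
                keep = False
                break
        if keep:
            accepted.append(h)
            by_contig[h.contig].append(h)
    return sorted(accepted, key=lambda a: (a.contig, a.start, a.subfamily))


def is_full_length(a: Annotation, params: ScanParams,
                   consensus_length: int | None = None) -> bool:
    """Full-length filter: starts within ``max_start`` of the consensus 5' end
    and reaches ``min_end`` (or, for consensuses shorter than
    ``min_end + end_tolerance``, to within ``end_tolerance`` of their 3' end).
    Explicit per-subfamily overrides win over both."""
    min_end = params.min_end_overrides.get(a.subfamily)
    if min_end is None:
        min_end = params.min_end
        if consensus_length is not None:
            min_end = min(min_end, consensus_length - params.end_tolerance)
    return a.consensus_start <= params.max_start and a.consensus_end >= min_end


# ---------------------------------------------------------------------------
# RepeatMasker-.out-style interchange (TSV, 1-based inclusive on disk)

_OUT_COLUMNS = ["sw_score", "pct_div", "genome_id", "contig", "begin", "end",
                "strand", "subfamily", "cons_begin", "cons_end"]


def write_scan_out(annotations: list[Annotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_OUT_COLUMNS) + "\n")
        for a in annotations:
            fh.write("\t".join([
                repr(a.sw_score), repr(a.pct_div), a.genome_id, a.contig,
                str(a.start + 1), str(a.end), a.strand, a.subfamily,
                str(a.consensus_start + 1), str(a.consensus_end),
            ]) + "\n")


def read_scan_out(path) -> list[Annotation]:
    out: list[Annotation] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _OUT_COLUMNS:
            raise ValueError(f"{path}: unrecognized header line")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_OUT_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected "
                                 f"{len(_OUT_COLUMNS)} fields, got {len(fields)}")
            try:
                out.append(Annotation(
                    genome_id=fields[2], contig=fields[3],
                    start=int(fields[4]) - 1, end=int(fields[5]),
                    strand=fields[6], subfamily=fields[7],
                    consensus_start=int(fields[8]) - 1, consensus_end=int(fields[9]),
                    sw_score=float(fields[0]), pct_div=float(fields[1]),
                ))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from exc
    return out
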