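"""Presence/absence calling at orthologous sites and lineage-specificity classes.

For every full-length element, a *locus* query is assembled -- up to 500 bp of
5' flank, the element body, and up to 500 bp of 3' flank (which begins with
the poly-A tail and the 3' target-site duplication).  The query is located in
each comparison genome by k-mer seeding plus diagonal chaining, then aligned
with a unit-cost path alignment (edlib).  The diagnostic signal is the
query-side unaligned run over the element body:

* **absent**  -- both flanks anchor on the target and the element (plus tail
  and one TSD copy) falls into a single query-side gap: the orthologous site
  is empty in the target;
* **present** -- the element body itself aligns between the flanks at high
  identity with no target-side hole;
* **ambiguous** -- anything else (one-flank anchors, low element identity such
  as an independent near-parallel insertion of a sister subfamily, no seeds).

Rolled up across the two comparison genomes, each locus is classed
lineage-specific (LS), sister-pair specific (Sag), or shared by all three
(Call); any ambiguous input call sends the locus to a needs-review queue.
"""

from __future__ import annotations

import collections
import re
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._seq import revcomp
from .libscan import Annotation

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class OrthologyParams:
    flank_len: int = 500
    expected_gap: int = 85       # the canonical empty-site gap for a ~100 bp element
    gap_tolerance: int = 40      # absent window floor = expected_gap - gap_tolerance
    max_atail: int = 170         # tail allowance on the absent window ceiling
    max_tsd: int = 16
    present_max_gap: int = 20    # max target-side hole inside a "present" element
    min_flank_aln: int = 100     # aligned bases required to anchor a flank
    min_flank_identity: float = 0.80
    min_element_identity: float = 0.95  # near-parallel-insertion guard
    min_element_cov: float = 0.80
    k: int = 12
    window_pad: int = 150
    min_seed_cov: int = 3        # distinct seeded query positions to accept a chain
    single_flank_ok: bool = False

    def absent_window(self, element_len: int) -> tuple[int, int]:
        return (self.expected_gap - self.gap_tolerance,
                element_len + self.max_atail + 2 * self.max_tsd)


@dataclass
class Locus:
    """A full-length element plus flanks, oriented so the element reads forward."""

    id: str
    genome_id: str
    contig: str
    annotation: Annotation
    flank5: str
    element: str
    flank3: str
    flank5_truncated: bool
    flank3_truncated: bool

    @property
    def query(self) -> str:
        return self.flank5 + self.element + self.flank3

    @property
    def elem_start(self) -> int:
        return len(self.flank5)

    @property
    def elem_end(self) -> int:
        return len(self.flank5) + len(self.element)


@dataclass
class Block:
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    matches: int
    mismatches: int


@dataclass
class Chain:
    """Best collinear alignment of a locus query against one target region."""

    contig: str = ""
    strand: str = "+"
    t_offset: int = 0
    cigar: str = ""
    blocks: list[Block] = field(default_factory=list)
    n_seeds: int = 0
    # per-query-position state: 0 unaligned, 1 match, 2 mismatch
    qstatus: "np.ndarray | None" = None
    window: str = ""
    w_start: int = 0

    @property
    def empty(self) -> bool:
        return not self.blocks


@dataclass
class PresenceCall:
    locus_id: str
    target_genome: str
    call: str                    # present | absent | ambiguous
    observed_gap: int | None
    evidence: dict


@dataclass
class SpecificityClass:
    locus_id: str
    cls: str                     # LS | Sag | Call | other
    needs_review: bool
    calls: dict[str, str]


# ---------------------------------------------------------------------------
# locus extraction

def extract_locus(genome: dict[str, str], annotation: Annotation,
                  params: OrthologyParams | None = None) -> Locus:
    params = params or OrthologyParams()
    seq = genome.get(annotation.contig)
    if seq is None:
        raise ValueError(f"contig {annotation.contig!r} not in genome")
    if not 0 <= annotation.start < annotation.end <= len(seq):
        raise ValueError(f"annotation [{annotation.start},{annotation.end}) "
                         f"outside contig {annotation.contig} (len {len(seq)})")
    f5_start = max(0, annotation.start - params.flank_len)
    flank5 = seq[f5_start:annotation.start]
    element = seq[annotation.start:annotation.end]
    flank3 = seq[annotation.end:annotation.end + params.flank_len]
    trunc5 = len(flank5) < params.flank_len
    trunc3 = len(flank3) < params.flank_len
    if annotation.strand == "-":
        flank5, element, flank3 = revcomp(flank3), revcomp(element), revcomp(flank5)
        trunc5, trunc3 = trunc3, trunc5
    return Locus(
        id=f"{annotation.genome_id}_{annotation.contig}_{annotation.start}",
        genome_id=annotation.genome_id, contig=annotation.contig,
        annotation=annotation, flank5=flank5, element=element, flank3=flank3,
        flank5_truncated=trunc5, flank3_truncated=trunc3,
    )


# ---------------------------------------------------------------------------
# k-mer target index and mapping

def _low_complexity(kmer: str) -> bool:
    """Homopolymer/dinucleotide-repeat k-mers seed everywhere (poly-A tails,
    microsatellites) and carry no positional signal."""
    return len(set(kmer)) <= 2


class GenomeIndex:
    """Exact k-mer index over a genome's forward strands.

    Low-complexity k-mers and k-mers occurring more than ``max_occupancy``
    times are dropped from the index, the usual over-represented-tile
    masking of seed-and-extend mappers.
    """

    def __init__(self, genome: dict[str, str], k: int = 12,
                 max_occupancy: int = 50):
        self.genome = genome
        self.k = k
        index: dict[str, list[tuple[int, int]]] = collections.defaultdict(list)
        self.contigs = list(genome)
        for ci, (name, seq) in enumerate(genome.items()):
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" not in kmer and not _low_complexity(kmer):
                    index[kmer].append((ci, i))
        self.index = {kmer: pos for kmer, pos in index.items()
                      if len(pos) <= max_occupancy}

    def seed_hits(self, query: str, step: int = 1) -> dict[int, list[tuple[int, int]]]:
        hits: dict[int, list[tuple[int, int]]] = collections.defaultdict(list)
        for q in range(0, len(query) - self.k + 1, step):
            for ci, t in self.index.get(query[q:q + self.k], ()):
                hits[ci].append((t, q))
        return hits


def _best_cluster(hits: list[tuple[int, int]], qlen: int, slack: int,
                  ) -> tuple[int, list[tuple[int, int]]] | None:
    """Group seed hits by diagonal band; return (coverage, cluster) of the best.

    ``slack`` bounds the diagonal shift tolerated inside one cluster (must
    absorb an element-sized indel between query and target).
    """
    if not hits:
        return None
    by_diag = sorted(hits, key=lambda h: (h[0] - h[1], h[0]))
    clusters: list[list[tuple[int, int]]] = [[by_diag[0]]]
    for h in by_diag[1:]:
        last = clusters[-1][-1]
        if (h[0] - h[1]) - (last[0] - last[1]) <= slack:
            clusters[-1].append(h)
        else:
            clusters.append([h])
    best = None
    for cl in clusters:
        cov = len({q for _, q in cl})
        t_lo = min(t for t, _ in cl)
        if best is None or cov > best[0] or (cov == best[0] and t_lo < best[2]):
            best = (cov, cl, t_lo)
    return best[0], best[1]


def map_locus(locus: Locus, target: "GenomeIndex | dict[str, str]",
              params: OrthologyParams | None = None) -> Chain:
    """Best collinear chain of the locus query against one target region.

    Both orientations of the query are seeded; the orientation and contig with
    the most distinct seeded query positions wins (ties -> forward strand,
    leftmost target).  Returns an empty chain when nothing seeds.
    """
    params = params or OrthologyParams()
    if not isinstance(target, GenomeIndex):
        target = GenomeIndex(target, k=params.k)
    query = locus.query
    slack = len(locus.element) + params.max_atail + 2 * params.max_tsd
    candidates = []  # (coverage, strand_rank, contig_idx, t_lo, strand, ci, cluster, q)
    for strand, q in (("+", query), ("-", revcomp(query))):
        for ci, hits in target.seed_hits(q).items():
            best = _best_cluster(hits, len(q), slack)
            if best:
                cov, cluster = best
                if cov < params.min_seed_cov:
                    continue
                t_lo = min(t for t, _ in cluster)
                candidates.append((-cov, 0 if strand == "+" else 1, ci, t_lo,
                                   strand, cluster, q))
    if not candidates:
        return Chain()
    candidates.sort(key=lambda c: c[:4])
    _, _, ci, _, strand, cluster, q = candidates[0]
    contig = target.contigs[ci]
    tseq = target.genome[contig]
    lo = max(0, min(t - qp for t, qp in cluster) - params.window_pad)
    hi = min(len(tseq), max(t + (len(q) - qp) for t, qp in cluster) + params.window_pad)
    window = tseq[lo:hi]
    res = edlib.align(q, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return Chain()
    t_start = res["locations"][0][0]
    blocks, qstatus = _cigar_blocks(res["cigar"], q, window, t_start)
    return Chain(contig=contig, strand=strand, t_offset=lo + t_start,
                 cigar=res["cigar"], blocks=blocks, n_seeds=len(cluster),
                 qstatus=qstatus, window=window, w_start=lo)


def _cigar_blocks(cigar: str, query: str, window: str, t_start: int,
                  ) -> tuple[list[Block], np.ndarray]:
    """Extended-CIGAR path -> gap-free aligned blocks + per-query-position state."""
    blocks: list[Block] = []
    qstatus = np.zeros(len(query), dtype=np.int8)
    q = 0
    t = t_start
    cur: Block | None = None
    for n_str, op in _CIGAR_RE.findall(cigar):
        n = int(n_str)
        if op in "=XM":
            if cur is None:
                cur = Block(q, q, t, t, 0, 0)
            if op == "=":
                matches = n
                qstatus[q:q + n] = 1
            elif op == "X":
                matches = 0
                qstatus[q:q + n] = 2
            else:  # plain M: resolve per position
                matches = 0
                for i in range(n):
                    hit = query[q + i] == window[t + i]
                    matches += hit
                    qstatus[q + i] = 1 if hit else 2
            cur.q_end = q + n
            cur.t_end = t + n
            cur.matches += matches
            cur.mismatches += n - matches
            q += n
            t += n
        else:
            if cur is not None:
                blocks.append(cur)
                cur = None
            if op == "I":
                q += n
            else:
                t += n
    if cur is not None:
        blocks.append(cur)
    return blocks, qstatus


# ---------------------------------------------------------------------------
# presence calling

def _hw_align(query: str, target: str) -> dict | None:
    """edlib infix alignment + aligned-column stats.

    Returns t_start/t_end (target, exclusive end), matches and mismatches over
    aligned columns (gap columns excluded), or None for empty input.
    """
    if not query or not target:
        return None
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    t0 = res["locations"][0][0]
    t1 = res["locations"][0][1] + 1
    flags: list[int] = []   # 1 match / 0 mismatch, one entry per aligned column
    q = 0
    t = t0
    for n_str, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n_str)
        if op == "=":
            flags.extend([1] * n)
            q += n
            t += n
        elif op == "X":
            flags.extend([0] * n)
            q += n
            t += n
        elif op == "M":
            flags.extend(1 if query[q + i] == target[t + i] else 0
                         for i in range(n))
            q += n
            t += n
        elif op == "I":
            q += n
        else:
            t += n
    matches = sum(flags)
    return {"t_start": t0, "t_end": t1, "matches": matches,
            "mismatches": len(flags) - matches, "flags": flags}


def _best_window_identity(flags: list[int], width: int) -> float:
    """Best match fraction over any ``width`` consecutive aligned columns.

    A flank anchors on its cleanest stretch: unrelated insertions elsewhere in
    the flank (smeared by the unit-cost aligner into mismatch-rich columns)
    must not veto an otherwise solid anchor.
    """
    if not flags:
        return 0.0
    if len(flags) <= width:
        return sum(flags) / len(flags)
    window = sum(flags[:width])
    best = window
    for i in range(width, len(flags)):
        window += flags[i] - flags[i - width]
        best = max(best, window)
    return best / width


def _leading_a_run(seq: str) -> int:
    n = 0
    for ch in seq:
        if ch in "Aa":
            n += 1
        else:
            break
    return n


def call_presence(chain: Chain, locus: Locus,
                  params: OrthologyParams | None = None,
                  target_genome: str = "") -> PresenceCall:
    """Classify the target site as present / absent / ambiguous.

    The whole-query chain localizes the site; the decision then rests on
    independent infix alignments of each flank against the chain's window.
    The target-side distance between the two flank anchors tells whether the
    element body has a counterpart in the target: an empty orthologous site
    leaves (element + tail + TSD) as a query-side gap, a full counterpart
    closes it.  Unit-cost path alignments fragment long gaps around chance
    matches, so the gap is derived from flank anchor geometry rather than
    from the longest unaligned run of the chain itself.
    """
    params = params or OrthologyParams()
    if chain.empty or not chain.window:
        return PresenceCall(locus.id, target_genome, "ambiguous", None,
                            {"reason": "no alignment"})
    window = chain.window
    if chain.strand == "+":
        f5, elem, f3 = locus.flank5, locus.element, locus.flank3
        junk = _leading_a_run(f3) + params.max_tsd   # tail + TSD copy
        f3_core = f3[min(junk, len(f3)):]
    else:
        # chain orientation reverse-complements the locus: the tail+TSD junk
        # sits at the element-adjacent end of the 5' flank
        f5_full = revcomp(locus.flank3)
        junk = _leading_a_run(locus.flank3) + params.max_tsd
        f5 = f5_full[:max(0, len(f5_full) - junk)]
        elem = revcomp(locus.element)
        f3_core = revcomp(locus.flank5)
    elem_len = len(elem)

    r5 = _hw_align(f5 if chain.strand == "+" else f5, window)
    r3 = _hw_align(f3_core, window)

    def flank_stats(r):
        if r is None:
            return False, 0, 0.0
        aligned = r["matches"] + r["mismatches"]
        ident = _best_window_identity(r["flags"], params.min_flank_aln)
        ok = aligned >= params.min_flank_aln and ident >= params.min_flank_identity
        return ok, aligned, ident

    ok5, aln5, id5 = flank_stats(r5)
    ok3, aln3, id3 = flank_stats(r3)
    evidence = {"flank5_aligned": aln5, "flank5_identity": round(id5, 4),
                "flank3_aligned": aln3, "flank3_identity": round(id3, 4),
                "strand": chain.strand, "contig": chain.contig}
    anchored = (ok5 or ok3) if params.single_flank_ok else (ok5 and ok3)

    gap_target = None
    if r5 is not None and r3 is not None:
        gap_target = r3["t_start"] - r5["t_end"]
    if gap_target is not None:
        observed = elem_len + junk - max(gap_target, 0)
        evidence["target_gap"] = gap_target
        evidence["observed_gap"] = observed
        lo_w, hi_w = params.absent_window(elem_len)
        if anchored and lo_w <= observed <= hi_w:
            return PresenceCall(locus.id, target_genome, "absent", observed,
                                evidence)

    # element-body check between the flank anchors (whole window if a flank
    # anchor is missing, e.g. truncated flanks)
    pad = 30
    seg_lo = r5["t_end"] - pad if r5 is not None else 0
    seg_hi = r3["t_start"] + pad if r3 is not None else len(window)
    seg = window[max(0, seg_lo):max(0, seg_hi)]
    re_ = _hw_align(elem, seg)
    if re_ is not None:
        aligned = re_["matches"] + re_["mismatches"]
        ident = re_["matches"] / aligned if aligned else 0.0
        cov = aligned / elem_len if elem_len else 0.0
        hole = 0
        if gap_target is not None:
            span = re_["t_end"] - re_["t_start"]
            hole = max(0, gap_target - span - junk)
        evidence.update({"element_cov": round(cov, 4),
                         "element_identity": round(ident, 4),
                         "target_hole": hole})
        if (cov >= params.min_element_cov
                and ident >= params.min_element_identity
                and hole <= params.present_max_gap):
            observed = 0 if cov >= 1.0 else elem_len - aligned
            return PresenceCall(locus.id, target_genome, "present", observed,
                                evidence)
    gap = evidence.get("observed_gap")
    return PresenceCall(locus.id, target_genome, "ambiguous",
                        gap if gap and gap > 0 else None, evidence)


# ---------------------------------------------------------------------------
# specificity classification

def classify_specificity(calls: dict[str, PresenceCall], source_genome: str,
                         roles: dict[str, str]) -> SpecificityClass:
    """Roll per-target calls for one locus into a specificity class.

    ``roles`` maps genome id -> "tamarin" | "marmoset" (the sister pair vs the
    outgroup).  From a tamarin source: absent/absent -> LS, present in the
    sister but absent from the outgroup -> Sag, present/present -> Call.  From
    the outgroup source only LS and Call are defined.  Ambiguous inputs send
    the locus to review with a best-guess class of "other".
    """
    for gid in list(calls) + [source_genome]:
        if roles.get(gid) not in ("tamarin", "marmoset"):
            raise ValueError(f"unknown genome role for {gid!r}")
    call_map = {gid: c.call for gid, c in calls.items()}
    locus_id = next(iter(calls.values())).locus_id if calls else "?"
    if "ambiguous" in call_map.values() or len(call_map) < 2:
        return SpecificityClass(locus_id, "other", True, call_map)
    if roles[source_genome] == "tamarin":
        sister = next(g for g in call_map if roles[g] == "tamarin")
        outgroup = next(g for g in call_map if roles[g] == "marmoset")
        s, o = call_map[sister], call_map[outgroup]
        if s == "absent" and o == "absent":
            cls = "LS"
        elif s == "present" and o == "absent":
            cls = "Sag"
        elif s == "present" and o == "present":
            cls = "Call"
        else:  # absent in the sister but present in the outgroup: incongruent
            return SpecificityClass(locus_id, "other", True, call_map)
    else:
        values = set(call_map.values())
        if values == {"absent"}:
            cls = "LS"
        elif values == {"present"}:
            cls = "Call"
        else:
            return SpecificityClass(locus_id, "other", True, call_map)
    return SpecificityClass(locus_id, cls, False, call_map)


# ---------------------------------------------------------------------------
# TSV output

CALLS_COLUMNS = ["locus_id", "target_genome", "call", "observed_gap",
                 "flank5_aligned", "flank5_identity", "flank3_aligned",
                 "flank3_identity", "element_cov", "element_identity"]


def write_calls(calls: list[PresenceCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CALLS_COLUMNS) + "\n")
        for c in calls:
            ev = c.evidence
            fh.write("\t".join([
                c.locus_id, c.target_genome, c.call,
                "" if c.observed_gap is None else str(c.observed_gap),
                str(ev.get("flank5_aligned", "")), str(ev.get("flank5_identity", "")),
                str(ev.get("flank3_aligned", "")), str(ev.get("flank3_identity", "")),
                str(ev.get("element_cov", "")), str(ev.get("element_identity", "")),
            ]) + "\n")
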