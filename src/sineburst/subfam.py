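"""Subfamily discovery from co-segregating diagnostic positions, and
improvement-based element reassignment.

Retroposon copies descend from a handful of source elements; a derived source
carries private ("diagnostic") substitutions and indels that all of its
progeny inherit.  Discovery therefore looks for sets of non-consensus states
-- substitutions, per-column deletions and shared insertion events -- that
co-occur in many rows of a consensus-anchored alignment matrix.  The greedy
splitter below emulates the co-segregation stage of classic subfamily
pipelines: seed on the best-supported deviation, collect every deviation
shared by most of its carriers, split, rebuild a majority-rule consensus, and
recurse into both partitions.

Reassignment is conservative: an element only moves to a discovered subfamily
when doing so does not worsen either its alignment score or its percent
divergence and strictly improves at least one; a discovered subfamily is
retained only if at least one element moves to it.
"""

from __future__ import annotations

import collections
import re
from dataclasses import dataclass, field

import edlib

from ._align import align_stats, make_aligner
from .libscan import ScanParams

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class SubfamilyParams:
    min_subfamily_size: int = 10     # simulation scale; ~50 is the classic default
    min_diagnostic_sites: int = 2
    site_purity: float = 0.8         # fraction of members carrying each diagnostic state
    max_rounds: int = 10
    min_identity: float = 0.5        # rows below this vs the consensus are excluded
    improvement_rule: str = "both"   # "both": neither score worsens; "either": one improves

    def validate(self) -> None:
        if self.min_subfamily_size < 2:
            raise ValueError("min_subfamily_size must be >= 2")
        if self.min_diagnostic_sites < 1:
            raise ValueError("min_diagnostic_sites must be >= 1")
        if not 0.5 < self.site_purity <= 1:
            raise ValueError("site_purity must be in (0.5, 1]")


@dataclass
class Row:
    """One element aligned into consensus coordinates.

    ``bases`` has one character per consensus column ('-' for a deleted
    column); ``insertions`` holds sequence inserted *after* consensus column
    ``pos`` (pos -1 for insertions before the first column).
    """

    element_id: str
    bases: str
    insertions: dict[int, str] = field(default_factory=dict)
    identity: float = 1.0


@dataclass
class ElementMatrix:
    consensus: str
    rows: list[Row] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)   # identity < min_identity
    exact: list[str] = field(default_factory=list)      # identical to consensus


@dataclass
class DiscoveredSubfamily:
    name: str
    consensus: str
    members: list[str]
    diagnostic_sites: list[tuple]


@dataclass
class SubfamilyCall:
    element_id: str
    old_subfamily: str
    new_subfamily: str | None
    old_sw: float
    new_sw: float | None
    old_div: float
    new_div: float | None
    moved: bool


# ---------------------------------------------------------------------------
# alignment into consensus coordinates

_ROW_ALIGNER = make_aligner(2, -3, -5, -1, mode="global")


def _align_row(element_id: str, seq: str, consensus: str) -> Row:
    # affine gaps keep indel diagnostics (e.g. a 9 bp insertion) contiguous,
    # where a unit-cost aligner would shred them around chance matches
    aln = _ROW_ALIGNER.align(consensus, seq)[0]
    c_blocks, q_blocks = aln.aligned
    bases = []
    insertions: dict[int, str] = {}
    matches = 0
    prev_c = prev_q = 0
    for (c0, c1), (q0, q1) in zip(c_blocks, q_blocks):
        if c0 > prev_c:                       # deleted consensus columns
            bases.extend("-" * (c0 - prev_c))
        if q0 > prev_q:                       # inserted relative to consensus
            insertions[prev_c - 1] = (insertions.get(prev_c - 1, "")
                                      + seq[prev_q:q0])
        for i in range(c1 - c0):
            bases.append(seq[q0 + i])
            matches += consensus[c0 + i] == seq[q0 + i]
        prev_c, prev_q = c1, q1
    if prev_c < len(consensus):
        bases.extend("-" * (len(consensus) - prev_c))
    if prev_q < len(seq):
        insertions[prev_c - 1] = insertions.get(prev_c - 1, "") + seq[prev_q:]
    identity = matches / len(consensus) if consensus else 0.0
    return Row(element_id=element_id, bases="".join(bases),
               insertions=insertions, identity=identity)


def align_elements_to_consensus(elements: dict[str, str], consensus: str,
                                params: SubfamilyParams | None = None,
                                ) -> ElementMatrix:
    """Global alignment of each (tail-trimmed) element into consensus columns.

    Elements identical to the consensus are flagged ``exact`` (they carry no
    information about derived states); elements under ``min_identity`` are
    excluded from the matrix entirely.
    """
    params = params or SubfamilyParams()
    matrix = ElementMatrix(consensus=consensus)
    for element_id, seq in elements.items():
        row = _align_row(element_id, seq, consensus)
        if row.identity < params.min_identity:
            matrix.excluded.append(element_id)
        elif row.bases == consensus and not row.insertions:
            matrix.exact.append(element_id)
            matrix.rows.append(row)
        else:
            matrix.rows.append(row)
    return matrix


# ---------------------------------------------------------------------------
# co-segregation discovery

def _row_features(row: Row, cons_bases: str, cons_ins: dict[int, str]) -> set[tuple]:
    feats: set[tuple] = set()
    for i, (b, cb) in enumerate(zip(row.bases, cons_bases)):
        if b != cb:
            feats.add(("col", i, b))
    for pos, seq in row.insertions.items():
        if cons_ins.get(pos) != seq:
            feats.add(("ins", pos, seq))
    for pos in cons_ins:
        if pos not in row.insertions:
            feats.add(("noins", pos, ""))
    return feats


def _feature_sort_key(feat: tuple) -> tuple:
    kind, pos, state = feat
    return (pos, kind, state)


def _build_consensus(members: list[Row], cons_bases: str, cons_ins: dict[int, str],
                     ) -> tuple[str, dict[int, str]]:
    """Majority-rule consensus over members; ties fall back to the parent state."""
    n = len(members)
    out = []
    for i, parent_base in enumerate(cons_bases):
        counts = collections.Counter(r.bases[i] for r in members)
        base, cnt = max(counts.items(), key=lambda kv: (kv[1], kv[0] == parent_base))
        if counts[parent_base] >= cnt:
            base = parent_base
        out.append(base)
    ins: dict[int, str] = {}
    candidates = {(p, s) for r in members for p, s in r.insertions.items()}
    candidates |= {(p, s) for p, s in cons_ins.items()}
    for pos, seq in sorted(candidates):
        support = sum(1 for r in members if r.insertions.get(pos) == seq)
        if support > n / 2:
            ins[pos] = seq
    return "".join(out), ins


def _realize(cons_bases: str, cons_ins: dict[int, str]) -> str:
    """Column string + insertion events -> plain consensus sequence."""
    out = []
    if -1 in cons_ins:
        out.append(cons_ins[-1])
    for i, b in enumerate(cons_bases):
        if b != "-":
            out.append(b)
        if i in cons_ins:
            out.append(cons_ins[i])
    return "".join(out)


def discover_subfamilies(matrix: ElementMatrix,
                         params: SubfamilyParams | None = None,
                         parent_name: str = "subfam",
                         ) -> list[DiscoveredSubfamily]:
    """Greedy iterative splitting on co-segregating deviations.

    At each node: the deviation (from the node's consensus) carried by the
    most rows seeds a candidate; the candidate's diagnostic set is every
    deviation carried by >= site_purity of its rows; a split requires
    >= min_diagnostic_sites diagnostics and >= min_subfamily_size rows.
    Both partitions are then searched recursively, the member partition
    against its new consensus.  Discovery order (largest support first, ties
    to the leftmost seed position) fixes the auto-assigned suffix letters.
    """
    params = params or SubfamilyParams()
    params.validate()
    results: list[DiscoveredSubfamily] = []
    suffixes = iter("abcdefghijklmnopqrstuvwxyz")

    def recurse(rows: list[Row], cons_bases: str, cons_ins: dict[int, str],
                rounds_left: int) -> None:
        if rounds_left <= 0 or len(rows) < params.min_subfamily_size:
            return
        feats_by_row = [_row_features(r, cons_bases, cons_ins) for r in rows]
        support: collections.Counter = collections.Counter()
        for feats in feats_by_row:
            support.update(feats)
        candidates = [f for f, n in support.items()
                      if n >= params.min_subfamily_size]
        best = None
        for f in sorted(candidates, key=_feature_sort_key):
            carriers = [i for i, feats in enumerate(feats_by_row) if f in feats]
            diag = [g for g, n in collections.Counter(
                        g for i in carriers for g in feats_by_row[i]).items()
                    if n >= params.site_purity * len(carriers)]
            if len(diag) < params.min_diagnostic_sites:
                continue
            # candidates iterate leftmost-first, so strict > keeps the
            # leftmost seed on support ties
            if best is None or len(carriers) > len(best[1]):
                best = (f, carriers, diag)
        if best is None:
            return
        _, carriers, diag = best
        members = [rows[i] for i in carriers]
        rest = [r for i, r in enumerate(rows) if i not in set(carriers)]
        new_bases, new_ins = _build_consensus(members, cons_bases, cons_ins)
        name = f"{parent_name}{next(suffixes)}"
        results.append(DiscoveredSubfamily(
            name=name, consensus=_realize(new_bases, new_ins),
            members=[r.element_id for r in members],
            diagnostic_sites=sorted(diag, key=_feature_sort_key),
        ))
        recurse(members, new_bases, new_ins, rounds_left - 1)
        recurse(rest, cons_bases, cons_ins, rounds_left - 1)

    recurse(matrix.rows, matrix.consensus, {}, params.max_rounds)
    return results


# ---------------------------------------------------------------------------
# rescoring and the retention rule

def _score_element(aligner, consensus: str, seq: str) -> tuple[float, float]:
    stats = align_stats(aligner, seq, consensus)
    if stats is None:
        return 0.0, 100.0
    return stats.score, stats.pct_div


def reassign_elements(elements: dict[str, str],
                      old_assignments: dict[str, str],
                      old_library: dict[str, str],
                      new_subfamilies: list[DiscoveredSubfamily],
                      scan_params: ScanParams | None = None,
                      params: SubfamilyParams | None = None,
                      ) -> tuple[list[SubfamilyCall], list[DiscoveredSubfamily]]:
    """Rescore elements against old + candidate consensuses; apply the
    improvement rule; retain only candidate subfamilies that gain members.

    Under the default "both" rule an element moves iff the new score is not
    worse on either axis (SW score, % divergence) and strictly better on at
    least one; "either" relaxes to a single strict improvement.
    """
    scan_params = scan_params or ScanParams()
    params = params or SubfamilyParams()
    aligner = make_aligner(scan_params.match, scan_params.mismatch,
                           scan_params.gap_open, scan_params.gap_extend,
                           mode="local")
    calls: list[SubfamilyCall] = []
    moved_to: collections.Counter = collections.Counter()
    for element_id, seq in elements.items():
        old_name = old_assignments[element_id]
        old_sw, old_div = _score_element(aligner, old_library[old_name], seq)
        best = None
        for sub in new_subfamilies:
            sw, div = _score_element(aligner, sub.consensus, seq)
            if best is None or (sw, -div) > (best[1], -best[2]):
                best = (sub.name, sw, div)
        if best is None:
            calls.append(SubfamilyCall(element_id, old_name, None, old_sw, None,
                                       old_div, None, False))
            continue
        name, new_sw, new_div = best
        if params.improvement_rule == "either":
            moves = new_sw > old_sw or new_div < old_div
        else:
            moves = (new_sw >= old_sw and new_div <= old_div
                     and (new_sw > old_sw or new_div < old_div))
        calls.append(SubfamilyCall(element_id, old_name, name if moves else None,
                                   old_sw, new_sw, old_div, new_div, moves))
        if moves:
            moved_to[name] += 1
    retained = [s for s in new_subfamilies if moved_to[s.name] > 0]
    return calls, retained


def improvement_summary(calls: list[SubfamilyCall]):
    """Per-new-subfamily mean delta-SW and delta-%div over moved elements."""
    import pandas as pd

    rows = [dict(new_subfamily=c.new_subfamily,
                 d_sw=c.new_sw - c.old_sw, d_div=c.new_div - c.old_div)
            for c in calls if c.moved]
    if not rows:
        return pd.DataFrame(columns=["new_subfamily", "n", "mean_d_sw", "mean_d_div"])
    df = pd.DataFrame(rows)
    out = df.groupby("new_subfamily").agg(n=("d_sw", "size"),
                                          mean_d_sw=("d_sw", "mean"),
                                          mean_d_div=("d_div", "mean"))
    return out.reset_index()


# ---------------------------------------------------------------------------
# consensus-ladder alignment rendering (dots = identity, dashes = gaps)

def render_consensus_alignment(parent_name: str, parent_seq: str,
                               subfamilies: list[DiscoveredSubfamily]) -> str:
    """Text alignment of each discovered consensus against the parent.

    Dots mark bases shared with the parent, dashes mark alignment gaps, and
    diagnostic changes appear as the substituted base -- the conventional way
    subfamily ladders are displayed.
    """
    width = max([len(parent_name)] + [len(s.name) for s in subfamilies]) + 2
    lines = [f"{parent_name:<{width}}{parent_seq}"]
    for sub in subfamilies:
        res = edlib.align(sub.consensus, parent_seq, mode="NW", task="path")
        out = []
        q = c = 0
        for n_str, op in _CIGAR_RE.findall(res["cigar"]):
            n = int(n_str)
            if op in "=XM":
                for i in range(n):
                    out.append("." if sub.consensus[q + i] == parent_seq[c + i]
                               else sub.consensus[q + i])
                q += n
                c += n
            elif op == "I":
                out.append(sub.consensus[q:q + n].lower())
                q += n
            else:
                out.append("-" * n)
                c += n
        lines.append(f"{sub.name:<{width}}{''.join(out)}")
    return "\n".join(lines)
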