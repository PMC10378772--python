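"""Summary surfaces: A-tail lengths, divergence bins, ages, and count tables.

The reporting conventions follow the field's habits for young-SINE surveys:

* A-tail length is the longest run of consecutive adenosines in the region
  between the element's 3' end and its 3' target-site duplication; a tail is
  "pristine" when the run spans the whole region (no intervening bases) --
  long pristine tails flag recently mobilized, retrotransposition-competent
  copies.
* Age is read linearly off percent divergence from the subfamily consensus:
  ``age_my = (pct_div / 100) / rate``.  For ~100 bp elements a single
  substitution is already 1% divergence (~1.66 my), so ages are coarse.
* Divergence histograms are stacked per subfamily in neighbor-joining tree
  order, oldest at the top.
* Percentage tables round half-up to two decimals, with per-class totals as
  denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .simgen import ELEMENT_DECAY_RATE


@dataclass(frozen=True)
class AgeModel:
    rate: float = ELEMENT_DECAY_RATE   # substitutions / bp / my

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be > 0")


@dataclass(frozen=True)
class BinSpec:
    width: float = 1.0      # percent divergence per bin
    lo: float = 0.0
    hi: float = 25.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("bin width must be > 0")

    def edges(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + self.width, self.width)


def longest_terminal_a_run(seq: str) -> int:
    """Longest run of consecutive A's within the 3' tail region."""
    best = run = 0
    for ch in seq:
        if ch in "Aa":
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def is_pristine(seq: str) -> bool:
    """True when the tail is one uninterrupted A-run spanning the region."""
    return bool(seq) and longest_terminal_a_run(seq) == len(seq)


def divergence_to_age(pct_div: float, model: AgeModel | None = None) -> float:
    """Percent divergence -> age in my, 2-decimal reporting precision."""
    if pct_div < 0:
        raise ValueError("pct_div must be >= 0")
    model = model or AgeModel()
    return round((pct_div / 100.0) / model.rate, 2)


def bin_elements(elements: pd.DataFrame, spec: BinSpec | None = None,
                 order: list[str] | None = None) -> pd.DataFrame:
    """Stacked per-bin, per-subfamily counts.

    ``elements`` needs columns ``pct_div`` and ``subfamily``; rows with a
    missing subfamily are counted in an explicit ``unassigned`` stratum.
    Column order follows ``order`` (the NJ tree leaf order) with any
    leftover subfamilies appended alphabetically.
    """
    spec = spec or BinSpec()
    df = elements.copy()
    df["subfamily"] = df["subfamily"].fillna("unassigned").replace("", "unassigned")
    edges = spec.edges()
    labels = [f"{edges[i]:g}-{edges[i + 1]:g}" for i in range(len(edges) - 1)]
    df["bin"] = pd.cut(df["pct_div"].clip(upper=spec.hi - 1e-9), bins=edges,
                       labels=labels, right=False, include_lowest=True)
    table = (df.groupby(["bin", "subfamily"], observed=False).size()
             .unstack(fill_value=0))
    table = table.reindex(labels, fill_value=0)
    cols = list(table.columns)
    ordered = [c for c in (order or []) if c in cols]
    ordered += sorted(c for c in cols if c not in ordered and c != "unassigned")
    if "unassigned" in cols:
        ordered.append("unassigned")
    return table[ordered]


def _pct(numer: int, denom: int) -> str:
    """Half-up 2-decimal percentage; empty string on a zero denominator."""
    if denom == 0:
        return ""
    numer, denom = int(numer), int(denom)
    value = (Decimal(numer) * 100 / Decimal(denom)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP)
    return f"{value}"


def assignment_percentages(counts: dict[str, int], class_total: int) -> pd.DataFrame:
    """Per-subfamily counts + percentages of the class total, plus a total row.

    This is the arithmetic behind "assigned to new subfamilies" tables: the
    denominator is the class total (all loci of that specificity class), so
    the total row reports how much of the class the new subfamilies absorb.
    """
    rows = [{"subfamily": name, "count": n, "pct_of_class": _pct(n, class_total)}
            for name, n in counts.items()]
    total = sum(counts.values())
    rows.append({"subfamily": "total_assigned", "count": total,
                 "pct_of_class": _pct(total, class_total)})
    return pd.DataFrame(rows, columns=["subfamily", "count", "pct_of_class"])


def atail_report(tails: dict[str, str]) -> pd.DataFrame:
    """Per-element A-tail stats: max run, region length, pristine flag."""
    rows = [{"element_id": eid,
             "tail_length": len(region),
             "max_a_run": longest_terminal_a_run(region),
             "pristine": is_pristine(region)}
            for eid, region in tails.items()]
    return pd.DataFrame(rows, columns=["element_id", "tail_length",
                                       "max_a_run", "pristine"])


def specificity_report(annotations: pd.DataFrame, classes: pd.DataFrame,
                       assignments: pd.DataFrame | None = None,
                       ) -> dict[str, pd.DataFrame]:
    """Count tables over the pipeline's outputs.

    ``annotations``: one row per full-length element (genome_id, subfamily,
    flanks_complete).  ``classes``: one row per classified locus (genome_id,
    cls).  ``assignments`` (optional): element_id, genome_id, cls,
    new_subfamily for reassigned elements.

    Returns ``table1`` (per-genome per-subfamily counts), ``table2``
    (per-genome totals / flank-complete / specificity counts) and, when
    assignments are given, ``table3`` (per-new-subfamily counts with
    percentages of each class total).
    """
    t1 = (annotations.groupby(["genome_id", "subfamily"]).size()
          .unstack(fill_value=0).reset_index())

    rows = []
    for gid, sub in annotations.groupby("genome_id"):
        cls_counts = classes[classes.genome_id == gid].cls.value_counts()
        rows.append({
            "genome_id": gid,
            "total_full_length": len(sub),
            "full_length_with_flanks": int(sub.flanks_complete.sum())
            if "flanks_complete" in sub else len(sub),
            "LS": int(cls_counts.get("LS", 0)),
            "Sag": int(cls_counts.get("Sag", 0)),
            "Call": int(cls_counts.get("Call", 0)),
            "other": int(cls_counts.get("other", 0)),
        })
    t2 = pd.DataFrame(rows)

    out = {"table1": t1, "table2": t2}
    if assignments is not None and len(assignments):
        t3_parts = []
        for (gid, cls), sub in assignments.groupby(["genome_id", "cls"]):
            class_total = int((classes[(classes.genome_id == gid)
                                       & (classes.cls == cls)]).shape[0])
            counts = sub[sub.new_subfamily.notna()].new_subfamily.value_counts()
            t3 = assignment_percentages(dict(counts), class_total)
            t3.insert(0, "cls", cls)
            t3.insert(0, "genome_id", gid)
            t3_parts.append(t3)
        if t3_parts:
            out["table3"] = pd.concat(t3_parts, ignore_index=True)
    return out
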