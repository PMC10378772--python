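"""End-to-end orchestration: simulate -> scan -> classify -> discover -> report.

``run_all`` executes the stages in study order against a simulated trio (or
user-provided FASTAs), writing TSVs per stage under one run directory, and
``evaluate_against_truth`` scores every stage against the simulator's
manifest.  All stage outputs are deterministic under the run seed; the run
log (timings, versions) is the only non-reproducible file.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import time
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import njtree, orthocall, subfam, summarize
from ._seq import read_fasta
from .libscan import Annotation, ScanParams, is_full_length, scan_genome, write_scan_out
from .orthocall import GenomeIndex, OrthologyParams
from .simgen import SimConfig, TrioResult, make_founder_library, simulate_trio
from .subfam import SubfamilyParams
from .summarize import AgeModel, BinSpec

DEFAULT_ROLES = {"A": "tamarin", "B": "tamarin", "C": "marmoset"}


@dataclass
class RunConfig:
    outdir: str = "run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    scan: ScanParams = field(default_factory=ScanParams)
    ortho: OrthologyParams = field(default_factory=OrthologyParams)
    subfam: SubfamilyParams = field(default_factory=SubfamilyParams)
    bins: BinSpec = field(default_factory=BinSpec)
    age: AgeModel = field(default_factory=AgeModel)
    roles: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ROLES))
    genomes: dict[str, str] = field(default_factory=dict)  # role-tagged FASTA paths
    library_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(open(path)) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if dataclasses.is_dataclass(current) and isinstance(value, dict):
                setattr(cfg, key, dataclasses.replace(current, **value))
            else:
                setattr(cfg, key, value)
        cfg.sim.seed = cfg.seed
        return cfg

    def validate(self) -> None:
        for tip, path in self.genomes.items():
            if not pathlib.Path(path).exists():
                raise FileNotFoundError(f"genome for {tip!r} not found: {path}")
        if self.genomes and set(self.genomes) != set(self.roles):
            raise ValueError("genome roles must cover exactly the configured taxa")


@dataclass
class RunResult:
    outdir: pathlib.Path
    trio: TrioResult | None
    annotations: dict[str, list[Annotation]]
    loci: dict[str, list]
    classes: list[dict]
    discovered: list
    retained: list
    calls_df: pd.DataFrame
    classes_df: pd.DataFrame
    assignments_df: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    newick: str
    leaf_order: list[str]


def _log(fh, msg: str) -> None:
    fh.write(msg + "\n")
    fh.flush()


def run_all(config: RunConfig) -> RunResult:
    """Run every stage; returns in-memory results and writes stage TSVs."""
    config.validate()
    out = pathlib.Path(config.outdir)
    for sub in ("sim", "scan", "ortho", "subfam", "summary", "tree"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    log = open(out / "run.log", "w")
    _log(log, f"seed={config.seed}")
    t_start = time.time()

    # -- stage 1: genomes (simulated unless provided)
    if config.genomes:
        genomes = {tip: read_fasta(path) for tip, path in config.genomes.items()}
        trio = None
        if not config.library_path:
            raise ValueError("library_path is required with user-provided genomes")
        library = read_fasta(config.library_path)
        scan_library = dict(library)
    else:
        config.sim.seed = config.seed
        trio = simulate_trio(config.sim, make_founder_library(config.seed))
        trio.write(out / "sim")
        genomes = trio.genomes
        library = dict(trio.library.sequences)
        scan_library = dict(trio.library.founders())  # derived subfamilies are unknown
    _log(log, f"stage=sim wall={time.time() - t_start:.1f}s")

    # -- stage 2: library scan + full-length filter
    t0 = time.time()
    annotations: dict[str, list[Annotation]] = {}
    full_length: dict[str, list[Annotation]] = {}
    for tip in sorted(genomes):
        hits = scan_genome(genomes[tip], scan_library, config.scan, genome_id=tip)
        annotations[tip] = hits
        full_length[tip] = [h for h in hits
                            if is_full_length(h, config.scan,
                                              len(scan_library[h.subfamily]))]
        write_scan_out(hits, out / "scan" / f"hits_{tip}.tsv")
        write_scan_out(full_length[tip], out / "scan" / f"full_length_{tip}.tsv")
    _log(log, f"stage=scan wall={time.time() - t0:.1f}s "
              f"hits={sum(len(v) for v in annotations.values())}")

    # -- stage 3: orthology presence/absence + specificity
    t0 = time.time()
    indexes = {tip: GenomeIndex(genomes[tip], k=config.ortho.k) for tip in genomes}
    loci: dict[str, list] = {tip: [] for tip in genomes}
    presence_rows = []
    class_rows = []
    for tip in sorted(genomes):
        for ann in full_length[tip]:
            locus = orthocall.extract_locus(genomes[tip], ann, config.ortho)
            loci[tip].append(locus)
            calls = {}
            for tgt in sorted(genomes):
                if tgt == tip:
                    continue
                chain = orthocall.map_locus(locus, indexes[tgt], config.ortho)
                call = orthocall.call_presence(chain, locus, config.ortho,
                                               target_genome=tgt)
                calls[tgt] = call
                ev = call.evidence
                presence_rows.append({
                    "locus_id": locus.id, "source": tip, "target": tgt,
                    "call": call.call, "observed_gap": call.observed_gap,
                    "flank5_identity": ev.get("flank5_identity"),
                    "flank3_identity": ev.get("flank3_identity"),
                    "element_identity": ev.get("element_identity"),
                })
            spec_class = orthocall.classify_specificity(calls, tip, config.roles)
            class_rows.append({
                "locus_id": locus.id, "genome_id": tip, "contig": locus.contig,
                "start": ann.start, "end": ann.end,
                "subfamily": ann.subfamily, "pct_div": ann.pct_div,
                "cls": spec_class.cls, "needs_review": spec_class.needs_review,
                "flanks_complete": not (locus.flank5_truncated
                                        or locus.flank3_truncated),
            })
    calls_df = pd.DataFrame(presence_rows)
    classes_df = pd.DataFrame(class_rows)
    calls_df.to_csv(out / "ortho" / "calls.tsv", sep="\t", index=False)
    classes_df.to_csv(out / "ortho" / "classes.tsv", sep="\t", index=False)
    classes_df[classes_df.needs_review].to_csv(out / "ortho" / "review_queue.tsv",
                                               sep="\t", index=False)
    _log(log, f"stage=ortho wall={time.time() - t0:.1f}s loci={len(classes_df)}")

    # -- stage 4: subfamily discovery on LS and shared-pair sets, then reassignment
    t0 = time.time()
    tamarins = sorted(t for t, r in config.roles.items() if r == "tamarin")
    discovery_sets: dict[str, dict[str, str]] = {}
    for tip in tamarins:
        sub = classes_df[(classes_df.genome_id == tip) & (classes_df.cls == "LS")]
        discovery_sets[f"LS-{tip}"] = _element_seqs(sub, genomes)
    sag = classes_df[(classes_df.genome_id.isin(tamarins)) & (classes_df.cls == "Sag")]
    discovery_sets["Sag"] = _element_seqs(sag, genomes)

    parent_name = max(scan_library, key=lambda n: sum(
        classes_df.subfamily == n))  # the dominant ancestral subfamily
    parent_seq = scan_library[parent_name]
    candidates: list[subfam.DiscoveredSubfamily] = []
    seen_consensus: set[str] = set()
    for set_name, elements in discovery_sets.items():
        if len(elements) < config.subfam.min_subfamily_size:
            continue
        matrix = subfam.align_elements_to_consensus(elements, parent_seq,
                                                    config.subfam)
        for cand in subfam.discover_subfamilies(matrix, config.subfam,
                                                parent_name=parent_name):
            if cand.consensus not in seen_consensus:
                seen_consensus.add(cand.consensus)
                candidates.append(cand)
    # stable re-lettering across discovery sets
    candidates = [dataclasses.replace(c, name=f"{parent_name}{chr(97 + i)}_new")
                  for i, c in enumerate(candidates)]

    all_elements: dict[str, str] = {}
    elem_meta: dict[str, tuple[str, str]] = {}
    for _, row in classes_df.iterrows():
        seq = genomes[row.genome_id][row.contig][row.start:row.end]
        all_elements[row.locus_id] = seq
        elem_meta[row.locus_id] = (row.genome_id, row.cls)
    old_assign = {row.locus_id: row.subfamily for _, row in classes_df.iterrows()}
    calls, retained = subfam.reassign_elements(all_elements, old_assign,
                                               scan_library, candidates,
                                               config.scan, config.subfam)
    assignments_df = pd.DataFrame([{
        "element_id": c.element_id,
        "genome_id": elem_meta[c.element_id][0],
        "cls": elem_meta[c.element_id][1],
        "old_subfamily": c.old_subfamily,
        "new_subfamily": c.new_subfamily if c.moved else None,
        "old_sw": c.old_sw, "new_sw": c.new_sw,
        "old_div": c.old_div, "new_div": c.new_div,
    } for c in calls])
    assignments_df.to_csv(out / "subfam" / "assignments.tsv", sep="\t", index=False)
    summary_df = subfam.improvement_summary(calls)
    summary_df.to_csv(out / "subfam" / "improvement.tsv", sep="\t", index=False)
    with open(out / "subfam" / "consensus_ladder.txt", "w") as fh:
        fh.write(subfam.render_consensus_alignment(parent_name, parent_seq,
                                                   retained) + "\n")
    new_library = dict(scan_library)
    for sub in retained:
        new_library[sub.name] = sub.consensus
    _log(log, f"stage=subfam wall={time.time() - t0:.1f}s "
              f"candidates={len(candidates)} retained={len(retained)}")

    # -- stage 5: NJ tree of the augmented library
    t0 = time.time()
    labels, dmat = njtree.pairwise_distances(new_library, config.scan.match,
                                             config.scan.mismatch,
                                             config.scan.gap_open,
                                             config.scan.gap_extend)
    tree = njtree.neighbor_joining(labels, dmat)
    nwk = njtree.newick(tree)
    order = njtree.leaf_order(tree)
    (out / "tree" / "subfamilies.nwk").write_text(nwk + "\n")
    _log(log, f"stage=tree wall={time.time() - t0:.1f}s")

    # -- stage 6: summaries
    t0 = time.time()
    final_div = []
    for _, row in assignments_df.iterrows():
        div = row.new_div if row.new_subfamily else row.old_div
        name = row.new_subfamily if row.new_subfamily else row.old_subfamily
        final_div.append({"locus_id": row.element_id, "genome_id": row.genome_id,
                          "cls": row.cls, "subfamily": name, "pct_div": div,
                          "age_my": summarize.divergence_to_age(div, config.age)})
    final_df = pd.DataFrame(final_div)
    final_df.to_csv(out / "summary" / "final_assignments.tsv", sep="\t", index=False)

    bins_parts = []
    for cls in ("Call", "Sag", "LS"):
        sub = final_df[final_df.cls == cls]
        if len(sub) == 0:
            continue
        table = summarize.bin_elements(sub, config.bins, order=order)
        table.insert(0, "cls", cls)
        bins_parts.append(table.reset_index())
    bins_df = (pd.concat(bins_parts, ignore_index=True)
               if bins_parts else pd.DataFrame())
    bins_df.to_csv(out / "summary" / "bins.tsv", sep="\t", index=False)

    tails = {}
    for tip in sorted(genomes):
        for locus in loci[tip]:
            region = _tail_region(genomes[tip], locus)
            tails[locus.id] = region
    atail_df = summarize.atail_report(tails)
    atail_df.to_csv(out / "summary" / "atail.tsv", sep="\t", index=False)

    ann_df = classes_df.rename(columns={"locus_id": "element_id"})
    tables = summarize.specificity_report(ann_df, classes_df, assignments_df)
    tables["atail"] = atail_df
    tables["bins"] = bins_df
    tables["final"] = final_df
    for name in ("table1", "table2", "table3"):
        if name in tables:
            tables[name].to_csv(out / "summary" / f"{name}_analog.tsv",
                                sep="\t", index=False)
    _log(log, f"stage=summary wall={time.time() - t0:.1f}s")
    _log(log, f"total wall={time.time() - t_start:.1f}s")
    log.close()

    return RunResult(outdir=out, trio=trio, annotations=annotations, loci=loci,
                     classes=class_rows, discovered=candidates, retained=retained,
                     calls_df=calls_df, classes_df=classes_df,
                     assignments_df=assignments_df, tables=tables,
                     newick=nwk, leaf_order=order)


def _element_seqs(rows: pd.DataFrame, genomes: dict) -> dict[str, str]:
    return {row.locus_id: genomes[row.genome_id][row.contig][row.start:row.end]
            for _, row in rows.iterrows()}


def _tail_region(genome: dict[str, str], locus) -> str:
    """Element 3' end to the 3' TSD, approximated as the contiguous A-run
    (exact under the default no-tail-mutation model)."""
    seq = genome[locus.contig]
    start = locus.annotation.end
    end = start
    while end < len(seq) and seq[end] in "Aa" and end - start < 200:
        end += 1
    return seq[start:end]


# ---------------------------------------------------------------------------
# evaluation against the simulator's ground truth

def evaluate_against_truth(result: RunResult, manifest: pd.DataFrame | None = None,
                           tolerance_bp: int = 2) -> dict:
    """Score every stage against the manifest.

    Returns ascertainment per class (manifest insertions recovered as
    full-length loci), classification precision/recall per class over
    classified loci, youngest-subfamily assignment rate, and the coordinate
    error distribution.  Loci at planted near-parallel sites are expected in
    the review queue and are scored as their own category.
    """
    if manifest is None:
        if result.trio is None:
            raise ValueError("no manifest available for a non-simulated run")
        manifest = result.trio.manifest

    truth_by_tip: dict[str, dict] = {}
    for _, row in manifest.iterrows():
        for tip in ("A", "B", "C"):
            if row[f"{tip}_start"] >= 0:
                truth_by_tip.setdefault(tip, {})[
                    (row[f"{tip}_contig"], int(row[f"{tip}_start"]))] = row

    def true_class(row) -> str:
        return {"Call": "Call", "Sag": "Sag"}.get(row.sharing_class, "LS")

    matched = []
    coord_errors = []
    for rec in result.classes:
        lookup = truth_by_tip.get(rec["genome_id"], {})
        found = None
        for offset in range(0, 11):
            for sign in (1, -1):
                key = (rec["contig"], rec["start"] - sign * offset)
                if key in lookup:
                    found = (lookup[key], offset)
                    break
            if found:
                break
        if found is None:
            matched.append((rec, None, None))
            continue
        row, err = found
        coord_errors.append(err)
        matched.append((rec, row, err))

    confusion: dict[tuple[str, str], int] = {}
    parallel_reviewed = parallel_total = 0
    for rec, row, _ in matched:
        if row is None:
            continue
        if row.parallel_site >= 0:
            parallel_total += 1
            if rec["needs_review"]:
                parallel_reviewed += 1
            continue
        key = (true_class(row), rec["cls"])
        confusion[key] = confusion.get(key, 0) + 1

    metrics = {}
    classes = ("LS", "Sag", "Call")
    for cls in classes:
        tp = confusion.get((cls, cls), 0)
        fp = sum(v for (t, p), v in confusion.items() if p == cls and t != cls)
        fn = sum(v for (t, p), v in confusion.items() if t == cls and p != cls)
        metrics[f"precision_{cls}"] = tp / (tp + fp) if tp + fp else float("nan")
        metrics[f"recall_{cls}"] = tp / (tp + fn) if tp + fn else float("nan")

    # ascertainment: manifest rows (per carrier genome) recovered as loci
    ascert: dict[str, list[int]] = {}
    recovered_keys = {(rec["genome_id"], rec["contig"],
                       rec["start"]) for rec in result.classes}
    for _, row in manifest.iterrows():
        cls = true_class(row)
        for tip in ("A", "B", "C"):
            if row[f"{tip}_start"] < 0:
                continue
            hit = any(g == tip and c == row[f"{tip}_contig"]
                      and abs(s - row[f"{tip}_start"]) <= tolerance_bp
                      for g, c, s in recovered_keys)
            ascert.setdefault(cls, []).append(int(hit))
    for cls, flags in ascert.items():
        metrics[f"ascertainment_{cls}"] = sum(flags) / len(flags)

    # youngest-subfamily concentration among reassigned LS elements
    adf = result.assignments_df
    youngest = _youngest_subfamily(result)
    ls_moved = adf[(adf.cls == "LS") & adf.new_subfamily.notna()]
    if len(ls_moved) and youngest:
        metrics["youngest_fraction_of_reassigned_LS"] = float(
            (ls_moved.new_subfamily == youngest).mean())
    metrics["coordinate_error_max"] = max(coord_errors) if coord_errors else None
    metrics["parallel_site_reviewed"] = (parallel_reviewed, parallel_total)
    metrics["confusion"] = confusion
    return metrics


def _youngest_subfamily(result: RunResult) -> str | None:
    """The retained subfamily with the lowest mean divergence of its movers."""
    adf = result.assignments_df
    moved = adf[adf.new_subfamily.notna()]
    if not len(moved):
        return None
    return moved.groupby("new_subfamily").new_div.mean().idxmin()


def write_evaluation(metrics: dict, path) -> None:
    flat = {k: (list(v) if isinstance(v, tuple) else v)
            for k, v in metrics.items() if k != "confusion"}
    flat["confusion"] = {f"{t}->{p}": v
                        for (t, p), v in metrics.get("confusion", {}).items()}
    pathlib.Path(path).write_text(json.dumps(flat, indent=2, default=str) + "\n")
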