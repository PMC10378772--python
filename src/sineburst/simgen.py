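"""Seeded synthetic genome trios with planted SINE insertions and exact ground truth.

The simulator emulates the data regime of a three-taxon study system
``((A, B), C)`` -- two closely related sister species (tamarin-like, split 5
million years ago by default) and an outgroup (marmoset-like, split 15 my ago)
-- undergoing a recent burst of SINE retroposition.  Every planted insertion
is a target-primed reverse transcription (TPRT) product::

    5'-[TSD] [element consensus, mutated by age] [poly-A tail] [TSD copy]-3'

where the target-site duplication (TSD) is copied from the background at the
insertion point.  Insertions are partitioned into sharing classes:

* ``Call``  -- present in all three genomes (pre-dates the deepest split);
* ``Sag``   -- shared by the two sister taxa only;
* ``LS-A`` / ``LS-B`` / ``LS-C`` -- specific to a single tip.

Element copies are mutated once, with a Binomial(len, age x rate) draw, and the
identical copy is planted in every carrier genome; flanking background instead
accumulates substitutions independently along each tree branch.  That single
draw makes the manifest exact: stripping TSD and tail from the recorded
coordinates recovers a sequence whose distance to the subfamily consensus
equals the drawn mutation count.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seq import decode, encode, random_seq, write_fasta

ELEMENT_DECAY_RATE = 0.006024  # substitutions / bp / my, SINE-body decay clock

SHARING_CLASSES = ("Call", "Sag", "LS-A", "LS-B", "LS-C")

# carrier tips per sharing class
_CARRIERS = {
    "Call": ("A", "B", "C"),
    "Sag": ("A", "B"),
    "LS-A": ("A",),
    "LS-B": ("B",),
    "LS-C": ("C",),
}

MANIFEST_COLUMNS = [
    "id", "subfamily", "sharing_class", "age_my", "n_sub", "strand",
    "tsd", "atail_length", "anc_pos", "parallel_site",
    "A_contig", "A_start", "A_end",
    "B_contig", "B_start", "B_end",
    "C_contig", "C_start", "C_end",
]


# ---------------------------------------------------------------------------
# configuration and domain types

@dataclass
class SimConfig:
    """Study conditions for one simulated trio.

    Ages are in millions of years (my); rates in substitutions/bp/my.
    ``mutation_rate`` is the element-body decay clock; flanking background
    evolves at the slower neutral ``background_mutation_rate`` (genomic
    divergence between the sister taxa and the outgroup in real New World
    monkey assemblies is far below what the SINE decay clock would predict).
    """

    seed: int = 0
    genome_length: int = 1_000_000
    split_ab_my: float = 5.0
    split_abc_my: float = 15.0
    max_age_my: float = 20.0
    n_call: int = 300
    n_sag: int = 300
    n_ls_a: int = 450
    n_ls_b: int = 450
    n_ls_c: int = 100
    n_parallel: int = 0          # LS-A / LS-C near-parallel insertion pairs at one site
    mutation_rate: float = ELEMENT_DECAY_RATE
    background_mutation_rate: float = 0.0025
    ls_age_mean_my: float = 2.0  # recency of the burst: truncated-exponential mean
    tsd_length_range: tuple[int, int] = (8, 16)
    atail_geometric_mean: float = 15.0
    atail_long_fraction_a: float = 0.023   # heavy-tail mixture weight, lineage A only
    atail_long_range: tuple[int, int] = (50, 165)
    background_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    min_spacing: int = 200
    edge_margin: int = 600
    n_contigs: int = 1
    mutate_tails: bool = False
    pol3_terminator: bool = False
    max_placement_retries: int = 200

    def validate(self) -> None:
        counts = (self.n_call, self.n_sag, self.n_ls_a, self.n_ls_b,
                  self.n_ls_c, self.n_parallel)
        if any(c < 0 for c in counts):
            raise ValueError("insertion counts must be >= 0")
        if self.mutation_rate <= 0:
            raise ValueError("mutation_rate must be > 0")
        if not 0 < self.split_ab_my < self.split_abc_my < self.max_age_my:
            raise ValueError("require 0 < split_ab < split_abc < max_age")
        # ~140 bp footprint per insertion; inserted bases must stay under half
        # the genome so flanks remain mostly background.
        n_per_genome = self.n_call + self.n_sag + max(self.n_ls_a, self.n_ls_b,
                                                      self.n_ls_c) + self.n_parallel
        if n_per_genome * 140 > 0.5 * self.genome_length:
            raise ValueError("genome_length too small for requested insertion counts")


Edit = tuple  # ("sub", pos, base) | ("ins", pos, seq) | ("del", pos, length)


@dataclass(frozen=True)
class SubfamilyModel:
    """A subfamily consensus plus its derivation from a parent consensus.

    ``diagnostic_edits`` are positions on the *parent* consensus; applying them
    (right to left) to the parent reproduces ``consensus`` exactly.
    ``active_interval`` is the age window (my) in which the subfamily spawns
    new copies; ``branch`` restricts it to a side of the tree ("saguinus" for
    the sister-pair side, "any" otherwise).
    """

    name: str
    parent: str | None
    consensus: str
    diagnostic_edits: tuple[Edit, ...] = ()
    active_interval: tuple[float, float] = (0.0, 25.0)
    branch: str = "any"


@dataclass
class ConsensusLibrary:
    """Named subfamily consensus sequences with lineage metadata."""

    sequences: "collections.OrderedDict[str, str]"
    lineage: dict[str, str] = field(default_factory=dict)

    def names(self) -> list[str]:
        return list(self.sequences)

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def founders(self) -> "collections.OrderedDict[str, str]":
        """Subfamilies with no parent in the library ('publicly known' set)."""
        return collections.OrderedDict(
            (n, s) for n, s in self.sequences.items() if self.lineage.get(n) is None
        )

    def write(self, path) -> None:
        write_fasta(dict(self.sequences), path)


@dataclass
class Insertion:
    id: str
    subfamily: str
    sharing_class: str
    age_my: float
    n_sub: int
    strand: str
    tsd: str
    atail: str
    anc_pos: int
    element_seq: str
    parallel_site: int = -1


@dataclass
class TrioResult:
    genomes: dict[str, dict[str, str]]   # tip -> {contig: seq}
    manifest: pd.DataFrame
    library: ConsensusLibrary
    models: list[SubfamilyModel]
    config: SimConfig

    def write(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for tip, contigs in self.genomes.items():
            write_fasta(contigs, out / f"genome_{tip}.fa")
        self.library.write(out / "library.fa")
        write_manifest(self.manifest, out / "manifest.tsv")


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"tsd": str})


# ---------------------------------------------------------------------------
# consensus library construction

def apply_edits(parent_seq: str, edits: tuple[Edit, ...]) -> str:
    """Apply diagnostic edits (positions on the parent) right-to-left."""
    seq = list(parent_seq)
    for edit in sorted(edits, key=lambda e: e[1], reverse=True):
        kind, pos = edit[0], edit[1]
        if not 0 <= pos <= len(parent_seq) - (1 if kind != "ins" else 0):
            raise ValueError(f"edit position {pos} outside parent length {len(parent_seq)}")
        if kind == "sub":
            seq[pos] = edit[2]
        elif kind == "ins":
            seq[pos:pos] = list(edit[2])
        elif kind == "del":
            k = edit[2]
            if pos + k > len(parent_seq):
                raise ValueError(f"deletion [{pos},{pos + k}) outside parent length")
            del seq[pos:pos + k]
        else:
            raise ValueError(f"unknown edit kind {kind!r}")
    return "".join(seq)


def default_derivation_plan(rng: np.random.Generator, founder: str) -> list[dict]:
    """Founder -> a -> b -> c ladder with substitution and indel diagnostics.

    The youngest subfamily carries a 9 bp insertion on top of a 5 bp deletion
    inherited from its immediate precursor -- the indel signature that makes
    derived copies unambiguous.  Edit positions stay >= 10 bp from either end
    so the library scan's full-length filter is unaffected.
    """
    n = len(founder)
    positions = rng.choice(np.arange(10, n - 12), size=10, replace=False)
    positions = iter(sorted(int(p) for p in positions))

    def subs(seq: str, k: int) -> tuple[Edit, ...]:
        out = []
        for _ in range(k):
            p = next(positions)
            old = seq[p]
            new = "ACGT"[("ACGT".index(old) + int(rng.integers(1, 4))) % 4]
            out.append(("sub", p, new))
        return tuple(out)

    plan = []
    founder_seq = founder
    edits_a = subs(founder_seq, 3)
    seq_a = apply_edits(founder_seq, edits_a)
    plan.append(dict(name_suffix="a", parent_is_founder=True, edits=edits_a,
                     active_interval=(10.0, 15.0), branch="saguinus"))
    del_pos = next(positions)
    edits_b = subs(seq_a, 2) + (("del", del_pos, 5),)
    plan.append(dict(name_suffix="b", parent_is_founder=False, parent_suffix="a",
                     edits=edits_b, active_interval=(5.0, 10.0), branch="saguinus"))
    seq_b = apply_edits(seq_a, edits_b)
    ins_pos = min(next(positions), len(seq_b) - 10)
    ins_seq = random_seq(rng, 9)
    edits_c = (("ins", ins_pos, ins_seq),) + tuple(
        ("sub", p, b) for (_, p, b) in subs(seq_b, 2)
    )
    plan.append(dict(name_suffix="c", parent_is_founder=False, parent_suffix="b",
                     edits=edits_c, active_interval=(0.0, 5.0), branch="saguinus"))
    return plan


def make_founder_library(seed: int, n_subfamilies: int = 4,
                         derivation_plan: list[dict] | None = None,
                         founder_length: int = 100,
                         ) -> tuple[ConsensusLibrary, list[SubfamilyModel]]:
    """Generate a founder consensus plus derived subfamily consensuses.

    The founder is random background sequence except for a fixed ``gggg``
    5' start (a hallmark of the real element head, handy when eyeballing
    alignments).  ``derivation_plan`` is a parent->child list of dicts with
    keys ``name_suffix``, ``parent_suffix`` (or ``parent_is_founder``),
    ``edits``, ``active_interval``, ``branch``; when None, a default
    founder -> a -> b -> c ladder is built (n_subfamilies consensuses total).
    """
    if n_subfamilies < 1:
        raise ValueError("n_subfamilies must be >= 1")
    rng = np.random.default_rng(seed)
    founder_name = "SbSINE1"
    founder = "GGGG" + random_seq(rng, founder_length - 4)
    if not 80 <= len(founder) <= 120:
        raise ValueError("founder consensus length must be in [80, 120] bp")
    if derivation_plan is None:
        derivation_plan = default_derivation_plan(rng, founder)[: n_subfamilies - 1]

    models = [SubfamilyModel(name=founder_name, parent=None, consensus=founder,
                             active_interval=(0.0, 25.0), branch="any")]
    by_suffix: dict[str, SubfamilyModel] = {}
    pending = list(derivation_plan)
    guard = 0
    while pending:
        guard += 1
        if guard > 10 * len(derivation_plan) + 10:
            raise ValueError("cyclic or unsatisfiable derivation plan")
        entry = pending.pop(0)
        suffix = entry["name_suffix"]
        if suffix in by_suffix:
            raise ValueError(f"duplicate subfamily suffix {suffix!r}")
        if entry.get("parent_is_founder"):
            parent = models[0]
        else:
            parent_suffix = entry.get("parent_suffix")
            if parent_suffix == suffix:
                raise ValueError("derivation plan contains a self-loop")
            if parent_suffix not in by_suffix:
                pending.append(entry)  # parent not built yet; retry later
                continue
            parent = by_suffix[parent_suffix]
        consensus = apply_edits(parent.consensus, tuple(entry["edits"]))
        if not 80 <= len(consensus) <= 120:
            raise ValueError(f"derived consensus {suffix!r} length outside [80, 120] bp")
        model = SubfamilyModel(
            name=f"{founder_name}{suffix}",
            parent=parent.name,
            consensus=consensus,
            diagnostic_edits=tuple(entry["edits"]),
            active_interval=tuple(entry.get("active_interval", (0.0, 25.0))),
            branch=entry.get("branch", "any"),
        )
        models.append(model)
        by_suffix[suffix] = model

    sequences = collections.OrderedDict((m.name, m.consensus) for m in models)
    lineage = {m.name: m.parent for m in models}
    return ConsensusLibrary(sequences=sequences, lineage=lineage), models


# ---------------------------------------------------------------------------
# mutation model

def mutate_sequence(seq: str, age_my: float, rate: float,
                    seed: int | np.random.Generator = 0) -> str:
    """Substitute each base independently with prob min(1, age x rate).

    A substituted base becomes one of the three other bases, uniformly.
    Deterministic under ``seed`` (an int or a Generator).
    """
    mutated, _ = _mutate_counted(seq, age_my, rate, seed)
    return mutated


def _mutate_counted(seq: str, age_my: float, rate: float,
                    seed: int | np.random.Generator) -> tuple[str, int]:
    if age_my < 0 or rate < 0:
        raise ValueError("age and rate must be >= 0")
    if not seq:
        return "", 0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = min(1.0, age_my * rate)
    codes = encode(seq)
    hit = rng.random(len(codes)) < p
    n = int(hit.sum())
    if n:
        shift = rng.integers(1, 4, size=n).astype(np.uint8)
        codes[hit] = (codes[hit] + shift) % 4
    return decode(codes), n


# ---------------------------------------------------------------------------
# trio simulation

def _draw_age(rng: np.random.Generator, cls: str, cfg: SimConfig) -> float:
    if cls.startswith("LS"):
        hi = cfg.split_ab_my if cls in ("LS-A", "LS-B") else cfg.split_abc_my
        # truncated exponential: the burst is recent, so young ages dominate
        while True:
            a = float(rng.exponential(cfg.ls_age_mean_my))
            if a < hi:
                return a
    if cls == "Sag":
        return float(rng.uniform(cfg.split_ab_my, cfg.split_abc_my))
    return float(rng.uniform(cfg.split_abc_my, cfg.max_age_my))


def _pick_subfamily(rng: np.random.Generator, models: list[SubfamilyModel],
                    cls: str, age: float) -> SubfamilyModel:
    on_saguinus = cls in ("Sag", "LS-A", "LS-B")
    eligible = []
    for m in models:
        lo, hi = m.active_interval
        if not lo <= age < hi:
            continue
        if m.branch == "saguinus" and not on_saguinus:
            continue
        eligible.append(m)
    if not eligible:
        raise ValueError(f"no subfamily active for class {cls} at age {age:.2f} my")
    # narrowest activity window wins: derived subfamilies out-compete founders
    eligible.sort(key=lambda m: (m.active_interval[1] - m.active_interval[0], m.name))
    return eligible[0]


def _draw_atail(rng: np.random.Generator, cls: str, cfg: SimConfig) -> int:
    if cls == "LS-A" and rng.random() < cfg.atail_long_fraction_a:
        lo, hi = cfg.atail_long_range
        return int(rng.integers(lo, hi + 1))
    return int(rng.geometric(1.0 / cfg.atail_geometric_mean))


def _place_sites(rng: np.random.Generator, n: int, cfg: SimConfig) -> list[int]:
    """Uniform sites with pairwise spacing >= min_spacing.

    Sorted uniforms are drawn over the range shrunk by the total spacing
    budget, then the budget is re-inserted cumulatively; duplicates in the
    shrunk draw (which would collapse spacing to exactly min_spacing - 0) are
    re-drawn a bounded number of times.
    """
    if n == 0:
        return []
    lo, hi = cfg.edge_margin, cfg.genome_length - cfg.edge_margin
    budget = (n - 1) * cfg.min_spacing
    if hi - lo <= budget:
        raise RuntimeError("could not place insertions without overlap; "
                           "increase genome_length or lower counts")
    for _ in range(cfg.max_placement_retries):
        base = np.sort(rng.integers(lo, hi - budget, size=n))
        sites = base + np.arange(n) * cfg.min_spacing
        if n < 2 or np.diff(sites).min() >= cfg.min_spacing:
            return [int(s) for s in sites]
    raise RuntimeError("could not place insertions without overlap; "
                       "increase genome_length or lower counts")


def _evolve_background(rng: np.random.Generator, codes: np.ndarray,
                       branch_my: float, rate: float) -> np.ndarray:
    p = min(1.0, branch_my * rate)
    out = codes.copy()
    hit = rng.random(len(out)) < p
    n = int(hit.sum())
    if n:
        shift = rng.integers(1, 4, size=n).astype(np.uint8)
        out[hit] = (out[hit] + shift) % 4
    return out


def simulate_trio(config: SimConfig,
                  library_models: tuple[ConsensusLibrary, list[SubfamilyModel]] | None = None,
                  ) -> TrioResult:
    """Simulate the 3-taxon genome trio with planted insertions and manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    if library_models is None:
        library_models = make_founder_library(int(rng.integers(0, 2**31)))
    library, models = library_models

    # ancestral (root) background
    anc = random_seq(rng, config.genome_length, config.background_freqs)
    anc_codes = encode(anc)

    # draw insertions on ancestral coordinates
    class_counts = [("Call", config.n_call), ("Sag", config.n_sag),
                    ("LS-A", config.n_ls_a), ("LS-B", config.n_ls_b),
                    ("LS-C", config.n_ls_c)]
    classes = [c for c, n in class_counts for _ in range(n)]
    n_sites = len(classes) + config.n_parallel
    sites = _place_sites(rng, n_sites, config)

    insertions: list[Insertion] = []
    for i, cls in enumerate(classes):
        insertions.append(_make_insertion(rng, f"ins{i:05d}", cls, sites[i],
                                          anc, config, models))
    # near-parallel pairs: an LS-A and an LS-C insertion at the same ancestral
    # site (different subfamilies), emulating independent integration events
    for j in range(config.n_parallel):
        site = sites[len(classes) + j]
        ia = _make_insertion(rng, f"par{j:03d}A", "LS-A", site, anc, config, models)
        ic = _make_insertion(rng, f"par{j:03d}C", "LS-C", site, anc, config, models)
        ia.parallel_site = site
        ic.parallel_site = site
        insertions.extend([ia, ic])

    # evolve background along the tree
    rate = config.background_mutation_rate
    ab_codes = _evolve_background(rng, anc_codes, config.split_abc_my - config.split_ab_my, rate)
    tips = {
        "A": _evolve_background(rng, ab_codes, config.split_ab_my, rate),
        "B": _evolve_background(rng, ab_codes, config.split_ab_my, rate),
        "C": _evolve_background(rng, anc_codes, config.split_abc_my, rate),
    }

    genomes: dict[str, dict[str, str]] = {}
    coords: dict[str, dict[str, tuple[int, int]]] = {i.id: {} for i in insertions}
    for tip, bg_codes in tips.items():
        seq, tip_coords = _assemble_tip(tip, bg_codes, anc, insertions, config)
        for ins_id, (s, e) in tip_coords.items():
            coords[ins_id][tip] = (s, e)
        genomes[tip] = _split_contigs(rng, tip, seq, tip_coords, config, coords)

    rows = []
    for ins in insertions:
        row = dict(id=ins.id, subfamily=ins.subfamily, sharing_class=ins.sharing_class,
                   age_my=round(ins.age_my, 4), n_sub=ins.n_sub, strand=ins.strand,
                   tsd=ins.tsd, atail_length=len(ins.atail), anc_pos=ins.anc_pos,
                   parallel_site=ins.parallel_site)
        for tip in ("A", "B", "C"):
            if tip in coords[ins.id]:
                contig, s, e = coords[ins.id][tip]
                row[f"{tip}_contig"], row[f"{tip}_start"], row[f"{tip}_end"] = contig, s, e
            else:
                row[f"{tip}_contig"], row[f"{tip}_start"], row[f"{tip}_end"] = "", -1, -1
        rows.append(row)
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return TrioResult(genomes=genomes, manifest=manifest, library=library,
                      models=models, config=config)


def _make_insertion(rng, ins_id, cls, site, anc, config, models) -> Insertion:
    age = _draw_age(rng, cls, config)
    model = _pick_subfamily(rng, models, cls, age)
    element, n_sub = _mutate_counted(model.consensus, age, config.mutation_rate, rng)
    tsd_len = int(rng.integers(config.tsd_length_range[0], config.tsd_length_range[1] + 1))
    tsd = anc[site:site + tsd_len]
    atail_len = _draw_atail(rng, cls, config)
    atail = "A" * atail_len
    if config.mutate_tails:
        atail = mutate_sequence(atail, age, config.mutation_rate, rng)
    return Insertion(id=ins_id, subfamily=model.name, sharing_class=cls,
                     age_my=age, n_sub=n_sub, strand="+", tsd=tsd, atail=atail,
                     anc_pos=site, element_seq=element)


def _assemble_tip(tip: str, bg_codes: np.ndarray, anc: str,
                  insertions: list[Insertion], config: SimConfig,
                  ) -> tuple[str, dict[str, tuple[int, int]]]:
    """Insert carried elements into the tip background, left to right."""
    carried = sorted((i for i in insertions if tip in _CARRIERS[i.sharing_class]),
                     key=lambda i: i.anc_pos)
    bg = decode(bg_codes)
    parts: list[str] = []
    tip_coords: dict[str, tuple[int, int]] = {}
    prev = 0
    offset = 0
    for ins in carried:
        p, t = ins.anc_pos, len(ins.tsd)
        parts.append(bg[prev:p])
        parts.append(ins.tsd)                      # left TSD: pristine site copy
        elem_start = p + t + offset
        parts.append(ins.element_seq)
        parts.append(ins.atail)
        parts.append(ins.tsd)                      # right TSD copy
        tip_coords[ins.id] = (elem_start, elem_start + len(ins.element_seq))
        if config.pol3_terminator:
            # overwrite 4 bg bases, 21 bp downstream of the right TSD
            term_at = p + t + 21
            bg = bg[:term_at] + "TTTT" + bg[term_at + 4:]
        offset += len(ins.element_seq) + len(ins.atail) + t
        prev = p + t
    parts.append(bg[prev:])
    return "".join(parts), tip_coords


def _split_contigs(rng, tip: str, seq: str,
                   tip_coords: dict[str, tuple[int, int]], config: SimConfig,
                   coords_out: dict[str, dict],
                   ) -> dict[str, str]:
    """Split the assembled tip sequence into contigs; remap coordinates.

    Cut points avoid element+tail+TSD footprints so manifest element
    coordinates stay valid; flanks may still be truncated at contig edges,
    emulating a scaffold-level assembly.
    """
    n = config.n_contigs
    if n <= 1:
        for ins_id, (s, e) in tip_coords.items():
            coords_out[ins_id][tip] = (f"{tip}_chr1", s, e)
        return {f"{tip}_chr1": seq}
    protected = sorted((s - 20, e + 220) for s, e in tip_coords.values())
    cuts: list[int] = []
    tries = 0
    while len(cuts) < n - 1 and tries < 1000:
        tries += 1
        c = int(rng.integers(1000, len(seq) - 1000))
        if any(lo <= c < hi for lo, hi in protected) or c in cuts:
            continue
        cuts.append(c)
    bounds = [0] + sorted(cuts) + [len(seq)]
    contigs = {}
    for i in range(len(bounds) - 1):
        contigs[f"{tip}_ctg{i + 1}"] = seq[bounds[i]:bounds[i + 1]]
    for ins_id, (s, e) in tip_coords.items():
        for i in range(len(bounds) - 1):
            if bounds[i] <= s < bounds[i + 1]:
                coords_out[ins_id][tip] = (f"{tip}_ctg{i + 1}", s - bounds[i], e - bounds[i])
                break
    return contigs
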