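# Methods

`sineburst` implements a desk-scale version of the workflow used to
characterize a burst of SINE retroposition in a clade of three genomes: a
sister pair of species (split ~5 million years ago, "my") and an outgroup
(split ~15 my). Every stage that would normally consume multi-gigabyte
assemblies and external annotation binaries runs here against seeded
synthetic trios with exact ground truth, so each stage is testable end to
end.

## The simulator (`simgen`)

### Insertion model

Each planted insertion is a target-primed reverse transcription (TPRT)
product: `TSD + element + poly(A) tail + TSD copy`, where the target-site
duplication (TSD, uniform 8–16 bp) is copied from the ancestral background at
the insertion point. Insertions belong to one of five sharing classes —
shared by all three genomes (`Call`), shared by the sister pair (`Sag`), or
specific to one tip (`LS-A/B/C`) — with ages drawn consistently with the
species tree: `Call` in (15, 20] my, `Sag` uniform on (5, 15) my, and `LS`
from a truncated exponential (mean 2 my) on [0, 5) my.

The exponential `LS` age mixture encodes the system's defining feature: the
burst is ongoing, so young copies dominate. With the element decay clock
(below), this puts roughly two-thirds or more of lineage-specific elements
under 2% divergence, the regime the pipeline is meant to resolve. A uniform
age draw would not reproduce that concentration.

### Mutation model

Element bodies decay at the SINE-specific clock of **0.006024
substitutions/bp/my**; a copy of age `a` receives `Binomial(L, a × rate)`
substitutions, each to a uniformly chosen different base. The draw happens
*once* per insertion and the identical mutated copy is planted in every
carrier genome. This makes the truth manifest exact — stripping TSD and tail
from the recorded coordinates recovers a sequence whose Hamming distance to
the subfamily consensus equals the recorded draw — at the cost of ignoring
post-speciation divergence between orthologous copies. TSDs and A-tails are
likewise exempt from substitution by default (a `mutate_tails` flag restores
realism at the cost of exact tail accounting).

Flanking background instead evolves along the tree branches at a separate
neutral rate, default **0.0025 substitutions/bp/my**. The element decay clock
is not appropriate for neutral genomic background: applied over the 15-my
root depth it would imply ~18% flank divergence between a tip and the
outgroup, whereas real New World monkey assemblies differ by roughly 7–8%
genome-wide — the regime in which flank-anchored presence/absence calling
actually operates. The default background rate reproduces that (~7.5%
tip–outgroup, ~2.5% within the sister pair). Background evolution is
substitution-only (no indels), which keeps orthologous coordinates exactly
derivable.

### Subfamily ladder

The default consensus library is a founder (~100 bp, random under the
background composition, with a fixed `GGGG` 5' head as a recognizable
landmark) plus a derivation ladder founder → a → b → c: `a` adds 3
diagnostic substitutions, `b` adds 2 substitutions and a **5 bp deletion**,
`c` adds 2 substitutions and a **9 bp insertion**. Indel diagnostics are
first-class because they are the strongest signature separating derived
subfamilies in this element family. Activity windows place `c` on the tips
(ages < 5 my), `a`/`b` on the sister-pair stem, and the founder everywhere
else, so lineage-specific insertions descend (almost) exclusively from the
youngest subfamily — the concentration the discovery stage must recover.
Edit positions are kept ≥ 10 bp from the consensus termini so the
full-length filter is not confounded.

### A-tails

Tail lengths are geometric (mean 15 bp), with a small heavy-tail mixture
(weight 0.023, uniform 50–165 bp) in lineage A only, mirroring the empirical
situation where one lineage carries dozens of 50–165 bp homopolymeric tails
— a marker of very recent, mobilization-competent copies.

### What the simulator does not emulate

No background indels, no within-species polymorphism, no CpG
hypermutability, no L1 machinery or competing element families (an optional
decoy mechanism is out of scope), no chromosome structure. Shared copies are
identical across genomes rather than independently decayed. Passing tests
therefore demonstrate correctness of the *pipeline logic* under controlled
conditions, not calibrated performance on real assemblies.

## Library scanning (`libscan`)

Seed-and-extend: exact 12-mers of each consensus are looked up in a per-contig
index, clustered by diagonal (tolerance 15 bp), and each candidate window is
scored with an exact affine Smith–Waterman alignment (match +2, mismatch −3,
gap open −5, gap extend −1; a gap of length L costs 5 + (L−1)). Both strands
are scanned; overlapping hits from different subfamilies resolve best-score
first (ties: lexicographic subfamily name) when overlap exceeds 50% of the
shorter hit. Percent divergence is mismatches plus indel events per aligned
consensus position × 100; the A-tail lies outside the consensus and never
enters the alignment.

The full-length filter keeps hits with `consensus_start ≤ 4` and
`consensus_end ≥ 103` (0-based half-open). For consensuses shorter than
~105 bp the end bound falls back to `length − 2`, and explicit per-subfamily
overrides take precedence — short subfamilies would otherwise be
categorically excluded.

Known behavior: optimal local alignment trims terminal mismatches, so old
copies (≥ 15 my, ~9–12% diverged) occasionally lose > 4 leading consensus
positions and fail the filter (~7% of the oldest class at default scale).
This is inherent to the filter definition plus scoring, not a recall bug; the
evaluation reports per-class ascertainment separately from classification
accuracy.

## Presence/absence calling (`orthocall`)

Each full-length element plus up to 500 bp of each flank forms a locus query.
The query is located in a target genome by 12-mer seeding (low-complexity
k-mers and k-mers occurring > 50 times are masked, as BLAT masks
over-represented tiles; ≥ 3 seeded positions are required) and diagonal
chaining, then path-aligned within the best window by edlib.

The presence decision rests on *flank anchor geometry*, not on the raw
unaligned runs of the chain: a unit-cost aligner shreds a long gap around
chance matches, so each flank is instead aligned independently into the
window. The 3' flank's head (the tail's A-run plus up to one TSD) is skipped
before anchoring, since it has no counterpart at an empty site. A flank
anchors when ≥ 100 of its columns align and its *best window* of 100 aligned
columns reaches 80% identity — windowed, because a differential neighboring
insertion elsewhere in the flank otherwise dilutes a genuine anchor; 80% over
100 columns is unreachable for unrelated sequence.

With both flanks anchored, the target-side distance `g` between the anchors
yields the query-side unaligned span `observed = element + tail + TSD − g`:

* **absent** when `observed` falls within `[expected_gap − tolerance,
  element + max_tail + 2×TSD]` (defaults: floor 45 bp, ceiling ~300 bp for a
  100 bp element) — the classic ~85 bp empty-site gap, widened for tails;
* **present** when ≥ 80% of the element body aligns between the anchors at
  ≥ 95% identity with ≤ 20 bp of target-side hole. The high identity bar is
  the near-parallel-insertion guard: an independent insertion of a sister
  subfamily at the same site (planted by `n_parallel`) aligns at ~90% and is
  deliberately pushed to review rather than called shared by descent;
* **ambiguous** otherwise — an explicit state written to a review queue,
  replacing manual alignment inspection.

Specificity rolls the two calls up: from a sister-pair genome,
absent/absent → LS, present(sister)/absent(outgroup) → Sag,
present/present → Call; any ambiguous input flags the locus for review with
class `other`. Both flanks are required by default (`single_flank_ok`
relaxes).

## Subfamily discovery (`subfam`)

Elements are globally aligned (affine gaps, same scoring) into consensus
coordinates: one column per consensus position ('-' for deletions) plus
insertion events keyed by anchor column. Affine gaps matter here too — they
keep the 9 bp insertion one event. Exact matches to the consensus are
flagged; rows under 50% identity (matched columns / consensus length) are
excluded.

Discovery is greedy co-segregation: among all deviations from the current
node's consensus, the best-supported one (ties: leftmost) seeds a candidate;
the candidate's diagnostic set is every deviation carried by ≥ 80% of its
carriers; a split requires ≥ 2 diagnostics and ≥ 10 members (a deliberately
small floor for simulation scale; ~50 is the classic genome-scale default).
Members get a majority-rule consensus (ties → parent state; insertion events
at > 50% support) and both partitions recurse, up to 10 rounds. Discovered
subfamilies are auto-named with letter suffixes in discovery order. This
omits the significance testing a full co-segregation engine performs;
at the planted effect sizes (≥ 2 co-segregating sites at ≥ 80% purity)
independent noise cannot mimic a subfamily, which the noise-only test
verifies.

Reassignment rescoring uses the scan aligner. An element moves to the best
candidate iff neither its score nor its divergence worsens and at least one
strictly improves (`improvement_rule="either"` relaxes to a single strict
improvement); a candidate is retained iff it gains ≥ 1 member. Consensuses
identical to the parent can never strictly improve and are thereby
eliminated automatically.

## Tree building (`njtree`)

Pairwise p-distances (mismatches + gap events over aligned columns) from
global alignments feed a hand-written Saitou–Nei neighbor-joining with
deterministic tie-breaking (lexicographically smallest joined pair, tracked
by the smallest leaf name per subtree) and negative branch lengths clamped
to zero with a warning. On additive matrices the output path-length matrix
reproduces the input to < 1e-9. The Newick leaf order is the documented
stacking order for the divergence histograms. Full multiple alignment before
tree building is unnecessary at ~100 bp consensus length; topology near very
short internal branches is inherently unstable and is not treated as a
strong output surface.

## Summaries (`summarize`)

* **A-tails**: the tail region runs from the element's 3' end to the 3' TSD;
  the statistic is the longest run of consecutive A's in it, "pristine" when
  the run spans the whole region. The pipeline approximates the region by
  scanning consecutive A's from the annotation end (exact under the default
  no-tail-mutation model; leading A's of the TSD extend the run, which the
  tests account for).
* **Ages**: `age = (pct_div/100) / 0.006024`, reported to 2 decimals; 2% ↔
  3.32 my, 7% ↔ 11.62 my. At ~100 bp one substitution is already 1%
  (~1.66 my), so ages are coarse by construction. The conventional "young"
  cutoff of 2% is kept as a parameter with that caveat.
* **Bins**: per-subfamily stacked counts over 1%-wide divergence bins
  (0–25%), stacked in tree order, with an explicit `unassigned` stratum so
  nothing is dropped silently.
* **Percentages**: per-class assignment tables round half-up to 2 decimals
  with the class total as denominator; a zero denominator reports an empty
  cell rather than NaN.

## Pipeline and evaluation

`run_all` chains the stages under one seed and one run directory; stage TSVs
are byte-identical across reruns of the same seed (the wall-time log is the
only exception). The scan stage deliberately uses only the *founder* subset
of the library — derived subfamilies are what discovery must find.

`evaluate_against_truth` reports two separate surfaces: **ascertainment**
(manifest insertions recovered as full-length loci, per class — bounded by
the full-length filter behavior noted above) and **classification
precision/recall** per class over classified loci, plus the
youngest-subfamily assignment fraction, coordinate-error maxima, and the
review status of planted near-parallel sites.

### Problem sizes

The default study conditions are three ~1 Mb genomes with 300 `Call`, 300
`Sag`, 450 `LS` per tamarin tip, 100 marmoset-specific insertions (~1,600
total), running end to end in about a minute on one CPU. Module tests use
smaller trios (~120 kb, ~110 insertions). `scripts/acceptance.py` runs the
default conditions under the given seed and recomputes the headline
quantities from scratch.

## Known limitations

* Shared copies being identical across genomes makes present-calls easier
  than in real data; the 95% element-identity bar would need lowering for
  genuinely diverged orthologs.
* The co-segregation splitter has no statistical test; very small or
  low-purity subfamilies below the configured floors are invisible.
* Percent divergence depends on local alignment extent; terminal trimming
  biases it slightly downward for old elements.
* The pipeline's tail-region heuristic undercounts interrupted tails when
  `mutate_tails` is enabled; only the manifest-based accounting is exact in
  that mode.
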