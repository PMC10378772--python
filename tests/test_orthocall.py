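import numpy as np
import pytest

from sineburst import orthocall
from sineburst._seq import random_seq, revcomp
from sineburst.libscan import Annotation
from sineburst.orthocall import GenomeIndex, OrthologyParams, PresenceCall


def _annotation(contig="c1", start=600, end=705, strand="+"):
    return Annotation(genome_id="g", contig=contig, start=start, end=end,
                      strand=strand, subfamily="s", consensus_start=0,
                      consensus_end=end - start, sw_score=200.0, pct_div=0.0)


class TestExtractLocus:
    def test_flank_coordinates(self):
        rng = np.random.default_rng(0)
        genome = {"c1": random_seq(rng, 10_000)}
        locus = orthocall.extract_locus(genome, _annotation(start=600, end=705))
        assert locus.flank5 == genome["c1"][100:600]
        assert locus.flank3 == genome["c1"][705:1205]
        assert locus.element == genome["c1"][600:705]
        assert len(locus.query) == len(locus.flank5) + 105 + len(locus.flank3)
        assert not locus.flank5_truncated and not locus.flank3_truncated

    def test_truncated_flank_flagged(self):
        rng = np.random.default_rng(1)
        genome = {"c1": random_seq(rng, 5_000)}
        locus = orthocall.extract_locus(genome, _annotation(start=200, end=300))
        assert len(locus.flank5) == 200
        assert locus.flank5_truncated and not locus.flank3_truncated

    def test_annotation_outside_contig_rejected(self):
        genome = {"c1": "ACGT" * 100}
        with pytest.raises(ValueError, match="outside contig"):
            orthocall.extract_locus(genome, _annotation(start=300, end=500))

    def test_minus_strand_normalized(self):
        rng = np.random.default_rng(2)
        genome = {"c1": random_seq(rng, 3_000)}
        plus = orthocall.extract_locus(genome, _annotation(start=1000, end=1100))
        minus = orthocall.extract_locus(genome,
                                        _annotation(start=1000, end=1100,
                                                    strand="-"))
        assert minus.element == revcomp(plus.element)
        assert minus.flank5 == revcomp(plus.flank3)


@pytest.fixture()
def planted_pair():
    """A locus present in 'target_present' and cleanly deleted (element +
    tail + one TSD copy) in 'target_absent'."""
    rng = np.random.default_rng(3)
    bg = random_seq(rng, 4_000)
    element = random_seq(rng, 100)
    tail = "A" * 15
    tsd = bg[2000:2010]
    with_ins = bg[:2010] + element + tail + tsd + bg[2010:]
    genome = {"c1": with_ins}
    ann = Annotation(genome_id="q", contig="c1", start=2010, end=2110,
                     strand="+", subfamily="s", consensus_start=0,
                     consensus_end=100, sw_score=200.0, pct_div=0.0)
    locus = orthocall.extract_locus(genome, ann)
    return locus, {"present": {"t": with_ins}, "absent": {"t": bg}}


class TestMapLocus:
    def test_identical_target_single_block(self, planted_pair):
        locus, targets = planted_pair
        chain = orthocall.map_locus(locus, targets["present"])
        assert not chain.empty
        assert len(chain.blocks) == 1
        assert chain.blocks[0].q_end - chain.blocks[0].q_start == len(locus.query)
        assert chain.blocks[0].mismatches == 0

    def test_deleted_element_leaves_query_side_gap(self, planted_pair):
        locus, targets = planted_pair
        chain = orthocall.map_locus(locus, targets["absent"])
        assert len(chain.blocks) >= 2
        unaligned = int((chain.qstatus == 0).sum())
        # element (100) + tail (15) + TSD copy (10), +/- alignment smear
        assert abs(unaligned - 125) <= 15

    def test_unrelated_target_empty_chain(self, planted_pair):
        locus, _ = planted_pair
        rng = np.random.default_rng(99)
        chain = orthocall.map_locus(locus, {"t": random_seq(rng, 4_000)})
        assert chain.empty

    def test_minus_strand_target_found(self, planted_pair):
        locus, targets = planted_pair
        flipped = {"t": revcomp(targets["present"]["t"])}
        chain = orthocall.map_locus(locus, flipped)
        assert not chain.empty
        assert chain.strand == "-"


class TestCallPresence:
    def test_identical_locus_called_present(self, planted_pair):
        locus, targets = planted_pair
        chain = orthocall.map_locus(locus, targets["present"])
        call = orthocall.call_presence(chain, locus)
        assert call.call == "present"
        assert call.observed_gap == 0

    def test_deleted_element_called_absent(self, planted_pair):
        locus, targets = planted_pair
        chain = orthocall.map_locus(locus, targets["absent"])
        call = orthocall.call_presence(chain, locus)
        assert call.call == "absent"
        lo, hi = OrthologyParams().absent_window(len(locus.element))
        assert lo <= call.observed_gap <= hi

    def test_single_anchorable_flank_is_ambiguous(self, planted_pair):
        locus, targets = planted_pair
        # target retains only the 3' side of the locus
        full = targets["absent"]["t"]
        chain = orthocall.map_locus(locus, {"t": full[2010 - 40:]})
        call = orthocall.call_presence(chain, locus)
        assert call.call == "ambiguous"

    def test_single_flank_ok_relaxation(self, planted_pair):
        locus, targets = planted_pair
        full = targets["absent"]["t"]
        params = OrthologyParams(single_flank_ok=True)
        chain = orthocall.map_locus(locus, {"t": full[2010 - 40:]}, params)
        call = orthocall.call_presence(chain, locus, params)
        assert call.call == "absent"

    def test_different_element_at_site_not_present_by_descent(self, planted_pair):
        """An independent insertion of a diverged element at the same site
        must not be mistaken for the orthologous copy."""
        locus, targets = planted_pair
        rng = np.random.default_rng(7)
        other = list(locus.element)
        for pos in rng.choice(len(other), size=12, replace=False):
            other[pos] = "ACGT"[(("ACGT".index(other[pos])) + 1) % 4]
        bg = targets["absent"]["t"]
        parallel = bg[:2010] + "".join(other) + "A" * 20 + bg[2000:2010] + bg[2010:]
        chain = orthocall.map_locus(locus, {"t": parallel})
        call = orthocall.call_presence(chain, locus)
        assert call.call == "ambiguous"


class TestClassifySpecificity:
    ROLES = {"A": "tamarin", "B": "tamarin", "C": "marmoset"}

    def _call(self, target, state):
        return PresenceCall("locus", target, state, None, {})

    @pytest.mark.parametrize("sister,outgroup,expected", [
        ("absent", "absent", "LS"),
        ("present", "absent", "Sag"),
        ("present", "present", "Call"),
    ])
    def test_tamarin_source_mapping(self, sister, outgroup, expected):
        calls = {"B": self._call("B", sister), "C": self._call("C", outgroup)}
        sc = orthocall.classify_specificity(calls, "A", self.ROLES)
        assert sc.cls == expected
        assert not sc.needs_review

    def test_incongruent_pattern_goes_to_review(self):
        calls = {"B": self._call("B", "absent"), "C": self._call("C", "present")}
        sc = orthocall.classify_specificity(calls, "A", self.ROLES)
        assert sc.cls == "other" and sc.needs_review

    def test_ambiguous_input_goes_to_review(self):
        calls = {"B": self._call("B", "present"), "C": self._call("C", "ambiguous")}
        sc = orthocall.classify_specificity(calls, "A", self.ROLES)
        assert sc.cls == "other" and sc.needs_review

    def test_marmoset_source(self):
        calls = {"A": self._call("A", "absent"), "B": self._call("B", "absent")}
        sc = orthocall.classify_specificity(calls, "C", self.ROLES)
        assert sc.cls == "LS"

    def test_unknown_role_rejected(self):
        calls = {"B": self._call("B", "absent"), "X": self._call("X", "absent")}
        with pytest.raises(ValueError, match="unknown genome role"):
            orthocall.classify_specificity(calls, "A", self.ROLES)


class TestSimulationProperties:
    def test_near_parallel_insertions_reviewed(self, small_run):
        """Planted same-site different-subfamily insertion pairs all land in
        the review queue instead of being called shared by descent."""
        _, metrics = small_run
        reviewed, total = metrics["parallel_site_reviewed"]
        assert total > 0 and reviewed == total

    def test_reciprocity_of_call_class(self, small_run):
        """A locus shared by all three genomes classifies as Call from every
        source genome."""
        result, _ = small_run
        manifest = result.trio.manifest
        call_rows = manifest[manifest.sharing_class == "Call"]
        classes = result.classes_df
        by_tip = {tip: classes[classes.genome_id == tip] for tip in "ABC"}
        checked = consistent = 0
        for _, row in call_rows.iterrows():
            verdicts = []
            for tip in "ABC":
                sub = by_tip[tip]
                hit = sub[(sub.contig == row[f"{tip}_contig"])
                          & ((sub.start - row[f"{tip}_start"]).abs() <= 10)]
                if len(hit):
                    verdicts.append(hit.iloc[0].cls)
            if len(verdicts) == 3:
                checked += 1
                consistent += int(all(v == "Call" for v in verdicts))
        assert checked > 0
        assert consistent / checked >= 0.95
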