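import numpy as np
import pytest

from sineburst import simgen
from sineburst.simgen import SimConfig


class TestFounderLibrary:
    def test_deterministic_under_seed(self):
        lib1, models1 = simgen.make_founder_library(42)
        lib2, models2 = simgen.make_founder_library(42)
        assert lib1.sequences == lib2.sequences
        assert [m.consensus for m in models1] == [m.consensus for m in models2]

    def test_founder_head_and_lengths(self, founder_library):
        lib, models = founder_library
        assert models[0].consensus.startswith("GGGG")
        for m in models:
            assert 80 <= len(m.consensus) <= 120

    def test_edits_reproduce_consensus(self, founder_library):
        lib, models = founder_library
        by_name = {m.name: m for m in models}
        for m in models[1:]:
            parent = by_name[m.parent]
            assert simgen.apply_edits(parent.consensus, m.diagnostic_edits) \
                == m.consensus

    def test_substitution_edits_give_hamming_distance(self):
        _, models = simgen.make_founder_library(3)
        founder, child_a = models[0], models[1]
        assert len(child_a.consensus) == len(founder.consensus)
        ham = sum(x != y for x, y in zip(founder.consensus, child_a.consensus))
        assert ham == 3  # child = parent + 3 substitutions

    def test_indel_edits_appear_as_gaps_in_global_alignment(self, founder_library):
        # the youngest consensus carries a 9 bp insertion on top of a 5 bp
        # deletion inherited from its precursor; a global alignment against
        # the founder must show exactly those two gap runs
        _, models = founder_library
        founder, youngest = models[0], models[-1]
        from Bio import Align
        aligner = Align.PairwiseAligner(mode="global", match_score=2,
                                        mismatch_score=-3, open_gap_score=-5,
                                        extend_gap_score=-1)
        aln = aligner.align(founder.consensus, youngest.consensus)[0]
        t_blocks, q_blocks = aln.aligned
        gaps_in_parent = []   # child-only sequence (insertion)
        gaps_in_child = []    # parent-only sequence (deletion)
        for k in range(1, len(t_blocks)):
            t_jump = int(t_blocks[k][0] - t_blocks[k - 1][1])
            q_jump = int(q_blocks[k][0] - q_blocks[k - 1][1])
            if q_jump:
                gaps_in_parent.append(q_jump)
            if t_jump:
                gaps_in_child.append(t_jump)
        assert gaps_in_parent == [9]
        assert gaps_in_child == [5]

    def test_cyclic_plan_rejected(self):
        plan = [dict(name_suffix="a", parent_suffix="b", edits=()),
                dict(name_suffix="b", parent_suffix="a", edits=())]
        with pytest.raises(ValueError, match="cyclic|self-loop"):
            simgen.make_founder_library(0, derivation_plan=plan)

    def test_edit_outside_parent_rejected(self):
        plan = [dict(name_suffix="a", parent_is_founder=True,
                     edits=(("sub", 999, "A"),))]
        with pytest.raises(ValueError, match="outside parent"):
            simgen.make_founder_library(0, derivation_plan=plan)


class TestMutateSequence:
    def test_age_zero_is_identity(self):
        seq = "GGGGACGTACGTTTTT"
        assert simgen.mutate_sequence(seq, 0.0, 0.006024, seed=1) == seq

    def test_rate_zero_is_identity(self):
        seq = "GGGGACGTACGTTTTT"
        assert simgen.mutate_sequence(seq, 10.0, 0.0, seed=1) == seq

    def test_empty_sequence(self):
        assert simgen.mutate_sequence("", 5.0, 0.01, seed=0) == ""

    def test_substituted_fraction_matches_binomial(self):
        # 100,000 bases at age 1.66 my and the element decay clock: expected
        # fraction 0.0099998 with binomial sd sqrt(p(1-p)/n)
        rng = np.random.default_rng(0)
        from sineburst._seq import random_seq
        seq = random_seq(rng, 100_000)
        mutated = simgen.mutate_sequence(seq, 1.66, 0.006024, seed=123)
        frac = sum(a != b for a, b in zip(seq, mutated)) / len(seq)
        p = 1.66 * 0.006024
        sd = (p * (1 - p) / len(seq)) ** 0.5
        assert abs(frac - p) < 3 * sd

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        from sineburst._seq import random_seq
        seq = random_seq(rng, 500)
        assert simgen.mutate_sequence(seq, 3.0, 0.006024, seed=9) \
            == simgen.mutate_sequence(seq, 3.0, 0.006024, seed=9)


class TestSimulateTrio:
    def test_single_ls_insertion(self, founder_library):
        cfg = SimConfig(seed=3, genome_length=50_000, n_call=0, n_sag=0,
                        n_ls_a=1, n_ls_b=0, n_ls_c=0)
        trio = simgen.simulate_trio(cfg, founder_library)
        m = trio.manifest
        assert len(m) == 1
        row = m.iloc[0]
        assert row.sharing_class == "LS-A"
        assert row.A_start >= 0 and row.B_start < 0 and row.C_start < 0

    def test_class_partition_matches_config(self, small_trio):
        counts = small_trio.manifest.sharing_class.value_counts().to_dict()
        cfg = small_trio.config
        assert counts["Call"] == cfg.n_call
        assert counts["Sag"] == cfg.n_sag
        assert counts["LS-A"] == cfg.n_ls_a + cfg.n_parallel
        assert counts["LS-C"] == cfg.n_ls_c + cfg.n_parallel

    def test_manifest_genome_consistency(self, small_trio):
        """Extracting manifest coordinates recovers the element whose distance
        to its consensus equals the drawn mutation count, flanked by identical
        TSD copies around element + tail."""
        lib = small_trio.library
        for _, row in small_trio.manifest.iterrows():
            for tip in "ABC":
                if row[f"{tip}_start"] < 0:
                    continue
                g = small_trio.genomes[tip][row[f"{tip}_contig"]]
                elem = g[row[f"{tip}_start"]:row[f"{tip}_end"]]
                cons = lib[row.subfamily]
                assert len(elem) == len(cons)
                assert sum(a != b for a, b in zip(elem, cons)) == row.n_sub
                t = len(row.tsd)
                tail_end = row[f"{tip}_end"] + row.atail_length
                assert g[row[f"{tip}_start"] - t:row[f"{tip}_start"]] == row.tsd
                assert g[tail_end:tail_end + t] == row.tsd

    def test_age_zero_insertion_identical_to_consensus(self, founder_library):
        cfg = SimConfig(seed=4, genome_length=50_000, n_call=0, n_sag=0,
                        n_ls_a=5, n_ls_b=0, n_ls_c=0, ls_age_mean_my=1e-9)
        trio = simgen.simulate_trio(cfg, founder_library)
        assert (trio.manifest.n_sub == 0).all()

    def test_reproducible_under_seed(self, founder_library):
        cfg = SimConfig(seed=11, genome_length=60_000, n_call=5, n_sag=5,
                        n_ls_a=5, n_ls_b=5, n_ls_c=2)
        t1 = simgen.simulate_trio(cfg, founder_library)
        t2 = simgen.simulate_trio(cfg, founder_library)
        assert t1.genomes == t2.genomes
        assert t1.manifest.equals(t2.manifest)

    def test_genome_too_small_rejected(self, founder_library):
        cfg = SimConfig(seed=0, genome_length=20_000)
        with pytest.raises(ValueError, match="genome_length"):
            simgen.simulate_trio(cfg, founder_library)

    def test_multi_contig_coordinates_remain_exact(self, founder_library):
        cfg = SimConfig(seed=6, genome_length=150_000, n_call=10, n_sag=10,
                        n_ls_a=15, n_ls_b=15, n_ls_c=5, n_contigs=6)
        trio = simgen.simulate_trio(cfg, founder_library)
        lib = trio.library
        for tip in "ABC":
            assert len(trio.genomes[tip]) == 6
        for _, row in trio.manifest.iterrows():
            for tip in "ABC":
                if row[f"{tip}_start"] < 0:
                    continue
                g = trio.genomes[tip][row[f"{tip}_contig"]]
                elem = g[row[f"{tip}_start"]:row[f"{tip}_end"]]
                cons = lib[row.subfamily]
                assert sum(a != b for a, b in zip(elem, cons)) == row.n_sub

    def test_heavy_tail_mixture_reaches_long_tails(self, founder_library):
        cfg = SimConfig(seed=9, genome_length=400_000, n_call=0, n_sag=0,
                        n_ls_a=200, n_ls_b=0, n_ls_c=0,
                        atail_long_fraction_a=0.5)
        trio = simgen.simulate_trio(cfg, founder_library)
        tails = trio.manifest.atail_length
        assert tails.max() >= 100
        assert (tails >= 50).sum() >= 50
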