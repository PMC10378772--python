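import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import affine_local_score
from sineburst import libscan
from sineburst._align import align_stats, make_aligner
from sineburst._seq import random_seq, revcomp
from sineburst.libscan import Annotation, ScanParams

DNA = st.text(alphabet="ACGT", min_size=10, max_size=120)


class TestAlignmentOracle:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(DNA, DNA)
    def test_score_matches_bruteforce_dp(self, a, b):
        """The C aligner's local score equals an independent scalar Gotoh DP
        for all pairs up to 120 bp."""
        aligner = make_aligner(2, -3, -5, -1, mode="local")
        stats = align_stats(aligner, a, b)
        expected = affine_local_score(a, b)
        got = stats.score if stats is not None else 0.0
        assert got == expected


def _plant(rng, background_len, insert, pos):
    bg = random_seq(rng, background_len)
    return bg[:pos] + insert + bg[pos:]


class TestScanGenome:
    def test_exact_copy_recovered(self, founder_library):
        lib, _ = founder_library
        cons = lib["SbSINE1"]
        rng = np.random.default_rng(0)
        genome = {"c1": _plant(rng, 10_000, cons, 4000)}
        hits = libscan.scan_genome(genome, {"SbSINE1": cons}, genome_id="g")
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end) == (4000, 4000 + len(cons))
        assert (h.consensus_start, h.consensus_end) == (0, len(cons))
        assert h.pct_div == 0.0
        assert h.strand == "+"

    def test_two_substitutions_give_two_percent_divergence(self, founder_library):
        lib, _ = founder_library
        cons = lib["SbSINE1"]
        assert len(cons) == 100
        mutated = list(cons)
        mutated[40] = {"A": "C"}.get(mutated[40], "A")
        mutated[60] = {"A": "C"}.get(mutated[60], "A")
        mutated = "".join(mutated)
        # brute-force check on the pair itself: 2 mismatches, no gaps
        assert sum(a != b for a, b in zip(cons, mutated)) == 2
        assert affine_local_score(cons, mutated) == 2 * 98 - 3 * 2
        rng = np.random.default_rng(1234)
        genome = {"c1": _plant(rng, 10_000, mutated, 5000)}
        hits = libscan.scan_genome(genome, {"SbSINE1": cons}, genome_id="g")
        assert len(hits) == 1
        assert hits[0].pct_div == pytest.approx(2.0)

    def test_background_only_yields_no_hits(self, founder_library):
        """Empirical null: 100 random 10 kb backgrounds never reach the
        reporting threshold."""
        lib, _ = founder_library
        for seed in range(100):
            # offset from the library's seed so the streams are unrelated
            genome = {"c1": random_seq(np.random.default_rng(50_000 + seed), 10_000)}
            assert libscan.scan_genome(genome, dict(lib.founders()),
                                       genome_id="g") == []

    def test_strand_symmetry(self, founder_library):
        lib, _ = founder_library
        cons = lib["SbSINE1"]
        rng = np.random.default_rng(2)
        genome = {"c1": _plant(rng, 8_000, cons, 3000)}
        flipped = {"c1": revcomp(genome["c1"])}
        fwd = libscan.scan_genome(genome, {"SbSINE1": cons}, genome_id="g")
        rev = libscan.scan_genome(flipped, {"SbSINE1": cons}, genome_id="g")
        assert len(fwd) == len(rev) == 1
        L = len(genome["c1"])
        assert rev[0].strand == "-"
        assert (rev[0].start, rev[0].end) == (L - fwd[0].end, L - fwd[0].start)
        assert (rev[0].consensus_start, rev[0].consensus_end) == \
            (fwd[0].consensus_start, fwd[0].consensus_end)
        assert rev[0].sw_score == fwd[0].sw_score

    def test_non_acgtn_character_rejected(self, founder_library):
        lib, _ = founder_library
        with pytest.raises(ValueError, match="contig c1 at position 3"):
            libscan.scan_genome({"c1": "ACGRACGT"}, dict(lib.founders()))

    def test_recall_and_coordinates_on_simulation(self, small_trio):
        """>= 99% of manifest insertions aged <= 15 my are recovered with
        consensus-projected start error <= 2 bp."""
        lib = small_trio.library
        m = small_trio.manifest
        recovered = 0
        total = 0
        for tip in "AB":
            hits = libscan.scan_genome(small_trio.genomes[tip], lib.founders(),
                                       genome_id=tip)
            starts = {}
            for h in hits:
                starts.setdefault(h.contig, []).append(h.start - h.consensus_start)
            for _, row in m[(m[f"{tip}_start"] >= 0) & (m.age_my <= 15)].iterrows():
                total += 1
                errs = [abs(s - row[f"{tip}_start"])
                        for s in starts.get(row[f"{tip}_contig"], [])]
                if errs and min(errs) <= 2:
                    recovered += 1
        assert recovered / total >= 0.99


class TestFullLengthFilter:
    @pytest.mark.parametrize("cons_start,cons_end,expected", [
        (4, 103, True),    # boundary: at most 4 from the 5' start, end >= 103
        (5, 105, False),   # violates the 5'-start tolerance
        (0, 102, False),   # stops short of the required end
        (0, 103, True),
    ])
    def test_boundaries(self, cons_start, cons_end, expected):
        a = Annotation(genome_id="g", contig="c", start=0, end=cons_end,
                       strand="+", subfamily="s", consensus_start=cons_start,
                       consensus_end=cons_end, sw_score=200.0, pct_div=1.0)
        assert libscan.is_full_length(a, ScanParams(), 105) is expected

    def test_short_consensus_uses_relative_end(self):
        # an 82 bp consensus can never reach position 103; the effective
        # requirement falls back to (length - tolerance) unless overridden
        a = Annotation(genome_id="g", contig="c", start=0, end=82, strand="+",
                       subfamily="short", consensus_start=0, consensus_end=81,
                       sw_score=150.0, pct_div=0.0)
        assert libscan.is_full_length(a, ScanParams(), consensus_length=82)
        strict = ScanParams(min_end_overrides={"short": 103})
        assert not libscan.is_full_length(a, strict, consensus_length=82)


class TestScanOutRoundTrip:
    def _random_annotations(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            start = int(rng.integers(0, 100_000))
            end = start + int(rng.integers(50, 150))
            cs = int(rng.integers(0, 5))
            out.append(Annotation(
                genome_id="g", contig=f"ctg{int(rng.integers(1, 4))}",
                start=start, end=end, strand="+-"[int(rng.integers(0, 2))],
                subfamily=f"fam{int(rng.integers(0, 5))}",
                consensus_start=cs, consensus_end=cs + int(rng.integers(60, 100)),
                sw_score=float(rng.integers(60, 300)),
                pct_div=round(float(rng.uniform(0, 20)), 4)))
        return out

    def test_round_trip_is_lossless(self, tmp_path):
        annotations = self._random_annotations()
        path = tmp_path / "hits.tsv"
        libscan.write_scan_out(annotations, path)
        assert libscan.read_scan_out(path) == annotations

    def test_one_based_convention_on_disk(self, tmp_path):
        a = Annotation(genome_id="g", contig="c", start=10, end=115,
                       strand="+", subfamily="s", consensus_start=0,
                       consensus_end=100, sw_score=100.0, pct_div=0.0)
        path = tmp_path / "hits.tsv"
        libscan.write_scan_out([a], path)
        fields = path.read_text().splitlines()[1].split("\t")
        assert (fields[4], fields[5]) == ("11", "115")
        back = libscan.read_scan_out(path)[0]
        assert (back.start, back.end) == (10, 115)

    def test_empty_list(self, tmp_path):
        path = tmp_path / "hits.tsv"
        libscan.write_scan_out([], path)
        assert libscan.read_scan_out(path) == []

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "hits.tsv"
        libscan.write_scan_out(self._random_annotations(2), path)
        with open(path, "a") as fh:
            fh.write("garbage\tline\n")
        with pytest.raises(ValueError, match=":4:"):
            libscan.read_scan_out(path)
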