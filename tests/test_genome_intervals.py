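"""Interval core: BED I/O, overlap sweep, per-base consensus, shuffling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnapir.genome_intervals import (
    BedParseError,
    GenomeAssembly,
    GenomicInterval,
    IntervalTrack,
    consensus_intervals,
    overlap_flags,
    read_bed,
    read_chrom_sizes,
    shuffle_track,
    subseed,
    track_overlap_union,
    write_bed,
)


def _track(triples, name="t"):
    return IntervalTrack(name, sorted(GenomicInterval(*t) for t in triples), sorted=True)


def _random_track(rng, n, chroms=("chr1", "chr2"), span=1000, max_len=120, name="r"):
    ivs = []
    for _ in range(n):
        c = chroms[rng.integers(0, len(chroms))]
        s = int(rng.integers(0, span))
        ivs.append(GenomicInterval(c, s, s + int(rng.integers(1, max_len))))
    return IntervalTrack(name, sorted(ivs), sorted=True)


def brute_force_overlap(query, subject):
    """All-pairs O(n*m) overlap oracle."""
    return np.array(
        [any(q.overlaps(s) for s in subject) for q in query], dtype=bool
    )


def per_base_consensus(tracks, span=2000, chroms=("chr1", "chr2")):
    """Per-base coverage oracle: bases covered by every track, as runs."""
    out = []
    for chrom in chroms:
        covered_all = np.ones(span, dtype=bool)
        for t in tracks:
            cov = np.zeros(span, dtype=bool)
            for iv in t:
                if iv.chrom == chrom:
                    cov[iv.start : iv.end] = True
            covered_all &= cov
        # group into runs
        idx = np.flatnonzero(covered_all)
        if idx.size:
            breaks = np.flatnonzero(np.diff(idx) > 1)
            starts = np.concatenate([[idx[0]], idx[breaks + 1]])
            ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
            out += [GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)]
    return out


class TestBedIO:
    def test_parse_sorts_and_counts(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("track name=x\nchr1\t150\t250\nchr1\t100\t200\nchr2\t0\t50\n")
        t = read_bed(p)
        assert [iv for iv in t] == [
            GenomicInterval("chr1", 100, 200),
            GenomicInterval("chr1", 150, 250),
            GenomicInterval("chr2", 0, 50),
        ]
        assert t.sorted

    @pytest.mark.parametrize(
        "line", ["chr1\t200\t200", "chr1\t-5\t100", "chr1\t300\t200", "chr1\tx\t200"]
    )
    def test_malformed_coordinates_raise_with_line_number(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\n" + line + "\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(p)

    def test_dedupe_collapses_identical_rows(self, tmp_path):
        p = tmp_path / "dup.bed"
        p.write_text("chr1\t100\t200\nchr1\t100\t200\n")
        assert len(read_bed(p, dedupe=True)) == 1
        assert len(read_bed(p, dedupe=False)) == 2

    def test_unknown_chromosome_with_bound_assembly_errors(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chrZ\t0\t10\n")
        asm = GenomeAssembly("t", {"chr1": 1000})
        with pytest.raises(BedParseError, match="chrZ"):
            read_bed(p, assembly=asm)

    def test_interval_past_chromosome_end_errors(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t900\t1100\n")
        with pytest.raises(BedParseError, match="exceeds"):
            read_bed(p, assembly=GenomeAssembly("t", {"chr1": 1000}))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2", "chr10"]),
                st.integers(0, 10_000),
                st.integers(1, 500),
            ),
            min_size=0,
            max_size=40,
        )
    )
    def test_roundtrip(self, tmp_path_factory, raw):
        track = IntervalTrack(
            "t", sorted(GenomicInterval(c, s, s + l) for c, s, l in raw), sorted=True
        )
        p = tmp_path_factory.mktemp("rt") / "t.bed"
        write_bed(track, p)
        back = read_bed(p, name="t")
        assert back.intervals == track.intervals

    def test_chrom_sizes_reader(self, tmp_path):
        p = tmp_path / "g.sizes"
        p.write_text("chr1\t1000\nchr2\t500\n")
        asm = read_chrom_sizes(p, name="g")
        assert asm.size("chr1") == 1000 and asm.size("chr2") == 500
        with pytest.raises(KeyError):
            asm.size("chr3")


class TestOverlapFlags:
    def test_single_shared_base_counts(self):
        q = _track([("chr1", 100, 200)])
        assert overlap_flags(q, _track([("chr1", 199, 300)])).tolist() == [True]

    def test_half_open_abutment_does_not(self):
        q = _track([("chr1", 100, 200)])
        assert overlap_flags(q, _track([("chr1", 200, 300)])).tolist() == [False]

    def test_unsorted_input_rejected(self):
        q = IntervalTrack("q", [GenomicInterval("chr1", 0, 10)], sorted=False)
        with pytest.raises(ValueError, match="sort"):
            overlap_flags(q, _track([("chr1", 0, 5)]))

    def test_matches_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(42)
        q = _random_track(rng, 200, name="q")
        s = _random_track(rng, 300, name="s")
        got = overlap_flags(q, s)
        assert got.tolist() == brute_force_overlap(q.intervals, s.intervals).tolist()


class TestConsensus:
    def test_pairwise_intersection(self):
        c = consensus_intervals([_track([("chr1", 0, 10)]), _track([("chr1", 5, 15)])])
        assert c.intervals == [GenomicInterval("chr1", 5, 10)]

    def test_empty_track_gives_empty_consensus(self):
        c = consensus_intervals([_track([("chr1", 0, 10)]), _track([])])
        assert len(c) == 0

    def test_empty_track_list_errors(self):
        with pytest.raises(ValueError):
            consensus_intervals([])

    def test_five_random_tracks_match_per_base_oracle(self):
        rng = np.random.default_rng(3)
        tracks = [_random_track(rng, 30, span=1500, max_len=400, name=f"t{i}") for i in range(5)]
        assert consensus_intervals(tracks).intervals == per_base_consensus(tracks)

    def test_order_independent_and_monotone_shrinking(self):
        rng = np.random.default_rng(9)
        tracks = [_random_track(rng, 25, span=800, max_len=300, name=f"t{i}") for i in range(4)]
        base = consensus_intervals(tracks)
        assert consensus_intervals(tracks[::-1]).intervals == base.intervals
        cov_before = sum(iv.length for iv in consensus_intervals(tracks[:3]))
        cov_after = sum(iv.length for iv in base)
        assert cov_after <= cov_before

    def test_alternative_agreement_rule_is_superset_of_consensus_coverage(self):
        rng = np.random.default_rng(5)
        tracks = [_random_track(rng, 25, span=800, max_len=200, name=f"t{i}") for i in range(3)]
        cons = consensus_intervals(tracks)
        union_rule = track_overlap_union(tracks)
        # every consensus base lies in some agreement region
        flags = overlap_flags(cons, union_rule)
        assert flags.all()


class TestShuffle:
    ASM = GenomeAssembly("toy", {"chrA": 10_000, "chrB": 10_000})

    def test_lengths_preserved_and_in_bounds(self):
        rng = np.random.default_rng(0)
        t = _random_track(rng, 50, chroms=("chrA",), span=5000, max_len=500)
        s = shuffle_track(t, self.ASM, seed=1)
        assert sorted(iv.length for iv in s) == sorted(iv.length for iv in t)
        for iv in s:
            assert 0 <= iv.start < iv.end <= self.ASM.size(iv.chrom)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        t = _random_track(rng, 30, chroms=("chrA",), span=5000)
        assert shuffle_track(t, self.ASM, 7).intervals == shuffle_track(t, self.ASM, 7).intervals
        assert shuffle_track(t, self.ASM, 7).intervals != shuffle_track(t, self.ASM, 8).intervals

    def test_interval_filling_whole_chromosome_is_pinned(self):
        asm = GenomeAssembly("one", {"chr1": 500})
        t = _track([("chr1", 0, 500)])
        s = shuffle_track(t, asm, seed=3)
        assert s.intervals == [GenomicInterval("chr1", 0, 500)]

    def test_oversized_interval_errors(self):
        asm = GenomeAssembly("one", {"chr1": 100})
        t = IntervalTrack("t", [GenomicInterval("chr1", 0, 99)], sorted=True)
        # build a longer interval on a fake big chromosome, shuffle into small one
        big = IntervalTrack("t", [GenomicInterval("chr1", 0, 100)], sorted=True)
        shuffle_track(big, asm, 1)  # exactly fits
        too_big = IntervalTrack("t", [GenomicInterval("chrX", 0, 101)], sorted=True)
        with pytest.raises(ValueError, match="exceeds every chromosome"):
            shuffle_track(too_big, asm, 1)

    def test_chromosome_assignment_frequency_uniform(self):
        """Two equal chromosomes: placement frequency consistent with 1/2."""
        from scipy import stats

        t = _track([("chrA", 0, 100)])
        hits = sum(
            shuffle_track(t, self.ASM, seed=k).intervals[0].chrom == "chrA"
            for k in range(10_000)
        )
        p = stats.binomtest(hits, 10_000, 0.5).pvalue
        assert p > 1e-3

    def test_subseed_stable_and_bounded(self):
        assert subseed(1, 1) == subseed(1, 1)
        assert subseed(1, 1) != subseed(1, 2) != subseed(2, 1)
        assert 0 <= subseed(123456, 999) < 2**31
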