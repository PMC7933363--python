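"""Reciprocal overlap, size filtering, caller intersection, locus clustering."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from delscan.consensus import (
    cluster_loci,
    intersect_callsets,
    reciprocal_overlap,
    size_filter,
)
from delscan.core import GenomicInterval, Genotype

from conftest import make_call


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestReciprocalOverlap:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (iv(100, 200), iv(100, 200), 1.0),
            (iv(100, 200), iv(150, 250), 0.5),   # ov=50, both length 100
            (iv(100, 200), iv(300, 400), 0.0),
            (iv(100, 200), iv(100, 200, "chr2"), 0.0),
            (iv(0, 1000), iv(400, 500), 0.1),    # nested: min side dominates
        ],
    )
    def test_examples(self, a, b, expected):
        assert reciprocal_overlap(a, b) == pytest.approx(expected)

    @given(
        st.tuples(st.integers(0, 10_000), st.integers(1, 5_000)),
        st.tuples(st.integers(0, 10_000), st.integers(1, 5_000)),
    )
    @settings(max_examples=200, derandomize=True)
    def test_symmetric_and_bounded(self, p, q):
        a = iv(p[0], p[0] + p[1])
        b = iv(q[0], q[0] + q[1])
        r1, r2 = reciprocal_overlap(a, b), reciprocal_overlap(b, a)
        assert r1 == r2
        assert 0.0 <= r1 <= 1.0


class TestSizeFilter:
    def test_bounds_inclusive(self):
        calls = [make_call("chr1", 0, L) for L in (499, 500, 100_000, 100_001)]
        kept = size_filter(calls, 500, 100_000)
        assert [c.length for c in kept] == [500, 100_000]

    def test_empty_input(self):
        assert size_filter([], 500, 100_000) == []

    def test_vacuous_filter_is_identity(self):
        calls = [make_call("chr1", i * 10, i * 10 + i + 1) for i in range(1, 20)]
        assert size_filter(calls, 1, 10**9) == calls

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            size_filter([], 10, 5)


def brute_force_intersection(primary, secondary, ro_threshold):
    """All-pairs greedy matcher used as the independent oracle."""
    from fractions import Fraction

    pairs = []
    for i, p in enumerate(primary):
        for j, s in enumerate(secondary):
            if p.interval.chrom != s.interval.chrom:
                continue
            ov = max(
                0,
                min(p.interval.end, s.interval.end)
                - max(p.interval.start, s.interval.start),
            )
            if ov == 0:
                continue
            ro = min(Fraction(ov, p.interval.length), Fraction(ov, s.interval.length))
            if ro >= Fraction(ro_threshold).limit_denominator():
                pairs.append((ro, p, s, i, j))
    pairs.sort(
        key=lambda t: (
            -t[0],
            abs(t[1].interval.start - t[2].interval.start),
            t[2].interval.start,
            t[1].interval.start,
            t[1].interval.end,
            t[2].interval.end,
        )
    )
    taken_p, taken_s, matched = set(), set(), {}
    for ro, p, s, i, j in pairs:
        if i in taken_p or j in taken_s:
            continue
        taken_p.add(i)
        taken_s.add(j)
        matched[i] = float(ro)
    return matched


def random_calls(rng, n, sample="s1", caller="x"):
    calls = []
    for k in range(n):
        chrom = f"chr{rng.integers(1, 4)}"
        start = int(rng.integers(0, 200_000))
        length = int(rng.integers(500, 20_000))
        calls.append(
            make_call(chrom, start, start + length, sample, caller,
                      record_id=f"{caller}{k}")
        )
    return calls


class TestIntersectCallsets:
    def test_single_match_carries_ro_and_primary_coords(self):
        p = [make_call("chr1", 1000, 2000, caller="manta")]
        s = [make_call("chr1", 1200, 2200, caller="lumpy")]
        (c,) = intersect_callsets(p, s, 0.5)
        assert c.matched_ro == pytest.approx(0.8)
        assert c.interval == p[0].interval
        assert c.callers == ("manta", "lumpy")

    def test_below_threshold_is_empty(self):
        p = [make_call("chr1", 1000, 2000)]
        s = [make_call("chr1", 1510, 2510, caller="lumpy")]
        assert reciprocal_overlap(p[0].interval, s[0].interval) == pytest.approx(0.49)
        assert intersect_callsets(p, s, 0.5) == []

    def test_exactly_at_threshold_is_kept(self):
        p = [make_call("chr1", 1000, 2000)]
        s = [make_call("chr1", 1500, 2500, caller="lumpy")]
        assert len(intersect_callsets(p, s, 0.5)) == 1

    def test_mixed_samples_hard_error(self):
        with pytest.raises(ValueError, match="mixed sample"):
            intersect_callsets(
                [make_call("chr1", 0, 1000, sample="a")],
                [make_call("chr1", 0, 1000, sample="b")],
            )

    def test_one_to_one_consumption(self):
        # one broad secondary call may support only one primary call
        p = [make_call("chr1", 0, 1000), make_call("chr1", 900, 1900)]
        s = [make_call("chr1", 0, 1800, caller="lumpy")]
        out = intersect_callsets(p, s, 0.5)
        assert len(out) == 1

    def test_matches_brute_force_oracle(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            p = random_calls(rng, int(rng.integers(5, 120)), caller="manta")
            s = random_calls(rng, int(rng.integers(5, 120)), caller="lumpy")
            got = intersect_callsets(p, s, 0.5)
            expected = brute_force_intersection(p, s, 0.5)
            assert {(c.interval, round(c.matched_ro, 12)) for c in got} == {
                (p[i].interval, round(ro, 12)) for i, ro in expected.items()
            }

    def test_order_invariance_and_cardinality(self):
        rng = np.random.default_rng(99)
        p = random_calls(rng, 80, caller="manta")
        s = random_calls(rng, 80, caller="lumpy")
        base = intersect_callsets(p, s, 0.5)
        assert len(base) <= min(len(p), len(s))
        for seed in (1, 2):
            rng2 = np.random.default_rng(seed)
            p2 = [p[i] for i in rng2.permutation(len(p))]
            s2 = [s[i] for i in rng2.permutation(len(s))]
            assert intersect_callsets(p2, s2, 0.5) == base


def consensus_call(start, end, sample, chrom="chr1", gt=Genotype.REF_DEL):
    from delscan.consensus import ConsensusDeletion

    return ConsensusDeletion(
        GenomicInterval(chrom, start, end), sample, gt, 1.0, (".", "."),
    )


class TestClusterLoci:
    def test_identical_deletion_three_samples(self):
        calls = [consensus_call(1000, 2000, f"s{i}") for i in range(3)]
        (locus,) = cluster_loci(calls, 0.5)
        assert locus.n_members == 3
        assert locus.representative == GenomicInterval("chr1", 1000, 2000)

    def test_disjoint_deletions_make_two_loci(self):
        calls = [consensus_call(1000, 2000, "a"), consensus_call(5000, 6000, "b")]
        assert len(cluster_loci(calls, 0.5)) == 2

    def test_single_linkage_chain(self):
        # a-b and b-c linked, a-c not: still one locus via transitivity
        a = consensus_call(0, 1000, "sa")
        b = consensus_call(400, 1400, "sb")
        c = consensus_call(800, 1800, "sc")
        assert reciprocal_overlap(a.interval, c.interval) < 0.5
        (locus,) = cluster_loci([a, b, c], 0.5)
        assert set(locus.members) == {"sa", "sb", "sc"}

    def test_matches_transitive_closure_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(17)
        calls = []
        for k in range(150):
            chrom = f"chr{rng.integers(1, 3)}"
            start = int(rng.integers(0, 60_000))
            calls.append(
                consensus_call(start, start + int(rng.integers(500, 8000)),
                               f"s{rng.integers(0, 20)}", chrom)
            )
        g = nx.Graph()
        g.add_nodes_from(range(len(calls)))
        for i in range(len(calls)):
            for j in range(i + 1, len(calls)):
                if reciprocal_overlap(calls[i].interval, calls[j].interval) >= 0.5:
                    g.add_edge(i, j)
        expected_sizes = sorted(len(c) for c in nx.connected_components(g))
        loci = cluster_loci(calls, 0.5)
        got_sizes = sorted(
            sum(1 for c in calls
                if any(c.interval == ivl for ivl in l.member_intervals.values())
                and c.sample_id in l.members)
            for l in loci
        )
        assert len(loci) == len(expected_sizes)
        # partition: every call lands in exactly one locus
        total_members = sum(l.n_members for l in loci)
        distinct_pairs = len({(c.sample_id, c.interval) for c in calls})
        assert total_members <= len(calls)
        assert total_members <= distinct_pairs

    def test_allele_frequencies_with_absent_samples_as_ref(self):
        s2p = {"a": "pop1", "b": "pop1", "c": "pop2"}
        calls = [consensus_call(0, 1000, "a", gt=Genotype.DEL_DEL),
                 consensus_call(0, 1000, "c", gt=Genotype.REF_DEL)]
        (locus,) = cluster_loci(calls, 0.5, s2p)
        # pop1: b absent => 0/0; AF = 2/(2*2); pop2: AF = 1/2
        assert locus.population_af == {"pop1": 0.5, "pop2": 0.5}

    def test_missing_genotype_excluded_from_denominator(self):
        s2p = {"a": "pop1", "b": "pop1"}
        calls = [consensus_call(0, 1000, "a", gt=Genotype.REF_DEL),
                 consensus_call(0, 1000, "b", gt=Genotype.MISSING)]
        (locus,) = cluster_loci(calls, 0.5, s2p)
        assert locus.population_af == {"pop1": 0.5}

    def test_unmapped_sample_hard_error(self):
        with pytest.raises(ValueError, match="not in population map"):
            cluster_loci([consensus_call(0, 1000, "zzz")], 0.5, {"a": "p"})

    def test_median_representative_ties_toward_smaller(self):
        calls = [consensus_call(100, 1100, "a"), consensus_call(200, 1200, "b")]
        (locus,) = cluster_loci(calls, 0.5)
        assert locus.representative == GenomicInterval("chr1", 100, 1100)
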