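import numpy as np
import pytest

from lutiscan.clustering import (
    AGGREGATE,
    PERMISSIVE,
    STRICT,
    CtssPosition,
    TssCluster,
    aggregate_clusters,
    cluster_ctss,
    dominant_position,
    log2_fold_change,
    normalize_tpm,
)

from conftest import make_positions


def pos(p, tpm, chrom="chr1", strand="+", sample="s1"):
    return CtssPosition(chrom, p, strand, counts={sample: tpm}, tpm={sample: tpm})


# ---------------------------------------------------------------------------
# brute-force oracle: threshold filter, connected components, singleton rule
# ---------------------------------------------------------------------------

def oracle_cluster(positions, threshold, max_dist, remove_singletons, keep_singletons_above):
    seeds = [p for p in positions if p.pooled_tpm >= threshold]
    n = len(seeds)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = seeds[i], seeds[j]
            if (
                a.chrom == b.chrom
                and a.strand == b.strand
                and abs(a.pos - b.pos) <= max_dist
            ):
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(seeds[i])
    out = []
    for members in groups.values():
        members.sort(key=lambda m: m.pos)
        if remove_singletons and len(members) == 1:
            if sum(m.pooled_tpm for m in members) <= keep_singletons_above:
                continue
        out.append(tuple(m.pos for m in members))
    return sorted(out)


def as_member_tuples(clusters):
    return sorted(tuple(m.pos for m in c.members) for c in clusters)


class TestNormalizeTpm:
    def test_definition(self):
        positions = [
            CtssPosition("c", 1, "+", counts={"s": 10}),
            CtssPosition("c", 2, "+", counts={"s": 1e6 - 10}),
        ]
        normalize_tpm(positions)
        assert positions[0].tpm["s"] == pytest.approx(10.0)

    def test_equal_counts(self):
        positions = [CtssPosition("c", i, "+", counts={"s": 7.0}) for i in range(4)]
        normalize_tpm(positions)
        for p in positions:
            assert p.tpm["s"] == pytest.approx(2.5e5)

    def test_conservation(self, rng):
        positions = [
            CtssPosition("c", i, "+", counts={"s": float(rng.integers(1, 100))})
            for i in range(50)
        ]
        normalize_tpm(positions)
        assert sum(p.tpm["s"] for p in positions) == pytest.approx(1e6, rel=1e-6)

    def test_zero_library_errors(self):
        with pytest.raises(ValueError, match="library"):
            normalize_tpm([CtssPosition("c", 1, "+", counts={"s": 0.0})])


class TestClusterCtss:
    def test_merge_within_maxdist(self):
        clusters = cluster_ctss([pos(100, 3.0), pos(104, 2.5)], threshold=2, max_dist=5)
        assert as_member_tuples(clusters) == [(100, 104)]

    def test_split_beyond_maxdist(self):
        clusters = cluster_ctss([pos(100, 3.5), pos(106, 3.5)], threshold=2, max_dist=5)
        assert as_member_tuples(clusters) == [(100,), (106,)]

    def test_singleton_dropped_below_keep(self):
        clusters = cluster_ctss(
            [pos(50, 2.5)], threshold=2, max_dist=5,
            remove_singletons=True, keep_singletons_above=3,
        )
        assert clusters == []

    def test_singleton_kept_above(self):
        clusters = cluster_ctss(
            [pos(50, 3.5)], threshold=2, max_dist=5,
            remove_singletons=True, keep_singletons_above=3,
        )
        assert as_member_tuples(clusters) == [(50,)]

    def test_negative_maxdist_errors(self):
        with pytest.raises(ValueError):
            cluster_ctss([pos(1, 5.0)], max_dist=-1)

    @pytest.mark.parametrize("params", [STRICT, PERMISSIVE])
    def test_oracle_equivalence(self, params, rng):
        for _ in range(30):
            positions = make_positions(rng, int(rng.integers(1, 200)))
            got = cluster_ctss(positions, **params)
            want = oracle_cluster(
                positions, params["threshold"], params["max_dist"],
                params["remove_singletons"], params["keep_singletons_above"],
            )
            assert as_member_tuples(got) == want

    def test_input_order_invariance(self, rng):
        positions = make_positions(rng, 100)
        a = cluster_ctss(positions, **STRICT)
        shuffled = list(positions)
        rng.shuffle(shuffled)
        b = cluster_ctss(shuffled, **STRICT)
        assert as_member_tuples(a) == as_member_tuples(b)

    def test_strand_mirror_invariance(self, rng):
        positions = make_positions(rng, 80, max_pos=400)
        mirrored = [
            CtssPosition(p.chrom, 1000 - p.pos, "-" if p.strand == "+" else "+",
                         counts=dict(p.counts), tpm=dict(p.tpm))
            for p in positions
        ]
        a = as_member_tuples(cluster_ctss(positions, **STRICT))
        b = as_member_tuples(cluster_ctss(mirrored, **STRICT))
        mirrored_back = sorted(tuple(sorted(1000 - x for x in t)) for t in b)
        assert mirrored_back == a


class TestAggregate:
    def test_merge_within_gap(self):
        c1 = TssCluster("c", "+", [pos(100, 2.0), pos(110, 2.0)])
        c2 = TssCluster("c", "+", [pos(140, 2.0), pos(150, 2.0)])
        agg = aggregate_clusters([c1, c2], **AGGREGATE)
        assert len(agg) == 1
        assert (agg[0].start, agg[0].end) == (100, 150)

    def test_no_merge_far_apart(self):
        c1 = TssCluster("c", "+", [pos(100, 2.0)])
        c2 = TssCluster("c", "+", [pos(300, 2.0)])
        assert len(aggregate_clusters([c1, c2], **AGGREGATE)) == 2

    def test_subthreshold_excluded(self):
        c1 = TssCluster("c", "+", [pos(100, 0.5)])
        assert aggregate_clusters([c1], **AGGREGATE) == []

    def test_total_tpm_never_decreases(self, rng):
        positions = make_positions(rng, 150)
        clusters = cluster_ctss(positions, **PERMISSIVE)
        surviving = [c for c in clusters if c.pooled_tpm >= AGGREGATE["tpm_threshold"]]
        agg = aggregate_clusters(clusters, **AGGREGATE)
        assert sum(c.pooled_tpm for c in agg) >= sum(c.pooled_tpm for c in surviving) - 1e-9


class TestDominantPosition:
    def test_unique_max(self):
        c = TssCluster("c", "+", [pos(100, 5.0), pos(104, 3.0)])
        assert dominant_position(c) == 100

    def test_tie_break_five_prime(self):
        members = [pos(100, 5.0), pos(104, 5.0)]
        assert dominant_position(TssCluster("c", "+", members)) == 100
        minus = [pos(100, 5.0, strand="-"), pos(104, 5.0, strand="-")]
        assert dominant_position(TssCluster("c", "-", minus)) == 104

    def test_single_member(self):
        assert dominant_position(TssCluster("c", "+", [pos(7, 1.0)])) == 7

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            dominant_position(TssCluster("c", "+", []))


class TestLog2FoldChange:
    def make(self, tpm_a, tpm_b):
        p = CtssPosition("c", 1, "+", tpm={"a": tpm_a, "b": tpm_b})
        return TssCluster("c", "+", [p])

    def test_basic(self):
        assert log2_fold_change(self.make(2, 8), ["a"], ["b"], 0.0) == pytest.approx(2.0)

    def test_identity(self):
        assert log2_fold_change(self.make(4, 4), ["a"], ["b"], 0.0) == 0.0

    def test_pseudocount(self):
        got = log2_fold_change(self.make(0, 4), ["a"], ["b"], 0.5)
        assert got == pytest.approx(np.log2(9))
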