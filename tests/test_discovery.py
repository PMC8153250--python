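import numpy as np
import pytest

from lutiscan.clustering import CtssPosition, TssCluster
from lutiscan.core import GeneModel, GenomicInterval, LongReadSpan
from lutiscan.discovery import (
    classify_locus,
    discover,
    induction_filter,
    spanning_read_check,
)


def cluster_at(p, tpm=10.0, strand="+", chrom="c"):
    return TssCluster(chrom, strand, [
        CtssPosition(chrom, p, strand, tpm={"s": tpm})
    ])


def gene(start, end, strand="+", gid="g1", chrom="c"):
    return GeneModel(gid, GenomicInterval(chrom, start, end, strand))


def read(start, end, strand="+", chrom="c"):
    return LongReadSpan(GenomicInterval(chrom, start, end, strand))


class TestInductionFilter:
    def test_pass(self):
        assert induction_filter(0.3, 4.7)  # mean 2.5, strong fold change

    def test_low_mean_fails(self):
        assert not induction_filter(0.0, 3.8)  # mean 1.9 despite log2FC > 2

    def test_exact_log2fc_boundary_fails(self):
        # log2FC exactly 2.0 with pseudocount 0: 2 -> 8 TPM
        assert not induction_filter(2.0, 8.0, pseudocount=0.0)

    def test_exact_mean_boundary_fails(self):
        assert not induction_filter(0.0, 4.0, pseudocount=0.1, min_log2fc=0.0)


class TestSpanningReadCheck:
    def setup_method(self):
        self.gene = gene(1000, 2000)

    def test_containment_counted(self):
        assert spanning_read_check(500, self.gene, [read(500, 2010)]) == 1

    def test_partial_cds_not_counted(self):
        assert spanning_read_check(500, self.gene, [read(500, 1500)]) == 0

    def test_window_boundary(self):
        r = [read(551, 2010)]
        assert spanning_read_check(500, self.gene, r, near_window=50) == 0
        assert spanning_read_check(500, self.gene, r, near_window=51) == 1

    def test_wrong_strand_not_counted(self):
        assert spanning_read_check(500, self.gene, [read(500, 2010, strand="-")]) == 0


class TestClassifyLocus:
    def test_planted_luti_geometry(self):
        g = gene(1000, 2000)
        distal = cluster_at(200)  # 800 upstream of ATG
        prox = cluster_at(880)  # 120 upstream
        reads = [read(200, 2020)]
        call = classify_locus(distal, [distal, prox], [g], reads)
        assert call.cls == "luti_candidate"
        assert call.gene_id == "g1"
        assert call.prox_tss == 880
        assert call.spanning_read_count == 1

    def test_no_intervening_promoter_is_canonical(self):
        g = gene(1000, 2000)
        distal = cluster_at(880)
        call = classify_locus(distal, [distal], [g], [read(880, 2020)])
        assert call.cls == "canonical"

    def test_antisense(self):
        g = gene(1000, 2000, strand="+")
        cand = cluster_at(1500, strand="-")
        call = classify_locus(cand, [cand], [g], [])
        assert call.cls == "antisense"

    def test_intragenic(self):
        g = gene(1000, 2000, strand="+")
        cand = cluster_at(1300, strand="+")
        call = classify_locus(cand, [cand], [g], [])
        assert call.cls == "intragenic"

    def test_intergenic(self):
        cand = cluster_at(5000)
        call = classify_locus(cand, [cand], [gene(1000, 2000)], [])
        assert call.cls == "intergenic"

    def test_minus_strand_luti(self):
        g = gene(1000, 2000, strand="-")
        distal = cluster_at(2800, strand="-")
        prox = cluster_at(2120, strand="-")
        reads = [read(980, 2801, strand="-")]
        call = classify_locus(distal, [distal, prox], [g], reads)
        assert call.cls == "luti_candidate"
        assert call.prox_tss == 2120


class TestFullStudy:
    def test_class_counts_match_truth(self, default_study, default_calls):
        calls, _ = default_calls
        truth_counts = default_study.truth.cls.value_counts().to_dict()
        got = {}
        for c in calls:
            key = "luti" if c.cls == "luti_candidate" else c.cls
            got[key] = got.get(key, 0) + 1
        assert got == truth_counts

    def test_noiseless_precision_recall(self, default_study, default_calls):
        calls, _ = default_calls
        truth = default_study.truth
        planted = {(int(r.distal_tss), r.strand) for r in truth[truth.cls == "luti"].itertuples()}
        called = {(c.distal_tss, c.strand) for c in calls if c.cls == "luti_candidate"}

        def matched(x, pool):
            return any(abs(x[0] - y[0]) <= 5 and x[1] == y[1] for y in pool)

        assert all(matched(p, called) for p in planted)  # recall 1.0
        assert all(matched(c, planted) for c in called)  # precision 1.0

    def test_every_induced_cluster_single_class(self, default_calls):
        calls, _ = default_calls
        ids = [(id(c.distal_cluster)) for c in calls]
        assert len(ids) == len(set(ids))


class TestInvariance:
    def _tiny_instance(self, offset=0, mirror=False, genome_span=10_000):
        """LUTI geometry, optionally translated or strand-mirrored."""
        def t(p):
            return (genome_span - p if mirror else p) + offset

        strand = "-" if mirror else "+"
        if mirror:
            g = gene(t(2000), t(1000), strand=strand)
            reads = [read(t(2020), t(200) + 1, strand=strand)]
        else:
            g = gene(t(1000), t(2000), strand=strand)
            reads = [read(t(200), t(2020), strand=strand)]
        distal = cluster_at(t(200), strand=strand)
        prox = cluster_at(t(880), strand=strand)
        return distal, [distal, prox], [g], reads

    def test_translation_invariance(self):
        base = classify_locus(*self._tiny_instance(offset=0))
        moved = classify_locus(*self._tiny_instance(offset=7777))
        assert base.cls == moved.cls == "luti_candidate"
        assert moved.distal_tss - base.distal_tss == 7777

    def test_strand_mirror_invariance(self):
        base = classify_locus(*self._tiny_instance())
        mirrored = classify_locus(*self._tiny_instance(mirror=True))
        assert base.cls == mirrored.cls == "luti_candidate"

    def test_noisy_recall_single_seed(self):
        from lutiscan.pipeline import run_discovery
        from lutiscan.simulate import SimConfig, generate_study

        study = generate_study(SimConfig(seed=3, dispersion=0.2, n_luti=10,
                                         n_canonical=10, n_antisense=3,
                                         n_intergenic=3, n_intragenic=3))
        calls, _ = run_discovery(study)
        truth = study.truth
        planted = {(int(r.distal_tss), r.strand) for r in truth[truth.cls == "luti"].itertuples()}
        called = {(c.distal_tss, c.strand) for c in calls if c.cls == "luti_candidate"}
        hits = sum(
            any(abs(p[0] - c[0]) <= 5 and p[1] == c[1] for c in called) for p in planted
        )
        assert hits / len(planted) >= 0.9
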