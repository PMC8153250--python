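"""Distance-based clustering of 5'-end tag positions.

Single-base tag positions are TPM-normalized, thresholded, merged into
clusters when within a fixed distance on the same strand, and then
aggregated into promoter-level clusters. Two parameter sets are used:
a strict one for discovery and a permissive one for quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import SignalTrack

#: strict parameters: discovery clustering
STRICT = dict(threshold=2.0, max_dist=5, remove_singletons=True, keep_singletons_above=3.0)
#: permissive parameters: quantification clustering
PERMISSIVE = dict(threshold=1.0, max_dist=5, remove_singletons=False, keep_singletons_above=0.0)

#: promoter-level aggregation parameters
AGGREGATE = dict(tpm_threshold=1.0, max_dist=50)


@dataclass
class CtssPosition:
    """A single-base transcript 5' end with per-sample counts and TPM."""

    chrom: str
    pos: int
    strand: str
    counts: Dict[str, float] = field(default_factory=dict)
    tpm: Dict[str, float] = field(default_factory=dict)

    @property
    def pooled_tpm(self) -> float:
        return float(sum(self.tpm.values()))


@dataclass
class TssCluster:
    """A strand-specific cluster of CTSS positions.

    ``start``/``end`` are the min/max member positions (both inclusive of
    covered bases; ``end`` is the last member position, not half-open).
    """

    chrom: str
    strand: str
    members: List[CtssPosition]

    @property
    def start(self) -> int:
        return self.members[0].pos

    @property
    def end(self) -> int:
        return self.members[-1].pos

    @property
    def samples(self) -> Tuple[str, ...]:
        keys: set = set()
        for m in self.members:
            keys.update(m.tpm)
        return tuple(sorted(keys))

    def sample_tpm(self, sample: str) -> float:
        return float(sum(m.tpm.get(sample, 0.0) for m in self.members))

    def sample_count(self, sample: str) -> float:
        return float(sum(m.counts.get(sample, 0.0) for m in self.members))

    @property
    def pooled_tpm(self) -> float:
        return float(sum(m.pooled_tpm for m in self.members))

    @property
    def dominant_pos(self) -> int:
        return dominant_position(self)

    def mean_tpm(self, samples: Sequence[str]) -> float:
        if not samples:
            raise ValueError("no samples given")
        return float(np.mean([self.sample_tpm(s) for s in samples]))


def build_ctss(
    tracks: Mapping[str, Mapping[str, SignalTrack]],
) -> List[CtssPosition]:
    """Collect per-sample stranded 5'-end tracks into CTSS positions.

    ``tracks[sample][strand]`` is a count track; positions covered in any
    sample appear once with all samples' counts (absent = 0).
    """
    index: Dict[Tuple[str, int, str], CtssPosition] = {}
    for sample, by_strand in tracks.items():
        for strand, track in by_strand.items():
            for chrom in track.chroms:
                for pos, val in track.items(chrom):
                    key = (chrom, pos, strand)
                    ctss = index.get(key)
                    if ctss is None:
                        ctss = index[key] = CtssPosition(chrom, pos, strand)
                    ctss.counts[sample] = ctss.counts.get(sample, 0.0) + val
    return sorted(index.values(), key=lambda c: (c.chrom, c.strand, c.pos))


def normalize_tpm(positions: Sequence[CtssPosition]) -> List[CtssPosition]:
    """Fill per-sample TPM: count / library size * 1e6.

    The library size of a sample is its total tag count over all
    positions. Samples with zero total are an error.
    """
    totals: Dict[str, float] = {}
    for p in positions:
        for sample, c in p.counts.items():
            totals[sample] = totals.get(sample, 0.0) + c
    for sample, total in totals.items():
        if total <= 0:
            raise ValueError(f"zero library size for sample {sample!r}")
    for p in positions:
        p.tpm = {s: c / totals[s] * 1e6 for s, c in p.counts.items()}
    return list(positions)


def _per_sample_max_tpm(p: CtssPosition) -> float:
    return max(p.tpm.values(), default=0.0)


def cluster_ctss(
    positions: Sequence[CtssPosition],
    threshold: float = 2.0,
    max_dist: int = 5,
    remove_singletons: bool = True,
    keep_singletons_above: float = 3.0,
    pooled: bool = True,
) -> List[TssCluster]:
    """Distance-based clustering of thresholded CTSS positions.

    Positions whose TPM reaches ``threshold`` seed clusters; seeds on the
    same chromosome and strand merge transitively while consecutive gaps
    are at most ``max_dist`` bp. Single-position clusters are dropped
    when ``remove_singletons`` unless their pooled TPM exceeds
    ``keep_singletons_above``.

    ``pooled`` selects whether the seed threshold applies to the TPM
    summed over all samples (default) or to the per-sample maximum.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    level = (lambda p: p.pooled_tpm) if pooled else _per_sample_max_tpm
    seeds = [p for p in positions if level(p) >= threshold]
    seeds.sort(key=lambda p: (p.chrom, p.strand, p.pos))

    clusters: List[TssCluster] = []
    run: List[CtssPosition] = []
    for p in seeds:
        if run and (
            p.chrom != run[-1].chrom
            or p.strand != run[-1].strand
            or p.pos - run[-1].pos > max_dist
        ):
            clusters.append(TssCluster(run[0].chrom, run[0].strand, run))
            run = []
        run.append(p)
    if run:
        clusters.append(TssCluster(run[0].chrom, run[0].strand, run))

    if remove_singletons:
        clusters = [
            c
            for c in clusters
            if len(c.members) > 1 or c.pooled_tpm > keep_singletons_above
        ]
    return clusters


def aggregate_clusters(
    clusters: Sequence[TssCluster],
    tpm_threshold: float = 1.0,
    max_dist: int = 50,
) -> List[TssCluster]:
    """Merge nearby clusters into promoter-level aggregates.

    Clusters with pooled TPM >= ``tpm_threshold`` merge when the gap
    between their boundaries is at most ``max_dist`` bp on the same
    chromosome and strand; member lists concatenate.
    """
    kept = sorted(
        (c for c in clusters if c.pooled_tpm >= tpm_threshold),
        key=lambda c: (c.chrom, c.strand, c.start),
    )
    out: List[TssCluster] = []
    for c in kept:
        if (
            out
            and out[-1].chrom == c.chrom
            and out[-1].strand == c.strand
            and c.start - out[-1].end <= max_dist
        ):
            out[-1] = TssCluster(c.chrom, c.strand, out[-1].members + c.members)
        else:
            out.append(TssCluster(c.chrom, c.strand, list(c.members)))
    return out


def dominant_position(cluster: TssCluster) -> int:
    """Member position with maximal pooled TPM; ties go 5'-most."""
    if not cluster.members:
        raise ValueError("empty cluster")
    best = max(m.pooled_tpm for m in cluster.members)
    tied = [m.pos for m in cluster.members if m.pooled_tpm == best]
    return max(tied) if cluster.strand == "-" else min(tied)


def log2_fold_change(
    cluster: TssCluster,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    pseudocount: float = 0.1,
) -> float:
    """log2((mean_b + pc) / (mean_a + pc)) of replicate-mean cluster TPM."""
    mean_a = cluster.mean_tpm(samples_a)
    mean_b = cluster.mean_tpm(samples_b)
    return float(np.log2((mean_b + pseudocount) / (mean_a + pseudocount)))


def clusters_to_frame(clusters: Sequence[TssCluster]):
    """Tabular view of clusters (one row each) for TSV export."""
    import pandas as pd

    samples = sorted({s for c in clusters for s in c.samples})
    rows = []
    for c in clusters:
        row = {
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "strand": c.strand,
            "dominant_pos": c.dominant_pos,
            "pooled_tpm": c.pooled_tpm,
        }
        for s in samples:
            row[f"tpm_{s}"] = c.sample_tpm(s)
        rows.append(row)
    return pd.DataFrame(rows)
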