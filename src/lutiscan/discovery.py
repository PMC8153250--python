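"""Discovery of 5'-extended transcript isoforms.

Meiotically induced promoter clusters are validated against long-read
spans and classified into five locus classes: a 5'-extension call
(``luti_candidate``) requires a same-strand long read covering an
entire neighboring CDS plus a second promoter closer to that CDS;
induced clusters without the second promoter are canonical; the rest
split into antisense / intragenic / intergenic by gene-body overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .clustering import TssCluster, log2_fold_change
from .core import GeneModel, LongReadSpan

CLASSES = ("luti_candidate", "canonical", "antisense", "intergenic", "intragenic")


@dataclass
class LocusCall:
    """One classified transcript start event."""

    cls: str
    chrom: str
    strand: str
    distal_tss: int
    gene_id: Optional[str] = None
    prox_tss: Optional[int] = None
    distal_cluster: Optional[TssCluster] = None
    prox_cluster: Optional[TssCluster] = None
    spanning_read_count: int = 0

    def __post_init__(self) -> None:
        if self.cls not in CLASSES:
            raise ValueError(f"unknown class {self.cls!r}")


def induction_filter(
    mean_pre: float, mean_mei: float, pseudocount: float = 0.1,
    min_mean_tpm: float = 2.0, min_log2fc: float = 2.0,
) -> bool:
    """Pass iff the mean TPM over both timepoints exceeds ``min_mean_tpm``
    and the log2 fold change (meiotic over premeiotic) exceeds
    ``min_log2fc`` — both strictly."""
    mean_both = 0.5 * (mean_pre + mean_mei)
    lfc = float(np.log2((mean_mei + pseudocount) / (mean_pre + pseudocount)))
    return mean_both > min_mean_tpm and lfc > min_log2fc


def spanning_read_check(
    tss: int,
    gene: GeneModel,
    reads: Sequence[LongReadSpan],
    near_window: int = 50,
) -> int:
    """Count same-strand reads whose 5' end lies within ``near_window``
    of ``tss`` and whose span contains the entire CDS."""
    n = 0
    for read in reads:
        if read.strand != gene.strand:
            continue
        if abs(read.five_prime - tss) > near_window:
            continue
        if read.interval.chrom == gene.cds.chrom and read.interval.contains(gene.cds):
            n += 1
    return n


def _is_downstream(tss: int, pos: int, strand: str) -> bool:
    """Is ``pos`` strictly 3' of ``tss`` in transcript orientation?"""
    return pos > tss if strand == "+" else pos < tss


def classify_locus(
    candidate: TssCluster,
    promoter_clusters: Sequence[TssCluster],
    genes: Sequence[GeneModel],
    reads: Sequence[LongReadSpan],
    near_window: int = 50,
) -> LocusCall:
    """Apply the classification cascade to one induced cluster.

    (1) same-strand gene whose CDS is fully spanned by a read from this
    TSS, with a second same-strand promoter between the TSS and the CDS
    5' end -> luti_candidate; (2) same evidence, no closer promoter ->
    canonical; (3) TSS inside an opposite-strand CDS -> antisense;
    (4) TSS inside a same-strand CDS -> intragenic; (5) else intergenic.
    """
    tss = candidate.dominant_pos
    strand = candidate.strand
    chrom = candidate.chrom

    # rules (1)/(2): full-CDS spanning evidence
    supported: List[Tuple[GeneModel, int]] = []
    for gene in genes:
        if gene.strand != strand or gene.cds.chrom != chrom:
            continue
        if not _is_downstream(tss, gene.cds_start_5p, strand):
            continue
        n = spanning_read_check(tss, gene, reads, near_window)
        if n >= 1:
            supported.append((gene, n))
    if supported:
        # nearest CDS 5' end downstream of the TSS
        gene, n_reads = min(supported, key=lambda gn: abs(gn[0].cds_start_5p - tss))
        cds5 = gene.cds_start_5p
        prox = _closest_intervening_promoter(tss, cds5, strand, chrom, promoter_clusters, candidate)
        if prox is not None:
            return LocusCall(
                cls="luti_candidate", chrom=chrom, strand=strand,
                distal_tss=tss, gene_id=gene.gene_id,
                prox_tss=prox.dominant_pos, distal_cluster=candidate,
                prox_cluster=prox, spanning_read_count=n_reads,
            )
        return LocusCall(
            cls="canonical", chrom=chrom, strand=strand, distal_tss=tss,
            gene_id=gene.gene_id, distal_cluster=candidate,
            spanning_read_count=n_reads,
        )

    # rules (3)/(4): gene-body overlap
    for gene in genes:
        if gene.cds.chrom != chrom or not gene.cds.contains_pos(tss):
            continue
        if gene.strand != strand:
            return LocusCall(
                cls="antisense", chrom=chrom, strand=strand,
                distal_tss=tss, gene_id=gene.gene_id, distal_cluster=candidate,
            )
        return LocusCall(
            cls="intragenic", chrom=chrom, strand=strand,
            distal_tss=tss, gene_id=gene.gene_id, distal_cluster=candidate,
        )

    return LocusCall(
        cls="intergenic", chrom=chrom, strand=strand,
        distal_tss=tss, distal_cluster=candidate,
    )


def _closest_intervening_promoter(
    tss: int,
    cds5: int,
    strand: str,
    chrom: str,
    promoter_clusters: Sequence[TssCluster],
    exclude: TssCluster,
) -> Optional[TssCluster]:
    """Promoter-level cluster whose dominant position lies strictly
    between ``tss`` and ``cds5``; the one closest to the CDS wins."""
    best = None
    for cl in promoter_clusters:
        if cl is exclude or cl.strand != strand or cl.chrom != chrom:
            continue
        pos = cl.dominant_pos
        lo, hi = (tss, cds5) if strand == "+" else (cds5, tss)
        if lo < pos < hi:
            if best is None or abs(pos - cds5) < abs(best.dominant_pos - cds5):
                best = cl
    return best


def discover(
    promoter_clusters: Sequence[TssCluster],
    genes: Sequence[GeneModel],
    reads: Sequence[LongReadSpan],
    samples_pre: Sequence[str],
    samples_mei: Sequence[str],
    pseudocount: float = 0.1,
    min_mean_tpm: float = 2.0,
    min_log2fc: float = 2.0,
    near_window: int = 50,
) -> List[LocusCall]:
    """Run the full discovery cascade over promoter-level clusters."""
    calls: List[LocusCall] = []
    for cl in promoter_clusters:
        mean_pre = cl.mean_tpm(samples_pre)
        mean_mei = cl.mean_tpm(samples_mei)
        if not induction_filter(mean_pre, mean_mei, pseudocount, min_mean_tpm, min_log2fc):
            continue
        calls.append(classify_locus(cl, promoter_clusters, genes, reads, near_window))
    return calls


def calls_from_frame(frame) -> List[LocusCall]:
    """Rebuild locus calls from a TSV written by :func:`calls_to_frame`
    (cluster references and read counts are not reconstructed)."""
    calls = []
    for row in frame.itertuples():
        prox = int(row.prox_tss)
        calls.append(
            LocusCall(
                cls=row.cls, chrom=row.chrom, strand=row.strand,
                distal_tss=int(row.distal_tss),
                gene_id=row.gene_id or None,
                prox_tss=prox if prox >= 0 else None,
                spanning_read_count=int(getattr(row, "spanning_read_count", 0)),
            )
        )
    return calls


def calls_to_frame(calls: Sequence[LocusCall]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "cls": c.cls,
                "chrom": c.chrom,
                "strand": c.strand,
                "distal_tss": c.distal_tss,
                "gene_id": c.gene_id or "",
                "prox_tss": c.prox_tss if c.prox_tss is not None else -1,
                "spanning_read_count": c.spanning_read_count,
            }
            for c in calls
        ]
    )
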