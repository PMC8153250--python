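"""uORF inventory of 5'-extension leaders and footprint translation calls.

uORFs are operationalized as ATG occurrences on the transcript strand
between the distal and proximal TSSs (all offsets and frames, overlaps
counted). A uORF is called translated when at least ``min_reads``
footprint 5' counts fall within its first 6 codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import SignalTrack, revcomp


@dataclass
class UorfProfile:
    """Per-gene ATG/uORF inventory with translation calls."""

    gene_id: str
    chrom: str
    strand: str
    distal_tss: int
    prox_tss: int
    uorf_starts: List[int] = field(default_factory=list)  # 5'->3' order
    translated: List[bool] = field(default_factory=list)
    te: Optional[float] = None

    @property
    def n_atg(self) -> int:
        return len(self.uorf_starts)


def count_leader_atgs(
    genome: Mapping[str, str],
    chrom: str,
    distal_tss: int,
    prox_tss: int,
    strand: str,
) -> Tuple[int, List[int]]:
    """Count ATGs on the transcript strand between the two TSSs.

    The region is ``[distal, prox)`` in transcript orientation. Returned
    start positions are genome coordinates of the A base, 5'->3'.
    """
    seq = genome[chrom]
    if strand == "+":
        if distal_tss >= prox_tss:
            raise ValueError("distal TSS must be 5' of prox TSS")
        leader = seq[distal_tss:prox_tss]
        starts = [distal_tss + i for i in _find_all(leader, "ATG")]
    elif strand == "-":
        if distal_tss <= prox_tss:
            raise ValueError("distal TSS must be 5' of prox TSS")
        leader = revcomp(seq[prox_tss + 1 : distal_tss + 1])
        starts = [distal_tss - i for i in _find_all(leader, "ATG")]
    else:
        raise ValueError("strand must be + or -")
    return len(starts), starts


def _find_all(seq: str, motif: str) -> List[int]:
    out = []
    i = seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)  # overlapping occurrences count
    return out


def uorf_translated(
    footprints: SignalTrack,
    chrom: str,
    uorf_start: int,
    strand: str,
    min_reads: float = 4.0,
    window_codons: int = 6,
) -> bool:
    """True iff footprint counts over the uORF's first ``window_codons``
    codons (ATG included) reach ``min_reads``."""
    width = 3 * window_codons
    if strand == "+":
        total = footprints.window_sum(chrom, uorf_start, uorf_start + width)
    else:
        total = footprints.window_sum(chrom, uorf_start - width + 1, uorf_start + 1)
    return total >= min_reads


def annotate_translation(
    profile: UorfProfile,
    footprints: SignalTrack,
    min_reads: float = 4.0,
    window_codons: int = 6,
) -> UorfProfile:
    profile.translated = [
        uorf_translated(footprints, profile.chrom, s, profile.strand, min_reads, window_codons)
        for s in profile.uorf_starts
    ]
    return profile


def first_last_summary(
    profiles: Sequence[UorfProfile],
    min_uorfs: int = 4,
    strictly_greater: bool = False,
) -> Dict[str, float]:
    """Translated fraction of the 2 most-5' and 2 most-3' uORFs across
    genes with at least (or, optionally, more than) ``min_uorfs`` uORFs.

    Returns keys ``first_1``, ``first_2``, ``penultimate``, ``last`` plus
    ``n_genes``; empty dict when no gene qualifies.
    """
    if strictly_greater:
        qualifying = [p for p in profiles if p.n_atg > min_uorfs and p.translated]
    else:
        qualifying = [p for p in profiles if p.n_atg >= min_uorfs and p.translated]
    if not qualifying:
        return {}
    ranks = {"first_1": 0, "first_2": 1, "penultimate": -2, "last": -1}
    out: Dict[str, float] = {
        name: float(np.mean([p.translated[idx] for p in qualifying]))
        for name, idx in ranks.items()
    }
    out["n_genes"] = float(len(qualifying))
    return out


def atg_background(
    genome: Mapping[str, str],
    tss_list: Sequence[Tuple[str, int, str]],
    window: int = 500,
) -> List[Dict]:
    """Per-gene ATG frequency (per bp) in the window 5' of each TSS.

    ``tss_list`` holds (chrom, tss, strand). Windows running off the
    contig edge are truncated and flagged.
    """
    rows = []
    for chrom, tss, strand in tss_list:
        seq = genome[chrom]
        if strand == "+":
            lo, hi = max(0, tss - window), tss
            region = seq[lo:hi]
        else:
            lo, hi = tss + 1, min(len(seq), tss + 1 + window)
            region = revcomp(seq[lo:hi])
        truncated = len(region) < window
        n = len(_find_all(region, "ATG"))
        freq = n / len(region) if region else float("nan")
        rows.append(
            dict(chrom=chrom, tss=tss, strand=strand, n_atg=n,
                 window=len(region), freq=freq, truncated=truncated)
        )
    return rows


def rpkm(reads: float, feature_len_bp: float, total_mapped_reads: float) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if feature_len_bp <= 0 or total_mapped_reads <= 0:
        raise ValueError("feature length and library size must be positive")
    return reads / (feature_len_bp / 1e3) / (total_mapped_reads / 1e6)


def translational_efficiency(footprint_rpkm: float, transcript_rpkm: float) -> Optional[float]:
    """Footprint RPKM over transcript RPKM; None when undefined."""
    if transcript_rpkm <= 0:
        return None
    return footprint_rpkm / transcript_rpkm


def profile_from_call(
    genome: Mapping[str, str],
    gene_id: str,
    chrom: str,
    distal_tss: int,
    prox_tss: int,
    strand: str,
    footprints: Optional[SignalTrack] = None,
    min_reads: float = 4.0,
) -> UorfProfile:
    _, starts = count_leader_atgs(genome, chrom, distal_tss, prox_tss, strand)
    profile = UorfProfile(
        gene_id=gene_id, chrom=chrom, strand=strand,
        distal_tss=distal_tss, prox_tss=prox_tss, uorf_starts=starts,
    )
    if footprints is not None:
        annotate_translation(profile, footprints, min_reads)
    return profile
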