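"""Promoter-window histone-mark quantification and TF-target calling.

Mark enrichment is summed over a 50 bp window upstream and a 500 bp
window downstream of the proximal TSS (strand-aware); the score is the
downstream/upstream ratio so that a co-transcriptional mark gain over
the gene body raises it. The per-replicate meiotic/premeiotic ratio
change is averaged into one fold change per gene and mark.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import PeakRecord, SignalTrack

UP_WINDOW = 50
DOWN_WINDOW = 500


@dataclass
class PromoterChromatinScore:
    gene_id: str
    mark: str
    up_sum: float
    down_sum: float
    ratio: Optional[float]  # None when the upstream sum is zero


@dataclass
class TfTargetCall:
    gene_id: str
    tss: int
    nearest_peak_distance: List[Optional[int]]  # per replicate
    is_target: bool


def promoter_mark_score(
    track: SignalTrack,
    chrom: str,
    tss: int,
    strand: str,
    up_window: int = UP_WINDOW,
    down_window: int = DOWN_WINDOW,
    orientation: str = "down_over_up",
) -> Tuple[float, float, Optional[float]]:
    """Window sums around the TSS and their ratio.

    Upstream covers the ``up_window`` bases 5' of the TSS; downstream
    the ``down_window`` bases starting at the TSS, both strand-aware.
    Returns (up_sum, down_sum, ratio); ratio is None when the
    denominator is zero.
    """
    if strand == "+":
        up = track.window_sum(chrom, tss - up_window, tss)
        down = track.window_sum(chrom, tss, tss + down_window)
    elif strand == "-":
        up = track.window_sum(chrom, tss + 1, tss + 1 + up_window)
        down = track.window_sum(chrom, tss - down_window + 1, tss + 1)
    else:
        raise ValueError("strand must be + or -")
    if orientation == "down_over_up":
        num, den = down, up
    elif orientation == "up_over_down":
        num, den = up, down
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    ratio = num / den if den > 0 else None
    return up, down, ratio


def mark_fold_change(
    ratios_pre: Sequence[Optional[float]],
    ratios_mei: Sequence[Optional[float]],
) -> Optional[float]:
    """Mean over replicates of the meiotic/premeiotic ratio change.

    Replicates with an undefined ratio at either timepoint are skipped;
    None when no replicate is usable.
    """
    if len(ratios_pre) != len(ratios_mei):
        raise ValueError("replicate count mismatch")
    fcs = [
        m / p
        for p, m in zip(ratios_pre, ratios_mei)
        if p is not None and m is not None and p > 0
    ]
    if not fcs:
        return None
    return float(np.mean(fcs))


def tf_target_call(
    peaks_by_replicate: Sequence[Sequence[PeakRecord]],
    gene_id: str,
    chrom: str,
    tss: int,
    max_dist: int = 300,
    min_log2_enrichment: float = 2.0,
    min_replicates: int = 2,
) -> TfTargetCall:
    """Target iff, in at least ``min_replicates`` replicates, a peak with
    log2 enrichment above ``min_log2_enrichment`` has its summit within
    ``max_dist`` bp of the TSS."""
    distances: List[Optional[int]] = []
    n_qualifying = 0
    for peaks in peaks_by_replicate:
        best: Optional[int] = None
        for pk in peaks:
            if pk.interval.chrom != chrom:
                continue
            if pk.log2_enrichment <= min_log2_enrichment:
                continue
            d = abs(pk.summit - tss)
            if best is None or d < best:
                best = d
        distances.append(best)
        if best is not None and best <= max_dist:
            n_qualifying += 1
    return TfTargetCall(
        gene_id=gene_id, tss=tss, nearest_peak_distance=distances,
        is_target=n_qualifying >= min_replicates,
    )


def metagene_matrix(
    track: SignalTrack,
    anchors: Sequence[Tuple[str, int, str]],
    flank: int = 500,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-base value matrix around anchors, upstream always left.

    ``anchors`` holds (chrom, tss, strand). Rows are genes, columns run
    -flank..+flank (2*flank+1 wide). Bases outside the covered contig
    are representable (tracks default to 0); positions before the start
    of the coordinate system are NaN-padded. Returns (matrix,
    column mean ignoring NaN).
    """
    width = 2 * flank + 1
    mat = np.full((len(anchors), width), np.nan)
    for i, (chrom, tss, strand) in enumerate(anchors):
        lo, hi = tss - flank, tss + flank + 1
        row = np.full(width, np.nan)
        clip_lo = max(lo, 0)
        vals = track.to_array(chrom, clip_lo, hi)
        row[clip_lo - lo :] = vals
        if strand == "-":
            row = row[::-1]
        mat[i] = row
    if len(anchors):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            mean = np.nanmean(mat, axis=0)
    else:
        mean = np.full(width, np.nan)
    return mat, mean
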