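"""Nucleosome calling from dyad coverage, +1/-1 assignment, and
between-timepoint shift / fuzziness-change features.

Calls are local maxima of Gaussian-smoothed dyad density, accepted
greedily in decreasing density order under a minimum-spacing
constraint. Occupancy is the raw dyad count within +/-73 bp of the
accepted position; fuzziness is the count-weighted standard deviation
of dyad positions in that same window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import SignalTrack

HALF_NUC = 73  # bp on either side of the dyad used for occupancy/fuzziness


@dataclass
class NucleosomeCall:
    chrom: str
    dyad_pos: int
    occupancy: float
    fuzziness: float


@dataclass
class FlankingNucleosomes:
    gene_id: str
    plus_one: Optional[NucleosomeCall] = None
    minus_one: Optional[NucleosomeCall] = None


def call_nucleosomes(
    dyads: SignalTrack,
    smoothing_bw: float = 15.0,
    min_spacing: int = 120,
    min_occupancy: float = 20.0,
) -> List[NucleosomeCall]:
    """Call nucleosomes on every chromosome of a dyad-count track."""
    calls: List[NucleosomeCall] = []
    for chrom in dyads.chroms:
        start, end = dyads.span(chrom)
        if end <= start:
            continue
        pad = int(4 * smoothing_bw) + 1
        lo = max(start - pad, 0)
        hi = end + pad
        counts = dyads.to_array(chrom, lo, hi)
        density = gaussian_filter1d(counts, sigma=smoothing_bw, mode="constant")
        peak_idx = _local_maxima(density)
        # greedy acceptance, highest density first
        order = peak_idx[np.argsort(density[peak_idx])[::-1]]
        accepted: List[int] = []
        for idx in order:
            if all(abs(idx - a) >= min_spacing for a in accepted):
                accepted.append(int(idx))
        positions = np.arange(lo, hi)
        for idx in sorted(accepted):
            pos = lo + idx
            w_lo, w_hi = idx - HALF_NUC, idx + HALF_NUC + 1
            w_lo = max(w_lo, 0)
            w_hi = min(w_hi, len(counts))
            window = counts[w_lo:w_hi]
            occ = float(window.sum())
            if occ < min_occupancy or occ <= 0:
                continue
            pos_window = positions[w_lo:w_hi].astype(float)
            mean = float(np.average(pos_window, weights=window))
            var = float(np.average((pos_window - mean) ** 2, weights=window))
            calls.append(
                NucleosomeCall(chrom=chrom, dyad_pos=pos, occupancy=occ,
                               fuzziness=float(np.sqrt(var)))
            )
    return calls


def _local_maxima(density: np.ndarray) -> np.ndarray:
    """Strict-or-plateau local maxima of a 1D array (plateau midpoints)."""
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(density, plateau_size=1)
    return peaks


def assign_flanking(
    calls: Sequence[NucleosomeCall],
    gene_id: str,
    chrom: str,
    tss: int,
    strand: str,
    max_lookout: int = 500,
) -> FlankingNucleosomes:
    """+1 = nearest call strictly 3' of the TSS, -1 = nearest strictly 5',
    each within ``max_lookout`` bp; absent when none qualifies."""
    down: Optional[NucleosomeCall] = None
    up: Optional[NucleosomeCall] = None
    best_down = best_up = None
    for call in calls:
        if call.chrom != chrom:
            continue
        d = call.dyad_pos - tss
        if strand == "-":
            d = -d
        if 0 < d <= max_lookout and (best_down is None or d < best_down):
            down, best_down = call, d
        elif 0 < -d <= max_lookout and (best_up is None or -d < best_up):
            up, best_up = call, -d
    return FlankingNucleosomes(gene_id=gene_id, plus_one=down, minus_one=up)


def nucleosome_shift(
    pre: FlankingNucleosomes,
    mei: FlankingNucleosomes,
    strand: str,
    which: str = "plus_one",
) -> Tuple[Optional[float], Optional[float]]:
    """Strand-oriented dyad displacement and fuzziness change between
    timepoints for the +1 (or -1) nucleosome.

    The shift is signed in transcript orientation: for the +1
    nucleosome a negative value means movement toward the TSS (into the
    nucleosome-depleted region). Returns (shift, fuzziness_change), or
    (None, None) when either timepoint lacks the call.
    """
    a = getattr(pre, which)
    b = getattr(mei, which)
    if a is None or b is None:
        return None, None
    shift = float(b.dyad_pos - a.dyad_pos)
    if strand == "-":
        shift = -shift
    return shift, float(b.fuzziness - a.fuzziness)


def metagene_amplitude(mean_profile: np.ndarray) -> float:
    """(max - min) / mean of a metagene profile; a periodicity proxy."""
    m = np.nanmean(mean_profile)
    if not np.isfinite(m) or m == 0:
        return float("nan")
    return float((np.nanmax(mean_profile) - np.nanmin(mean_profile)) / m)
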