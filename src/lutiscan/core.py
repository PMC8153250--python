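"""Core genomic domain types shared by every analysis stage.

All coordinates are 0-based half-open. The 5' end of a minus-strand
feature is ``end - 1`` (the last covered base), so that strand-aware
window arithmetic is unambiguous everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, Mapping, Optional, Tuple

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Position of the 5'-most covered base (strand-aware)."""
        return self.end - 1 if self.strand == "-" else self.start

    @property
    def three_prime(self) -> int:
        return self.start if self.strand == "-" else self.end - 1

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass
class GeneModel:
    """A gene reduced to its CDS extent; only start/end/strand are used."""

    gene_id: str
    cds: GenomicInterval

    @property
    def strand(self) -> str:
        return self.cds.strand

    @property
    def cds_start_5p(self) -> int:
        """5' end of the CDS (the translation start side), strand-aware."""
        return self.cds.five_prime


@dataclass
class PeakRecord:
    """One narrowPeak record; summit is an absolute genome position."""

    interval: GenomicInterval
    name: str = "."
    score: int = 0
    enrichment: float = 0.0  # signalValue, linear fold enrichment
    p_value: float = -1.0
    q_value: float = -1.0
    summit: int = -1  # absolute position; midpoint fallback applied at parse

    @property
    def log2_enrichment(self) -> float:
        return float(np.log2(self.enrichment)) if self.enrichment > 0 else float("-inf")


@dataclass
class LongReadSpan:
    """The aligned genomic span of one long read (BED6, score ignored)."""

    interval: GenomicInterval
    name: str = "."

    @property
    def five_prime(self) -> int:
        return self.interval.five_prime

    @property
    def strand(self) -> str:
        return self.interval.strand


class SignalTrack:
    """Sparse per-base signal on one strand ('.' for unstranded tracks).

    Positions not present carry value 0. Values must be non-negative.
    """

    def __init__(
        self,
        strand: str = ".",
        units: str = "count",
        sample_id: str = "",
        timepoint: str = "",
        replicate: str = "",
    ) -> None:
        if strand not in STRANDS:
            raise ValueError(f"invalid strand {strand!r}")
        self.strand = strand
        self.units = units
        self.sample_id = sample_id
        self.timepoint = timepoint
        self.replicate = replicate
        self._data: Dict[str, Dict[int, float]] = {}

    # -- mutation ---------------------------------------------------------
    def add(self, chrom: str, pos: int, value: float) -> None:
        if value < 0:
            raise ValueError(f"negative signal {value} at {chrom}:{pos}")
        if value == 0:
            return
        d = self._data.setdefault(chrom, {})
        d[pos] = d.get(pos, 0.0) + value

    def set_interval(self, chrom: str, start: int, end: int, value: float) -> None:
        if value < 0:
            raise ValueError("negative signal")
        if value == 0:
            return
        d = self._data.setdefault(chrom, {})
        for pos in range(start, end):
            d[pos] = d.get(pos, 0.0) + value

    # -- access -----------------------------------------------------------
    def get(self, chrom: str, pos: int) -> float:
        return self._data.get(chrom, {}).get(pos, 0.0)

    @property
    def chroms(self) -> Tuple[str, ...]:
        return tuple(sorted(self._data))

    def positions(self, chrom: str) -> np.ndarray:
        return np.array(sorted(self._data.get(chrom, {})), dtype=np.int64)

    def items(self, chrom: str) -> Iterator[Tuple[int, float]]:
        d = self._data.get(chrom, {})
        for pos in sorted(d):
            yield pos, d[pos]

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        d = self._data.get(chrom)
        if not d:
            return 0.0
        if end - start < len(d):
            return sum(d.get(p, 0.0) for p in range(start, end))
        return sum(v for p, v in d.items() if start <= p < end)

    def to_array(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense value vector for ``[start, end)``; absent bases are 0."""
        out = np.zeros(end - start, dtype=float)
        d = self._data.get(chrom)
        if d:
            for p, v in d.items():
                if start <= p < end:
                    out[p - start] = v
        return out

    def total(self, chrom: Optional[str] = None) -> float:
        if chrom is not None:
            return float(sum(self._data.get(chrom, {}).values()))
        return float(sum(sum(d.values()) for d in self._data.values()))

    def span(self, chrom: str) -> Tuple[int, int]:
        d = self._data.get(chrom)
        if not d:
            return (0, 0)
        return min(d), max(d) + 1

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        return self.strand == other.strand and self._data == other._data

    def copy(self) -> "SignalTrack":
        t = SignalTrack(self.strand, self.units, self.sample_id, self.timepoint, self.replicate)
        t._data = {c: dict(d) for c, d in self._data.items()}
        return t


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
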