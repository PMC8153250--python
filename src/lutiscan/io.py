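"""Readers and writers for the plain-text formats the pipeline consumes.

bedGraph / BED6 / narrowPeak are 0-based half-open; GFF3 is 1-based
inclusive and converted on the way in/out. All tracks are returned as
:class:`~lutiscan.core.SignalTrack`; annotation as :class:`GeneModel`.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GeneModel, GenomicInterval, LongReadSpan, PeakRecord, SignalTrack


class FormatError(ValueError):
    """Raised on malformed or internally inconsistent input records."""


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path: str, strand_label: str = ".") -> SignalTrack:
    """Read a 4-column bedGraph into a per-base track.

    Each record's value is assigned to every base of its half-open
    interval. Overlapping records are rejected: a base may be covered at
    most once.
    """
    track = SignalTrack(strand=strand_label)
    covered: Dict[str, set] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom, s, e, v = fields
            try:
                start, end, value = int(s), int(e), float(v)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if end <= start:
                raise FormatError(f"{path}:{lineno}: zero/negative-length interval {start}-{end}")
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative value {value}")
            seen = covered.setdefault(chrom, set())
            for pos in range(start, end):
                if pos in seen:
                    raise FormatError(f"{path}:{lineno}: overlapping record at {chrom}:{pos}")
                seen.add(pos)
            if value > 0:
                for pos in range(start, end):
                    track.add(chrom, pos, value)
    return track


def write_bedgraph(track: SignalTrack, path: str) -> None:
    """Write a track as bedGraph, merging adjacent equal-valued bases."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            run_start: Optional[int] = None
            run_val = 0.0
            prev = None
            for pos, val in track.items(chrom):
                if run_start is not None and (pos != prev + 1 or val != run_val):
                    fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_val:g}\n")
                    run_start = None
                if run_start is None:
                    run_start, run_val = pos, val
                prev = pos
            if run_start is not None:
                fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_val:g}\n")


# ---------------------------------------------------------------------------
# BED6 (long-read spans)
# ---------------------------------------------------------------------------

def read_bed6(path: str) -> List[LongReadSpan]:
    spans: List[LongReadSpan] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 columns")
            chrom, s, e, name, _score, strand = fields[:6]
            try:
                iv = GenomicInterval(chrom, int(s), int(e), strand)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            spans.append(LongReadSpan(iv, name))
    return spans


def write_bed6(spans: Sequence[LongReadSpan], path: str) -> None:
    with open(path, "w") as fh:
        for sp in spans:
            iv = sp.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{sp.name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------

def read_narrowpeak(path: str) -> List[PeakRecord]:
    """Read ENCODE narrowPeak; the summit offset is converted to an
    absolute genome position, with a -1 offset falling back to the
    interval midpoint."""
    peaks: List[PeakRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise FormatError(f"{path}:{lineno}: narrowPeak needs 10 columns, got {len(fields)}")
            chrom, s, e, name, score, strand, signal, p, q, peak = fields
            try:
                iv = GenomicInterval(chrom, int(s), int(e), strand if strand in "+-" else ".")
                offset = int(peak)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if offset < 0:
                summit = iv.start + len(iv) // 2
            else:
                summit = iv.start + offset
            peaks.append(
                PeakRecord(
                    interval=iv,
                    name=name,
                    score=int(float(score)),
                    enrichment=float(signal),
                    p_value=float(p),
                    q_value=float(q),
                    summit=summit,
                )
            )
    return peaks


def write_narrowpeak(peaks: Sequence[PeakRecord], path: str) -> None:
    with open(path, "w") as fh:
        for pk in peaks:
            iv = pk.interval
            offset = pk.summit - iv.start
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{pk.name}\t{pk.score}\t"
                f"{iv.strand if iv.strand in '+-' else '.'}\t{pk.enrichment:g}\t"
                f"{pk.p_value:g}\t{pk.q_value:g}\t{offset}\n"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str, feature_types: Tuple[str, ...] = ("CDS", "gene")) -> List[GeneModel]:
    """Extract gene models from GFF3 CDS/gene features.

    1-based inclusive coordinates become 0-based half-open. Records
    without a usable strand are skipped with a warning on stderr.
    """
    import sys

    genes: List[GeneModel] = []
    seen_ids: set = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 needs 9 columns")
            chrom, _src, ftype, start1, end1, _score, strand, _frame, attrs = fields
            if ftype not in feature_types:
                continue
            if strand not in ("+", "-"):
                print(f"warning: {path}:{lineno}: missing strand, record skipped", file=sys.stderr)
                continue
            gene_id = _gff3_attr(attrs, "ID") or _gff3_attr(attrs, "Parent") or f"feat{lineno}"
            if gene_id in seen_ids:
                continue
            seen_ids.add(gene_id)
            iv = GenomicInterval(chrom, int(start1) - 1, int(end1), strand)
            genes.append(GeneModel(gene_id=gene_id, cds=iv))
    return genes


def _gff3_attr(attrs: str, key: str) -> Optional[str]:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def write_gff3(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.cds.chrom}\tlutiscan\tCDS\t{g.cds.start + 1}\t{g.cds.end}\t.\t"
                f"{g.cds.strand}\t0\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(genome: Dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# feature table (TSV)
# ---------------------------------------------------------------------------

def write_feature_table(rows: pd.DataFrame, path: str) -> None:
    """Tab-separated with header; missing values as empty cells."""
    rows.to_csv(path, sep="\t", index=False, na_rep="")


def read_feature_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# fragment -> dyad conversion (MNase)
# ---------------------------------------------------------------------------

def dyads_from_fragments(
    fragments: Iterable[GenomicInterval],
    min_len: int = 130,
    max_len: int = 170,
) -> SignalTrack:
    """Convert nucleosome-protected fragment spans to dyad counts.

    Only fragments within the [min_len, max_len] size window contribute;
    each deposits one count at floor((start + end) / 2).
    """
    track = SignalTrack(strand=".", units="dyads")
    for frag in fragments:
        if min_len <= len(frag) <= max_len:
            track.add(frag.chrom, (frag.start + frag.end) // 2, 1.0)
    return track


def stranded_bedgraph_pair(prefix: str) -> Tuple[str, str]:
    """Conventional file names for a stranded track pair."""
    return prefix + ".plus.bedgraph", prefix + ".minus.bedgraph"


def read_stranded_bedgraph(prefix: str) -> Dict[str, SignalTrack]:
    plus_path, minus_path = stranded_bedgraph_pair(prefix)
    out: Dict[str, SignalTrack] = {}
    if os.path.exists(plus_path):
        out["+"] = read_bedgraph(plus_path, "+")
    if os.path.exists(minus_path):
        out["-"] = read_bedgraph(minus_path, "-")
    return out


def write_stranded_bedgraph(tracks: Dict[str, SignalTrack], prefix: str) -> None:
    plus_path, minus_path = stranded_bedgraph_pair(prefix)
    write_bedgraph(tracks.get("+", SignalTrack("+")), plus_path)
    write_bedgraph(tracks.get("-", SignalTrack("-")), minus_path)
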