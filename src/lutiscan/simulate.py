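"""Synthetic study generator with planted ground truth.

Builds a random genome with planted loci of five classes (5'-extended
isoform, canonical induced, antisense, intergenic, intragenic) and
emits every data modality the pipeline consumes: stranded 5'-end tag
tracks at two timepoints in replicate, long-read spans, ribosome
footprints under a leaky-scanning model, histone-mark fold-enrichment
tracks, TF peak calls, and nucleosome dyad tracks. A truth table ties
every planted parameter to its locus so downstream stages can be
scored exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as lio
from .core import GeneModel, GenomicInterval, LongReadSpan, PeakRecord, SignalTrack, revcomp

TIMEPOINTS = ("pre", "mei")  # premeiotic, meiotic prophase
MARKS = ("H3K36me3", "H3K4me2")

#: tag-count jitter around a planted TSS: offsets -2..+2 and their weights
_JITTER_OFFSETS = np.array([-2, -1, 0, 1, 2])
_JITTER_WEIGHTS = np.array([0.1, 0.2, 0.4, 0.2, 0.1])

_SLOT = 4000  # bp reserved per planted locus
_MARGIN = 2000
_PROX_OFFSET = 120  # prox TSS this many bp upstream of the CDS 5' end
_CHROM = "chrS1"


@dataclass
class SimConfig:
    """All knobs of the generator; the seed fully determines the output."""

    seed: int = 1
    n_luti: int = 30
    n_canonical: int = 30
    n_antisense: int = 10
    n_intergenic: int = 10
    n_intragenic: int = 10
    tl_depth: float = 1_000_000.0  # expected tags per TL-seq sample
    tl_replicates: int = 3
    chip_replicates: int = 3
    dispersion: float = 0.0  # NB dispersion of tag counts; 0 = deterministic
    chip_noise_sd: float = 0.0  # per-bp Gaussian noise on mark tracks
    footprint_depth: int = 1000  # scanning ribosomes per 5'-extended locus
    dyads_per_nucleosome: int = 1000
    reads_per_locus: int = 3  # long reads per spanning locus

    def validate(self) -> None:
        for name in ("n_luti", "n_canonical", "n_antisense", "n_intergenic", "n_intragenic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tl_depth <= 0:
            raise ValueError("tl_depth must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    @property
    def n_loci(self) -> int:
        return (
            self.n_luti + self.n_canonical + self.n_antisense
            + self.n_intergenic + self.n_intragenic
        )

    def sample_ids(self) -> Dict[str, List[str]]:
        return {
            tp: [f"{tp}_rep{r + 1}" for r in range(self.tl_replicates)]
            for tp in TIMEPOINTS
        }


@dataclass
class Study:
    """All modalities of one synthetic study, in memory."""

    config: SimConfig
    genome: Dict[str, str]
    genes: List[GeneModel]
    truth: pd.DataFrame
    #: tl[sample_id][strand] -> tag-count track
    tl: Dict[str, Dict[str, SignalTrack]]
    long_reads: List[LongReadSpan]
    footprints: Dict[str, SignalTrack]
    #: chip[(mark, timepoint, replicate_index)] -> fold-enrichment track
    chip: Dict[Tuple[str, str, int], SignalTrack]
    #: peaks[replicate_index] -> TF peak calls
    peaks: Dict[int, List[PeakRecord]]
    #: dyads[timepoint] -> dyad-count track
    dyads: Dict[str, SignalTrack]

    @property
    def samples(self) -> Dict[str, List[str]]:
        return self.config.sample_ids()

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        import yaml

        with open(os.path.join(outdir, "config.yaml"), "w") as fh:
            yaml.safe_dump(vars(self.config), fh, sort_keys=True)
        lio.write_fasta(self.genome, os.path.join(outdir, "genome.fa"))
        lio.write_gff3(self.genes, os.path.join(outdir, "annotation.gff3"))
        self.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
        tl_dir = os.path.join(outdir, "tlseq")
        os.makedirs(tl_dir, exist_ok=True)
        for sample, tracks in self.tl.items():
            lio.write_stranded_bedgraph(tracks, os.path.join(tl_dir, sample))
        lio.write_bed6(self.long_reads, os.path.join(outdir, "longreads.bed"))
        lio.write_stranded_bedgraph(self.footprints, os.path.join(outdir, "footprints"))
        chip_dir = os.path.join(outdir, "chip")
        os.makedirs(chip_dir, exist_ok=True)
        for (mark, tp, rep), track in self.chip.items():
            lio.write_bedgraph(track, os.path.join(chip_dir, f"{mark}_{tp}_rep{rep + 1}.bedgraph"))
        peak_dir = os.path.join(outdir, "peaks")
        os.makedirs(peak_dir, exist_ok=True)
        for rep, peaks in self.peaks.items():
            lio.write_narrowpeak(peaks, os.path.join(peak_dir, f"tf_rep{rep + 1}.narrowPeak"))
        mnase_dir = os.path.join(outdir, "mnase")
        os.makedirs(mnase_dir, exist_ok=True)
        for tp, track in self.dyads.items():
            lio.write_bedgraph(track, os.path.join(mnase_dir, f"{tp}.bedgraph"))


# ---------------------------------------------------------------------------
# locus geometry helpers (strand-aware offsets in transcript orientation)
# ---------------------------------------------------------------------------

def _upstream(anchor: int, dist: int, strand: str) -> int:
    return anchor - dist if strand == "+" else anchor + dist


def _downstream(anchor: int, dist: int, strand: str) -> int:
    return anchor + dist if strand == "+" else anchor - dist


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_study(config: SimConfig) -> Study:
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_loci
    bg_len = 200 * 13 + 100
    genome_len = 2 * _MARGIN + n * _SLOT + bg_len
    seq = rng.choice(list("ACGT"), size=genome_len)

    classes = (
        ["luti"] * config.n_luti
        + ["canonical"] * config.n_canonical
        + ["antisense"] * config.n_antisense
        + ["intergenic"] * config.n_intergenic
        + ["intragenic"] * config.n_intragenic
    )

    genes: List[GeneModel] = []
    rows: List[dict] = []
    rep_states = ("repressed", "intermediate", "non_repressed")
    fc_ranges = {
        "repressed": (0.05, 0.2),
        "intermediate": (0.3, 0.9),
        "non_repressed": (1.1, 2.0),
    }

    luti_counter = 0
    for i, cls in enumerate(classes):
        base = _MARGIN + i * _SLOT
        strand = "+" if i % 2 == 0 else "-"
        locus_id = f"{cls}_{i:03d}"
        cds_len = 3 * int(rng.integers(200, 501))  # 600..1500 bp
        if strand == "+":
            cds_start = base + 1600
            cds = GenomicInterval(_CHROM, cds_start, cds_start + cds_len, "+")
        else:
            cds_end = base + _SLOT - 1600
            cds = GenomicInterval(_CHROM, cds_end - cds_len, cds_end, "-")
        cds5 = cds.five_prime

        row = dict(
            locus_id=locus_id,
            gene_id="",
            cls=cls,
            chrom=_CHROM,
            strand=strand,
            distal_tss=-1,
            prox_tss=-1,
            cds_start=-1,
            cds_end=-1,
            n_uorfs=0,
            uorf_probs="",
            repression_state="",
            prox_tpm_pre=np.nan,
            prox_tpm_mei=np.nan,
            luti_tpm_mei=np.nan,
            mark_gain_k36=np.nan,
            mark_gain_k4=np.nan,
            plus_one_shift=np.nan,
            fuzziness_delta=np.nan,
            tf_bound=False,
        )

        if cls == "luti":
            state = rep_states[luti_counter % 3]
            luti_counter += 1
            lo, hi = fc_ranges[state]
            fc = float(rng.uniform(lo, hi))
            # repression scale in [0, 1]: 1 = fully repressed
            r = 1.0 - (fc - 0.05) / (2.0 - 0.05)
            prox_pre = float(rng.uniform(8.0, 25.0))
            prox_tss = _upstream(cds5, _PROX_OFFSET, strand)
            dist_d = int(rng.integers(600, 1001))
            distal_tss = _upstream(cds5, dist_d, strand)
            n_uorfs = int(rng.integers(4, 9))
            probs = rng.uniform(0.3, 0.7, size=n_uorfs)
            if state == "repressed":
                shift, fuzz = -15.0, 10.0
            elif state == "non_repressed":
                shift, fuzz = 0.0, 0.0
            else:
                shift, fuzz = float(np.round(-15.0 * r)), float(10.0 * r)
            row.update(
                gene_id=locus_id,
                distal_tss=distal_tss,
                prox_tss=prox_tss,
                cds_start=cds.start,
                cds_end=cds.end,
                n_uorfs=n_uorfs,
                uorf_probs=";".join(f"{p:.4f}" for p in probs),
                repression_state=state,
                prox_tpm_pre=prox_pre,
                prox_tpm_mei=prox_pre * fc,
                luti_tpm_mei=10.0 + 35.0 * r,
                mark_gain_k36=1.0 + 3.0 * r,
                mark_gain_k4=1.0 + (0.5 * r if fc < 0.25 else 0.0),
                plus_one_shift=shift,
                fuzziness_delta=fuzz,
                tf_bound=True,
            )
            genes.append(GeneModel(locus_id, cds))
        elif cls == "canonical":
            tss = _upstream(cds5, _PROX_OFFSET, strand)
            row.update(
                gene_id=locus_id, distal_tss=tss,
                cds_start=cds.start, cds_end=cds.end,
            )
            genes.append(GeneModel(locus_id, cds))
        elif cls == "antisense":
            host_strand = strand
            as_strand = "-" if strand == "+" else "+"
            mid = (cds.start + cds.end) // 2
            row.update(
                gene_id=locus_id, strand=as_strand, distal_tss=mid,
                cds_start=cds.start, cds_end=cds.end,
            )
            genes.append(GeneModel(locus_id + "_host", cds))
        elif cls == "intragenic":
            tss = _downstream(cds5, 300, strand)
            row.update(
                gene_id=locus_id, distal_tss=tss,
                cds_start=cds.start, cds_end=cds.end,
            )
            genes.append(GeneModel(locus_id + "_host", cds))
        else:  # intergenic: no gene in this slot
            row.update(distal_tss=base + 2000)
        rows.append(row)

    truth_columns = [
        "locus_id", "gene_id", "cls", "chrom", "strand", "distal_tss", "prox_tss",
        "cds_start", "cds_end", "n_uorfs", "uorf_probs", "repression_state",
        "prox_tpm_pre", "prox_tpm_mei", "luti_tpm_mei", "mark_gain_k36",
        "mark_gain_k4", "plus_one_shift", "fuzziness_delta", "tf_bound",
    ]
    truth = pd.DataFrame(rows, columns=truth_columns)

    _plant_uorfs(seq, truth, rng)
    genome = {_CHROM: "".join(seq)}

    tl = _make_tl_tracks(config, truth, rng)
    long_reads = _make_long_reads(config, truth, rng)
    footprints = _make_footprints(config, truth, rng)
    chip = _make_chip_tracks(config, truth, rng)
    peaks = _make_peaks(config, truth)
    dyads = _make_dyads(config, truth, rng)

    return Study(
        config=config, genome=genome, genes=genes, truth=truth,
        tl=tl, long_reads=long_reads, footprints=footprints,
        chip=chip, peaks=peaks, dyads=dyads,
    )


# -- genome sequence: exact uORF counts in leaders --------------------------

def _plant_uorfs(seq: np.ndarray, truth: pd.DataFrame, rng: np.random.Generator) -> None:
    """Scrub all sense-strand ATGs from each 5'-extension leader, then
    insert exactly the planted number at evenly spaced starts."""
    for row in truth.itertuples():
        if row.cls != "luti":
            continue
        strand = row.strand
        distal, prox = int(row.distal_tss), int(row.prox_tss)
        lo, hi = (distal, prox) if strand == "+" else (prox + 1, distal + 1)
        _scrub_atgs(seq, lo, hi, strand, rng)
        n = int(row.n_uorfs)
        leader_len = hi - lo
        spacing = (leader_len - 60) // max(n, 1)
        starts = []  # strand-aware ATG start (position of the A base)
        for k in range(n):
            off = 30 + k * spacing
            starts.append(distal + off if strand == "+" else distal - off)
        for start in starts:
            if strand == "+":
                seq[start : start + 3] = list("ATG")
            else:
                seq[start - 2 : start + 1] = list("CAT")
        # planting may create accidental extra ATGs at insert boundaries
        _scrub_atgs(seq, lo, hi, strand, rng, protect=set(starts))


def _scrub_atgs(
    seq: np.ndarray,
    lo: int,
    hi: int,
    strand: str,
    rng: np.random.Generator,
    protect: Optional[set] = None,
) -> None:
    protect = protect or set()
    motif = "ATG" if strand == "+" else "CAT"
    # genome index of the codon's first stored base for a protected start
    for _ in range(10):  # converges quickly; guard against pathological loops
        segment = "".join(seq[lo:hi])
        changed = False
        idx = segment.find(motif)
        while idx != -1:
            gpos = lo + idx
            start_pos = gpos if strand == "+" else gpos + 2
            if start_pos not in protect:
                # mutate the middle base to a non-creating letter
                seq[gpos + 1] = "C" if strand == "+" else "G"
                changed = True
            idx = segment.find(motif, idx + 1)
        if not changed:
            return


# -- TL-seq ------------------------------------------------------------------

def _planted_tss_tpm(truth: pd.DataFrame) -> List[Tuple[int, str, float, float]]:
    """(position, strand, tpm_pre, tpm_mei) for every planted promoter."""
    out: List[Tuple[int, str, float, float]] = []
    for row in truth.itertuples():
        if row.cls == "luti":
            out.append((int(row.distal_tss), row.strand, 0.0, float(row.luti_tpm_mei)))
            out.append((int(row.prox_tss), row.strand, float(row.prox_tpm_pre), float(row.prox_tpm_mei)))
        elif row.cls == "canonical":
            out.append((int(row.distal_tss), row.strand, 0.3, 25.0))
        else:
            out.append((int(row.distal_tss), row.strand, 0.2, 15.0))
    return out


def _make_tl_tracks(
    config: SimConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> Dict[str, Dict[str, SignalTrack]]:
    planted = _planted_tss_tpm(truth)
    tpm_by_tp = {"pre": [p[2] for p in planted], "mei": [p[3] for p in planted]}
    bg_start = _MARGIN + config.n_loci * _SLOT + 50
    bg_positions = [bg_start + 13 * k for k in range(200)]

    tracks: Dict[str, Dict[str, SignalTrack]] = {}
    for tp in TIMEPOINTS:
        planted_total = float(np.sum(tpm_by_tp[tp]))
        bg_total = max(1e6 - planted_total, 0.0)
        bg_each = bg_total / len(bg_positions)
        for rep in range(config.tl_replicates):
            sample = f"{tp}_rep{rep + 1}"
            plus = SignalTrack("+", units="tags", sample_id=sample, timepoint=tp)
            minus = SignalTrack("-", units="tags", sample_id=sample, timepoint=tp)
            for (pos, strand, _, _), tpm in zip(planted, tpm_by_tp[tp]):
                if tpm <= 0:
                    continue
                track = plus if strand == "+" else minus
                expected = tpm * config.tl_depth / 1e6 * _JITTER_WEIGHTS
                counts = _nb_draw(expected, config.dispersion, rng)
                for off, c in zip(_JITTER_OFFSETS, counts):
                    if c > 0:
                        track.add(_CHROM, pos + int(off), float(c))
            # constant background pool keeps realized TPM on the planted scale
            bg_count = bg_each * config.tl_depth / 1e6
            for pos in bg_positions:
                plus.add(_CHROM, pos, bg_count)
            tracks[sample] = {"+": plus, "-": minus}
    return tracks


def _nb_draw(expected: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    if dispersion <= 0:
        return expected
    r = 1.0 / dispersion
    out = np.zeros_like(expected)
    mask = expected > 0
    p = r / (r + expected[mask])
    out[mask] = rng.negative_binomial(r, p)
    return out


# -- long reads --------------------------------------------------------------

def _make_long_reads(
    config: SimConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> List[LongReadSpan]:
    reads: List[LongReadSpan] = []
    for row in truth.itertuples():
        if row.cls not in ("luti", "canonical"):
            continue
        strand = row.strand
        for k in range(config.reads_per_locus):
            jitter = int(rng.integers(-3, 4))
            fp = int(row.distal_tss) + jitter
            over = int(rng.integers(10, 40))
            if strand == "+":
                iv = GenomicInterval(row.chrom, fp, int(row.cds_end) + over, "+")
            else:
                iv = GenomicInterval(row.chrom, int(row.cds_start) - over, fp + 1, "-")
            reads.append(LongReadSpan(iv, f"{row.locus_id}_read{k}"))
    return reads


# -- ribosome footprints -----------------------------------------------------

def simulate_footprints(
    uorf_starts: Sequence[int],
    init_probs: Sequence[float],
    depth: int,
    strand: str,
    chrom: str,
    rng: np.random.Generator,
    track: Optional[SignalTrack] = None,
) -> SignalTrack:
    """Leaky-scanning footprint counts for one leader.

    Each of ``depth`` scanning ribosomes initiates at uORF *i* with
    probability ``init_probs[i]`` conditioned on not having initiated at
    any upstream uORF; an initiating ribosome deposits one count at a
    uniform position within that uORF's first 6 codons (18 nt).
    """
    probs = np.asarray(init_probs, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("initiation probabilities must lie in [0, 1]")
    if len(uorf_starts) != len(probs):
        raise ValueError("uorf_starts and init_probs length mismatch")
    if track is None:
        track = SignalTrack(strand, units="footprints")
    remaining = int(depth)
    for start, p in zip(uorf_starts, probs):
        if remaining == 0:
            break
        n_init = int(rng.binomial(remaining, p)) if 0 < p < 1 else int(remaining * p)
        remaining -= n_init
        if n_init == 0:
            continue
        offsets = rng.integers(0, 18, size=n_init)
        for off in offsets:
            pos = start + int(off) if strand == "+" else start - int(off)
            track.add(chrom, pos, 1.0)
    return track


def _make_footprints(
    config: SimConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> Dict[str, SignalTrack]:
    plus = SignalTrack("+", units="footprints")
    minus = SignalTrack("-", units="footprints")
    for row in truth.itertuples():
        if row.cls != "luti" or not row.uorf_probs:
            continue
        probs = [float(x) for x in row.uorf_probs.split(";")]
        starts = _uorf_starts_from_truth(row)
        simulate_footprints(
            starts, probs, config.footprint_depth, row.strand, row.chrom, rng,
            track=plus if row.strand == "+" else minus,
        )
    return {"+": plus, "-": minus}


def _uorf_starts_from_truth(row) -> List[int]:
    """Recompute the planted uORF start positions for a truth row."""
    strand = row.strand
    distal, prox = int(row.distal_tss), int(row.prox_tss)
    leader_len = abs(prox - distal)
    n = int(row.n_uorfs)
    spacing = (leader_len - 60) // max(n, 1)
    starts = []
    for k in range(n):
        off = 30 + k * spacing
        starts.append(distal + off if strand == "+" else distal - off)
    return starts


# -- ChIP marks and TF peaks -------------------------------------------------

def _make_chip_tracks(
    config: SimConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> Dict[Tuple[str, str, int], SignalTrack]:
    tracks: Dict[Tuple[str, str, int], SignalTrack] = {}
    gain_col = {"H3K36me3": "mark_gain_k36", "H3K4me2": "mark_gain_k4"}
    luti = truth[truth.cls == "luti"]
    for mark in MARKS:
        for tp in TIMEPOINTS:
            for rep in range(config.chip_replicates):
                track = SignalTrack(".", units="fold_enrichment", timepoint=tp)
                for row in luti.itertuples():
                    tss, strand = int(row.prox_tss), row.strand
                    gain = float(getattr(row, gain_col[mark])) if tp == "mei" else 1.0
                    if strand == "+":
                        up = (tss - 600, tss)
                        down = (tss, tss + 600)
                    else:
                        up = (tss + 1, tss + 601)
                        down = (tss - 599, tss + 1)
                    _fill_noisy(track, row.chrom, up, 1.0, config.chip_noise_sd, rng)
                    _fill_noisy(track, row.chrom, down, gain, config.chip_noise_sd, rng)
                tracks[(mark, tp, rep)] = track
    return tracks


def _fill_noisy(
    track: SignalTrack,
    chrom: str,
    span: Tuple[int, int],
    value: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> None:
    start, end = span
    if noise_sd > 0:
        vals = np.clip(rng.normal(value, noise_sd, size=end - start), 0.0, None)
        for pos, v in zip(range(start, end), vals):
            track.add(chrom, pos, float(v))
    else:
        track.set_interval(chrom, start, end, value)


def _make_peaks(config: SimConfig, truth: pd.DataFrame) -> Dict[int, List[PeakRecord]]:
    peaks: Dict[int, List[PeakRecord]] = {rep: [] for rep in range(config.chip_replicates)}
    for row in truth.itertuples():
        if row.cls != "luti" or not row.tf_bound:
            continue
        tss = int(row.distal_tss)
        iv = GenomicInterval(row.chrom, tss - 100, tss + 100, ".")
        for rep in range(config.chip_replicates):
            peaks[rep].append(
                PeakRecord(
                    interval=iv, name=f"{row.locus_id}_peak", score=100,
                    enrichment=8.0, p_value=8.0, q_value=5.0, summit=tss,
                )
            )
    return peaks


# -- MNase dyads -------------------------------------------------------------

#: transcript-oriented dyad offsets of the planted array around the prox TSS
_NUC_OFFSETS = {"-1": -150, "+1": 60, "+2": 225, "+3": 390}
_NUC_SD = 15.0


def _make_dyads(
    config: SimConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> Dict[str, SignalTrack]:
    out: Dict[str, SignalTrack] = {}
    luti = truth[truth.cls == "luti"]
    for tp in TIMEPOINTS:
        track = SignalTrack(".", units="dyads", timepoint=tp)
        for row in luti.itertuples():
            tss, strand = int(row.prox_tss), row.strand
            for label, off in _NUC_OFFSETS.items():
                mean_off, sd = float(off), _NUC_SD
                if tp == "mei" and label == "+1":
                    mean_off += float(row.plus_one_shift)
                    sd += float(row.fuzziness_delta)
                center = _downstream(tss, 0, strand)
                mean = center + mean_off if strand == "+" else center - mean_off
                draws = np.rint(rng.normal(mean, sd, size=config.dyads_per_nucleosome))
                pos, counts = np.unique(draws.astype(int), return_counts=True)
                for p, c in zip(pos, counts):
                    track.add(row.chrom, int(p), float(c))
        out[tp] = track
    return out


# ---------------------------------------------------------------------------
# config / study file support
# ---------------------------------------------------------------------------

def load_config(path: str) -> SimConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimConfig(**data)


def load_study(outdir: str) -> Study:
    """Read a study directory written by :meth:`Study.write` back into
    memory, so the file-based CLI can run any downstream stage."""
    config_path = os.path.join(outdir, "config.yaml")
    config = load_config(config_path) if os.path.exists(config_path) else SimConfig()

    genome = lio.read_fasta(os.path.join(outdir, "genome.fa"))
    genes = lio.read_gff3(os.path.join(outdir, "annotation.gff3"))
    truth_path = os.path.join(outdir, "truth.tsv")
    truth = (
        pd.read_csv(truth_path, sep="\t")
        if os.path.exists(truth_path) and os.path.getsize(truth_path) > 1
        else pd.DataFrame()
    )

    tl: Dict[str, Dict[str, SignalTrack]] = {}
    tl_dir = os.path.join(outdir, "tlseq")
    for name in sorted(os.listdir(tl_dir)):
        if name.endswith(".plus.bedgraph"):
            sample = name[: -len(".plus.bedgraph")]
            tl[sample] = lio.read_stranded_bedgraph(os.path.join(tl_dir, sample))

    long_reads = lio.read_bed6(os.path.join(outdir, "longreads.bed"))
    footprints = lio.read_stranded_bedgraph(os.path.join(outdir, "footprints"))

    chip: Dict[Tuple[str, str, int], SignalTrack] = {}
    chip_dir = os.path.join(outdir, "chip")
    if os.path.isdir(chip_dir):
        for name in sorted(os.listdir(chip_dir)):
            if not name.endswith(".bedgraph"):
                continue
            mark, tp, rep_tag = name[: -len(".bedgraph")].rsplit("_", 2)
            chip[(mark, tp, int(rep_tag[3:]) - 1)] = lio.read_bedgraph(
                os.path.join(chip_dir, name)
            )

    peaks: Dict[int, List[PeakRecord]] = {}
    peak_dir = os.path.join(outdir, "peaks")
    if os.path.isdir(peak_dir):
        for name in sorted(os.listdir(peak_dir)):
            if name.endswith(".narrowPeak"):
                rep = int(name[: -len(".narrowPeak")].rsplit("rep", 1)[1]) - 1
                peaks[rep] = lio.read_narrowpeak(os.path.join(peak_dir, name))

    dyads: Dict[str, SignalTrack] = {}
    mnase_dir = os.path.join(outdir, "mnase")
    if os.path.isdir(mnase_dir):
        for name in sorted(os.listdir(mnase_dir)):
            if name.endswith(".bedgraph"):
                dyads[name[: -len(".bedgraph")]] = lio.read_bedgraph(
                    os.path.join(mnase_dir, name)
                )

    return Study(
        config=config, genome=genome, genes=genes, truth=truth,
        tl=tl, long_reads=long_reads, footprints=footprints,
        chip=chip, peaks=peaks, dyads=dyads,
    )
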