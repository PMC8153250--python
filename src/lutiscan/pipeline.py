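"""End-to-end orchestration on in-memory study objects.

Glues the stages together: tag clustering/quantification, isoform
discovery, uORF profiling, promoter chromatin scoring, nucleosome
features, and the per-gene feature table for the correlation analysis.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import chromatin as chrom_mod
from . import clustering as clu
from . import nucleosome as nuc_mod
from . import stats as stats_mod
from . import uorf as uorf_mod
from .clustering import TssCluster
from .core import GeneModel, LongReadSpan, SignalTrack
from .discovery import LocusCall, discover
from .simulate import MARKS, Study


def cluster_study(
    tl: Mapping[str, Mapping[str, SignalTrack]],
    mode: str = "strict",
    aggregate: bool = True,
) -> List[TssCluster]:
    """CTSS assembly -> TPM -> clustering (strict or permissive)."""
    positions = clu.build_ctss(tl)
    clu.normalize_tpm(positions)
    params = clu.STRICT if mode == "strict" else clu.PERMISSIVE
    clusters = clu.cluster_ctss(positions, **params)
    if aggregate and mode == "strict":
        clusters = clu.aggregate_clusters(clusters, **clu.AGGREGATE)
    return clusters


def run_discovery(
    study: Study,
    near_window: int = 50,
    pseudocount: float = 0.1,
) -> Tuple[List[LocusCall], List[TssCluster]]:
    """Strict clustering plus the full discovery cascade."""
    promoters = cluster_study(study.tl, mode="strict")
    samples = study.samples
    calls = discover(
        promoters, study.genes, study.long_reads,
        samples_pre=samples["pre"], samples_mei=samples["mei"],
        pseudocount=pseudocount, near_window=near_window,
    )
    return calls, promoters


def _cluster_containing(
    clusters: Sequence[TssCluster], chrom: str, pos: int, strand: str
) -> Optional[TssCluster]:
    for cl in clusters:
        if cl.chrom == chrom and cl.strand == strand and cl.start <= pos <= cl.end:
            return cl
    return None


def quantify_isoforms(
    study: Study,
    calls: Sequence[LocusCall],
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Permissive-mode quantification of distal/proximal isoforms for
    5'-extension calls: per-timepoint mean TPM, fold change, log2 FC,
    and repression class."""
    permissive = cluster_study(study.tl, mode="permissive")
    samples = study.samples
    rows = []
    for call in calls:
        if call.cls != "luti_candidate":
            continue
        prox_cl = _cluster_containing(permissive, call.chrom, call.prox_tss, call.strand)
        dist_cl = _cluster_containing(permissive, call.chrom, call.distal_tss, call.strand)
        if prox_cl is None or dist_cl is None:
            continue
        prox_pre = prox_cl.mean_tpm(samples["pre"])
        prox_mei = prox_cl.mean_tpm(samples["mei"])
        luti_mei = dist_cl.mean_tpm(samples["mei"])
        lfc = float(np.log2((prox_mei + pseudocount) / (prox_pre + pseudocount)))
        rows.append(
            dict(
                gene_id=call.gene_id,
                chrom=call.chrom,
                strand=call.strand,
                distal_tss=call.distal_tss,
                prox_tss=call.prox_tss,
                prox_tpm_pre=prox_pre,
                prox_tpm_mei=prox_mei,
                luti_tpm=luti_mei,
                prox_fc=prox_mei / prox_pre if prox_pre > 0 else np.nan,
                prox_log2fc=lfc,
                repression_class=stats_mod.classify_repression(prox_pre, prox_mei) or "",
            )
        )
    return pd.DataFrame(rows)


def uorf_profiles(
    study: Study, calls: Sequence[LocusCall], min_reads: float = 4.0
) -> List[uorf_mod.UorfProfile]:
    profiles = []
    for call in calls:
        if call.cls != "luti_candidate":
            continue
        fp = study.footprints.get(call.strand)
        profiles.append(
            uorf_mod.profile_from_call(
                study.genome, call.gene_id, call.chrom,
                call.distal_tss, call.prox_tss, call.strand,
                footprints=fp, min_reads=min_reads,
            )
        )
    return profiles


def promoter_chromatin_table(
    study: Study, calls: Sequence[LocusCall]
) -> pd.DataFrame:
    """Replicate-mean promoter mark fold changes per 5'-extension gene."""
    rows = []
    n_rep = study.config.chip_replicates
    for call in calls:
        if call.cls != "luti_candidate":
            continue
        row: Dict[str, object] = dict(gene_id=call.gene_id)
        for mark in MARKS:
            ratios = {"pre": [], "mei": []}
            for tp in ("pre", "mei"):
                for rep in range(n_rep):
                    track = study.chip[(mark, tp, rep)]
                    _, _, ratio = chrom_mod.promoter_mark_score(
                        track, call.chrom, call.prox_tss, call.strand
                    )
                    ratios[tp].append(ratio)
            fc = chrom_mod.mark_fold_change(ratios["pre"], ratios["mei"])
            row[f"{mark.lower()}_fc"] = fc if fc is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def nucleosome_feature_table(
    study: Study,
    calls: Sequence[LocusCall],
    smoothing_bw: float = 15.0,
    min_spacing: int = 120,
    min_occupancy: float = 20.0,
) -> pd.DataFrame:
    """+1/-1 shift and fuzziness-change features per 5'-extension gene."""
    nuc_calls = {
        tp: nuc_mod.call_nucleosomes(track, smoothing_bw, min_spacing, min_occupancy)
        for tp, track in study.dyads.items()
    }
    rows = []
    for call in calls:
        if call.cls != "luti_candidate":
            continue
        flanks = {
            tp: nuc_mod.assign_flanking(nuc_calls[tp], call.gene_id, call.chrom,
                                        call.prox_tss, call.strand)
            for tp in ("pre", "mei")
        }
        p1_shift, p1_fuzz = nuc_mod.nucleosome_shift(flanks["pre"], flanks["mei"], call.strand, "plus_one")
        m1_shift, m1_fuzz = nuc_mod.nucleosome_shift(flanks["pre"], flanks["mei"], call.strand, "minus_one")
        rows.append(
            dict(
                gene_id=call.gene_id,
                plus_one_shift=np.nan if p1_shift is None else p1_shift,
                plus_one_fuzziness_change=np.nan if p1_fuzz is None else p1_fuzz,
                minus_one_shift=np.nan if m1_shift is None else m1_shift,
                minus_one_fuzziness_change=np.nan if m1_fuzz is None else m1_fuzz,
            )
        )
    return pd.DataFrame(rows)


def tf_target_table(study: Study, calls: Sequence[LocusCall]) -> pd.DataFrame:
    peaks_by_rep = [study.peaks[r] for r in sorted(study.peaks)]
    rows = []
    for call in calls:
        if call.cls not in ("luti_candidate", "canonical"):
            continue
        tc = chrom_mod.tf_target_call(
            peaks_by_rep, call.gene_id or "", call.chrom, call.distal_tss
        )
        rows.append(dict(gene_id=tc.gene_id, tss=tc.tss, is_target=tc.is_target))
    return pd.DataFrame(rows)


def assemble_features(
    study: Study,
    calls: Optional[Sequence[LocusCall]] = None,
) -> pd.DataFrame:
    """Per-gene feature table for the repression correlation analysis."""
    if calls is None:
        calls, _ = run_discovery(study)
    quant = quantify_isoforms(study, calls)
    chrom_tab = promoter_chromatin_table(study, calls)
    nuc_tab = nucleosome_feature_table(study, calls)
    genes_by_id = {g.gene_id: g for g in study.genes}

    luti_calls = [c for c in calls if c.cls == "luti_candidate"]
    base = pd.DataFrame(
        [
            dict(
                gene_id=c.gene_id,
                tss_distance=abs(c.distal_tss - c.prox_tss),
                cds_length=len(genes_by_id[c.gene_id].cds) if c.gene_id in genes_by_id else np.nan,
            )
            for c in luti_calls
        ]
    )
    out = base
    for tab in (quant, chrom_tab, nuc_tab):
        if not tab.empty:
            out = out.merge(tab, on="gene_id", how="left")
    return out
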