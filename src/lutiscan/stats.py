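"""Repression classification and feature statistics.

Spearman correlation is computed as the Pearson correlation of
mid-ranks, with an exact permutation p-value at small n and the usual
t approximation otherwise. The paired signed-rank test uses the exact
null distribution (dynamic programming over rank sums) for n <= 25 and
a continuity-corrected normal approximation beyond that.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm, rankdata

REPRESSED_FC = 0.25
NON_REPRESSED_FC = 1.0

#: features fed to the correlation cluster map, in canonical order
FEATURE_COLUMNS = [
    "prox_log2fc",
    "luti_tpm",
    "h3k36me3_fc",
    "h3k4me2_fc",
    "plus_one_shift",
    "plus_one_fuzziness_change",
    "minus_one_shift",
    "minus_one_fuzziness_change",
    "tss_distance",
    "cds_length",
]


def classify_repression(prox_tpm_pre: float, prox_tpm_mei: float) -> Optional[str]:
    """repressed if FC < 0.25, non_repressed if FC > 1, else intermediate.

    FC = meiotic / premeiotic proximal-isoform TPM; None (undefined)
    when the premeiotic abundance is zero.
    """
    if prox_tpm_pre < 0 or prox_tpm_mei < 0:
        raise ValueError("TPM must be non-negative")
    if prox_tpm_pre == 0:
        return None
    fc = prox_tpm_mei / prox_tpm_pre
    if fc < REPRESSED_FC:
        return "repressed"
    if fc > NON_REPRESSED_FC:
        return "non_repressed"
    return "intermediate"


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 10
) -> Tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    Missing pairs (NaN in either vector) are dropped. rho is the
    Pearson correlation of mid-ranks. For n <= ``exact_max_n`` the
    p-value is an exact permutation tail; otherwise the t
    approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    rx = rankdata(x)
    ry = rankdata(y)
    sx, sy = np.std(rx), np.std(ry)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in ranks; rho undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        p = _exact_perm_pvalue(rx, ry, rho)
    else:
        t = rho * np.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
        from scipy.stats import t as t_dist

        p = float(2 * t_dist.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def _exact_perm_pvalue(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p-value for the rank correlation.

    With rank vectors fixed, rho is monotone in sum(rx * ry_perm), so
    tail counting reduces to dot products over all n! permutations
    (enumerated in chunks to bound memory).
    """
    n = len(rx)
    mx, my = rx.mean(), ry.mean()
    obs = abs(float(np.dot(rx, ry)) - n * mx * my)
    total = 0
    extreme = 0
    perms = itertools.permutations(range(n))
    chunk_size = 200_000
    tol = 1e-9
    while True:
        chunk = list(itertools.islice(perms, chunk_size))
        if not chunk:
            break
        idx = np.array(chunk, dtype=np.int8)
        s = ry[idx] @ rx
        dev = np.abs(s - n * mx * my)
        extreme += int(np.sum(dev >= obs - tol))
        total += len(chunk)
    return extreme / total


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# correlation cluster map
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    features: List[str]
    rho: pd.DataFrame  # symmetric, unit diagonal
    p: pd.DataFrame
    leaf_order: List[str]


def correlation_clustermap(
    rows: pd.DataFrame,
    features: Optional[Sequence[str]] = None,
    min_pairs: int = 3,
) -> CorrelationResult:
    """Pairwise-complete Spearman matrix with average-linkage clustering
    on distance 1 - rho; features lacking enough complete pairs are
    dropped with a warning."""
    import warnings

    if features is None:
        features = [c for c in FEATURE_COLUMNS if c in rows.columns]
    usable: List[str] = []
    for f in features:
        col = pd.to_numeric(rows[f], errors="coerce")
        if col.notna().sum() >= min_pairs and col.dropna().nunique() > 1:
            usable.append(f)
        else:
            warnings.warn(f"feature {f!r} dropped: insufficient complete pairs")
    k = len(usable)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            xi = pd.to_numeric(rows[usable[i]], errors="coerce").to_numpy()
            yj = pd.to_numeric(rows[usable[j]], errors="coerce").to_numpy()
            r, p = spearman(xi, yj)
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    dist = np.clip(1.0 - rho, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    if k > 1:
        z = linkage(squareform(dist, checks=False), method="average")
        order = [usable[i] for i in leaves_list(z)]
    else:
        order = list(usable)
    rho_df = pd.DataFrame(rho, index=usable, columns=usable)
    p_df = pd.DataFrame(pmat, index=usable, columns=usable)
    return CorrelationResult(features=list(usable), rho=rho_df, p=p_df, leaf_order=order)


# ---------------------------------------------------------------------------
# paired Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def paired_wilcoxon(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 25
) -> Tuple[float, float]:
    """Two-sided signed-rank test on paired samples.

    Zero differences are dropped. For n <= ``exact_max_n`` the exact
    null distribution of the positive-rank sum is used; otherwise a
    normal approximation with continuity and tie correction. Returns
    (W+, p); all-zero differences give (0, 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = y - x
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _exact_signed_rank_pvalue(ranks, w_plus)
    else:
        mean = n * (n + 1) / 4.0
        tie_sizes = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_sizes**3 - tie_sizes) / 48.0
        diff = w_plus - mean
        # continuity correction toward the mean
        cc = 0.5 * np.sign(diff)
        z = (diff - cc) / np.sqrt(var) if var > 0 else 0.0
        p = float(2 * norm.sf(abs(z)))
    return w_plus, min(p, 1.0)


def _exact_signed_rank_pvalue(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided tail of W+ over all 2^n sign assignments.

    Ranks are doubled so mid-ranks become integers; the distribution is
    built by convolution over items.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: len(counts) - r]
        counts = counts + shifted
    n = len(ranks)
    w2 = int(round(2 * w_plus))
    mean2 = total / 2.0
    dev = abs(w2 - mean2)
    sums = np.arange(total + 1)
    extreme = counts[np.abs(sums - mean2) >= dev - 1e-9].sum()
    return float(extreme / 2.0**n)
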