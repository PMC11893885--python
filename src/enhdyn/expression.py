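"""Expression quantification, differential expression, temporal clustering.

Counts are strand-specific tag totals per region.  Normalization adds a
prior count (default 0.25) and converts to counts per million over the
prior-adjusted library size, then log2.  The temporal test is a
negative-binomial likelihood-ratio ANOVA across timepoints with a
moment-based dispersion estimate shrunk toward the global median, followed
by Benjamini-Hochberg FDR.  Differentially expressed features are grouped
into four temporal clusters by k-means on z-scored profiles, relabeled
deterministically as 1: down from Day 3, 2: down at Day 6, 3: up from
Day 3, 4: up at Day 6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from enhdyn.io import SampleMetadata, TIMEPOINTS
from enhdyn.regions import GenomicRegion, nearest_region


# ---------------------------------------------------------------------------
# Counting and normalization


def count_tags(
    ctss_tables: Mapping[str, pd.DataFrame],
    regions: Sequence[GenomicRegion],
    strand_specific: bool = True,
) -> pd.DataFrame:
    """Region x sample raw tag counts.

    A tag at position p on strand s contributes to region r iff
    start <= p < end and, when ``strand_specific``, s matches r's strand.
    Unstranded regions (enhancers) always sum both strands.
    """
    index = [r.id for r in regions]
    out = pd.DataFrame(0, index=index, columns=list(ctss_tables), dtype=int)
    for sid, ctss in ctss_tables.items():
        if ctss.empty:
            continue
        # per (chrom, strand) sorted positions with cumulative counts
        lookup: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for (chrom, strand), g in ctss.groupby(["chrom", "strand"]):
            g = g.sort_values("pos")
            pos = g["pos"].to_numpy()
            csum = np.concatenate([[0], np.cumsum(g["count"].to_numpy())])
            lookup[(chrom, strand)] = (pos, csum)

        col = np.zeros(len(regions), dtype=int)
        for i, r in enumerate(regions):
            strands = ("+", "-") if (r.strand == "." or not strand_specific) \
                else (r.strand,)
            total = 0
            for s in strands:
                entry = lookup.get((r.chrom, s))
                if entry is None:
                    continue
                pos, csum = entry
                lo = np.searchsorted(pos, r.start, side="left")
                hi = np.searchsorted(pos, r.end, side="left")
                total += int(csum[hi] - csum[lo])
            col[i] = total
        out[sid] = col
    return out


@dataclass
class ExpressionMatrix:
    """CPM and log2 CPM with the prior count used to build them."""

    cpm: pd.DataFrame
    log2_cpm: pd.DataFrame
    prior_count: float


def cpm_normalize(counts: pd.DataFrame, prior: float = 0.25) -> ExpressionMatrix:
    """CPM_ij = 1e6 * (c_ij + prior) / sum_i (c_ij + prior), then log2.

    Per-sample CPM columns sum to 1e6 by construction.
    """
    if counts.shape[0] < 1:
        raise ValueError("need at least one feature")
    adj = counts.astype(float) + prior
    libsize = adj.sum(axis=0)
    if (libsize <= 0).any():
        raise ValueError("all-zero library with zero prior count")
    cpm = adj.div(libsize, axis=1) * 1e6
    return ExpressionMatrix(cpm=cpm, log2_cpm=np.log2(cpm), prior_count=prior)


def filter_expressed(
    expr: ExpressionMatrix | pd.DataFrame,
    threshold_log2cpm: float,
    min_samples: int = 1,
) -> list[str]:
    """Features with log2 CPM strictly above the threshold in >= min_samples."""
    log2 = expr.log2_cpm if isinstance(expr, ExpressionMatrix) else expr
    if not np.isfinite(threshold_log2cpm):
        raise ValueError("threshold must be finite")
    if min_samples > log2.shape[1]:
        raise ValueError("min_samples exceeds the number of samples")
    keep = (log2 > threshold_log2cpm).sum(axis=1) >= min_samples
    return list(log2.index[keep])


# ---------------------------------------------------------------------------
# Differential expression: NB likelihood-ratio ANOVA


def _nb_fit_mean(y: np.ndarray, s: np.ndarray, phi: np.ndarray,
                 n_iter: int = 50) -> np.ndarray:
    """Per-feature NB mean level via Fisher scoring with offsets.

    y: (F, n) counts; s: (n,) relative library sizes; phi: (F,) dispersions.
    Returns beta (F,) with mu_ij = s_j * exp(beta_i).
    """
    tot = y.sum(axis=1)
    beta = np.log(np.maximum(tot, 0.5) / s.sum())
    phi = phi[:, None]
    for _ in range(n_iter):
        mu = s[None, :] * np.exp(beta)[:, None]
        denom = 1.0 + phi * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = np.where(info > 0, score / np.maximum(info, 1e-12), 0.0)
        beta = beta + np.clip(step, -5, 5)
    return beta


def _nb_ll_part(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Mean-dependent part of the NB log-likelihood, summed over samples."""
    phi = phi[:, None]
    mu = np.maximum(mu, 1e-12)
    return (y * np.log(phi * mu) - (y + 1.0 / phi) * np.log1p(phi * mu)).sum(axis=1)


def estimate_dispersion(counts: pd.DataFrame, group: Sequence[str],
                        prior_df: float = 20.0) -> pd.Series:
    """Moment-based NB dispersion, shrunk toward a global estimate.

    Per feature, the pooled within-group variance of library-size-adjusted
    counts in excess of the Poisson part estimates phi * mu^2.  The global
    shrinkage center is a ratio-of-sums estimator with the squared-mean
    term corrected for sampling variance of the group means (the naive
    per-feature ratio is biased downward at few replicates).  Per-feature
    raw estimates are averaged in with ``resid_df`` worth of weight
    against ``prior_df`` for the global value.
    """
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    s = lib / np.exp(np.mean(np.log(np.maximum(lib, 1.0))))
    yadj = y / s[None, :]
    group = np.asarray(group)
    levels = pd.unique(group)
    n, G = y.shape[1], len(levels)
    resid_df = max(n - G, 1)

    ss = np.zeros(len(y))
    pois = np.zeros(len(y))
    musq = np.zeros(len(y))
    for g in levels:
        sel = group == g
        m = yadj[:, sel].mean(axis=1)
        ss += ((yadj[:, sel] - m[:, None]) ** 2).sum(axis=1)
        pois += m * (1.0 / s[sel]).mean() * sel.sum()
        musq += m**2 * sel.sum()
    v = ss / resid_df
    pois /= n
    musq /= n
    # correct E[mean^2] for the variance of the group means
    musq_u = np.maximum(musq - (G / n) * v, 0.0)
    excess = v - pois

    expressed = musq_u > 0
    denom = musq_u[expressed].sum()
    global_phi = float(np.clip(excess[expressed].sum() / denom, 1e-6, 10.0)) \
        if denom > 0 else 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = excess / np.maximum(musq_u, 1e-12)
    raw = np.clip(np.nan_to_num(raw, nan=global_phi), 0.0, 10.0)
    shrunk = (prior_df * global_phi + resid_df * raw) / (prior_df + resid_df)
    return pd.Series(np.maximum(shrunk, 1e-6), index=counts.index)


def de_test(counts: pd.DataFrame, group: Sequence[str],
            alpha: float = 0.05, prior_df: float = 20.0) -> pd.DataFrame:
    """ANOVA-like test for a timepoint effect on NB counts.

    Likelihood-ratio test of group-specific means against a common mean,
    with fixed moderated dispersions and log library-size offsets; p from
    chi-square with (groups - 1) df; Benjamini-Hochberg FDR.
    """
    group = np.asarray([str(g) for g in group])
    if len(group) != counts.shape[1]:
        raise ValueError("one group label per sample required")
    levels = pd.unique(group)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    for g in levels:
        if (group == g).sum() == 0:
            raise ValueError(f"group {g} has no samples")

    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    s = lib / np.exp(np.mean(np.log(np.maximum(lib, 1.0))))
    phi = estimate_dispersion(counts, group, prior_df=prior_df).to_numpy()

    beta0 = _nb_fit_mean(y, s, phi)
    mu0 = s[None, :] * np.exp(beta0)[:, None]
    ll0 = _nb_ll_part(y, mu0, phi)

    ll1 = np.zeros(len(y))
    for g in levels:
        sel = group == g
        beta_g = _nb_fit_mean(y[:, sel], s[sel], phi)
        mu_g = s[sel][None, :] * np.exp(beta_g)[:, None]
        ll1 += _nb_ll_part(y[:, sel], mu_g, phi)

    stat = np.maximum(2.0 * (ll1 - ll0), 0.0)
    stat[y.sum(axis=1) == 0] = 0.0
    stat[stat < 1e-10] = 0.0
    p = stats.chi2.sf(stat, df=len(levels) - 1)
    p[stat == 0.0] = 1.0
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "feature": counts.index,
        "statistic": stat,
        "p": p,
        "fdr": fdr,
        "is_de": fdr < alpha,
    }).set_index("feature")


# ---------------------------------------------------------------------------
# Temporal clustering

# archetype shapes over (D1, D3, D6) matching the cluster semantics
_ARCHETYPES = {
    1: np.array([1.0, 0.0, 0.0]),  # down from Day 3
    2: np.array([1.0, 1.0, 0.0]),  # down at Day 6
    3: np.array([0.0, 1.0, 1.0]),  # up from Day 3
    4: np.array([0.0, 0.0, 1.0]),  # up at Day 6
}


def cluster_temporal(
    log2_cpm: pd.DataFrame,
    samples: Sequence[SampleMetadata],
    k: int = 4,
    seed: int = 0,
    n_init: int = 10,
) -> pd.DataFrame:
    """k-means temporal clustering of DE features on z-scored profiles.

    Rows are z-scored across samples.  Cluster ids are relabeled
    deterministically by matching centroid timepoint profiles to the four
    archetype shapes (Hungarian assignment on correlation).  Constant
    rows cannot be z-scored and are excluded with a warning.
    """
    if k > len(log2_cpm):
        raise ValueError("k exceeds the number of features")
    order = [s.sample_id for s in samples]
    x = log2_cpm[order].to_numpy(dtype=float)
    sd = x.std(axis=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"excluding {const.sum()} constant-profile feature(s) "
                      "from clustering")
    keep = ~const
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(z)

    # centroid per raw label, collapsed to timepoint means
    tps = np.array([s.timepoint for s in samples])
    cent_tp = np.zeros((k, len(TIMEPOINTS)))
    for lab in range(k):
        prof = km.cluster_centers_[lab]
        for j, t in enumerate(TIMEPOINTS):
            cent_tp[lab, j] = prof[tps == t].mean()

    if k == len(_ARCHETYPES):
        arch = np.stack([_ARCHETYPES[i] for i in sorted(_ARCHETYPES)])
        arch_z = (arch - arch.mean(axis=1, keepdims=True)) / arch.std(axis=1, keepdims=True)
        cz = cent_tp - cent_tp.mean(axis=1, keepdims=True)
        czsd = cz.std(axis=1, keepdims=True)
        cz = np.divide(cz, czsd, out=np.zeros_like(cz), where=czsd > 0)
        sim = cz @ arch_z.T / len(TIMEPOINTS)
        rows, cols = linear_sum_assignment(-sim)
        relabel = {int(r): int(c) + 1 for r, c in zip(rows, cols)}
    else:
        relabel = {i: i + 1 for i in range(k)}

    return pd.DataFrame({
        "feature": log2_cpm.index[keep],
        "cluster": [relabel[int(l)] for l in raw_labels],
    }).set_index("feature")


# ---------------------------------------------------------------------------
# Enhancer-to-promoter cluster correspondence


def nearest_promoter(
    enhancers: Sequence[GenomicRegion],
    promoters: Sequence[GenomicRegion],
) -> dict[str, str | None]:
    """Nearest promoter per enhancer by midpoint distance (ties: lower start).

    Enhancers on chromosomes without promoters map to ``None``.
    """
    return nearest_region(enhancers, promoters)


def cluster_overlap_matrix(
    enhancer_clusters: Mapping[str, int],
    promoter_clusters: Mapping[str, int],
    nearest: Mapping[str, str | None],
    k: int = 4,
) -> pd.DataFrame:
    """Row-proportion matrix of enhancer vs nearest-promoter clusters.

    Entry (i, j): fraction of cluster-i enhancers whose nearest promoter
    is a DE promoter in cluster j.  Rows sum to <= 1; the remainder are
    enhancers whose nearest promoter is missing or not DE.
    """
    mat = np.zeros((k, k))
    totals = np.zeros(k)
    for enh, ci in enhancer_clusters.items():
        totals[ci - 1] += 1
        prom = nearest.get(enh)
        if prom is None:
            continue
        cj = promoter_clusters.get(prom)
        if cj is None:
            continue
        mat[ci - 1, cj - 1] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(totals[:, None] > 0, mat / totals[:, None], 0.0)
    labels = [str(i + 1) for i in range(k)]
    return pd.DataFrame(prop, index=pd.Index(labels, name="enhancer_cluster"),
                        columns=pd.Index(labels, name="promoter_cluster"))
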