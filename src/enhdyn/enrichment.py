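"""GWAS-variant enrichment and enhancer sequence characterization.

Enrichment of disease-associated SNPs inside a region set is tested GREGOR
style: each index SNP is expanded to its LD proxies (r2 >= 0.7 within 1 Mb
by default), a locus scores a hit when any proxy lands in the regions, and
significance comes from permutations that replace every index SNP with a
covariate-matched control SNP (MAF bin, proxy-count bin, distance-to-
nearest-gene bin) expanded identically.

Characterization of a region set against length-matched random regions:
per-region mean conservation, SNP counts, nucleotide diversity
pi = 2 * AF * (1 - AF) (per-region means, offset by the smallest non-zero
mean before log10), and eQTL overlap via Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from enhdyn.regions import GenomicRegion, overlaps_any


@dataclass(frozen=True)
class GWASLocus:
    """An index SNP (or merged group) with its LD-expanded proxy set."""

    index_snps: tuple[str, ...]
    proxies: frozenset

    def __post_init__(self) -> None:
        if not set(self.index_snps) <= self.proxies:
            raise ValueError("index SNPs must be contained in their proxy set")


@dataclass
class EnrichmentResult:
    observed: int
    expected: float
    fold: float
    p: float
    n_permutations: int
    n_loci: int


def proxy_map(
    snp_ids: Sequence[str],
    ld: pd.DataFrame,
    r2_threshold: float = 0.7,
    window: int = 1_000_000,
) -> dict[str, set[str]]:
    """LD proxies per SNP: partners with r2 >= threshold within the window."""
    if not (0.0 <= r2_threshold <= 1.0):
        raise ValueError("r2 threshold must lie in [0, 1]")
    sel = ld[(ld["r2"] >= r2_threshold) & (ld["distance"] <= window)]
    out: dict[str, set[str]] = {str(s): {str(s)} for s in snp_ids}
    wanted = set(out)
    for a, b in zip(sel["snp_a"], sel["snp_b"]):
        if a in wanted:
            out[a].add(b)
        if b in wanted:
            out[b].add(a)
    return out


def ld_expand(
    gwas_snps: Sequence[str],
    ld: pd.DataFrame,
    r2_threshold: float = 0.7,
    window: int = 1_000_000,
) -> list[GWASLocus]:
    """Expand index SNPs into GWAS loci, merging loci that share proxies."""
    proxies = proxy_map(gwas_snps, ld, r2_threshold, window)
    # union-find over index SNPs sharing any proxy
    parent = {s: s for s in proxies}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_proxy: dict[str, str] = {}
    for s, ps in proxies.items():
        for p in ps:
            if p in by_proxy:
                ra, rb = find(s), find(by_proxy[p])
                if ra != rb:
                    parent[ra] = rb
            else:
                by_proxy[p] = s
    groups: dict[str, list[str]] = {}
    for s in proxies:
        groups.setdefault(find(s), []).append(s)
    loci = []
    for members in groups.values():
        all_proxies: set[str] = set()
        for s in members:
            all_proxies |= proxies[s]
        loci.append(GWASLocus(tuple(sorted(members)), frozenset(all_proxies)))
    return sorted(loci, key=lambda l: l.index_snps)


# ---------------------------------------------------------------------------
# Matched controls


def _bin_series(values: pd.Series, n_bins: int) -> pd.Series:
    ranked = values.rank(method="first")
    return pd.qcut(ranked, q=min(n_bins, max(1, values.nunique())),
                   labels=False, duplicates="drop")


def snp_covariates(
    variants: pd.DataFrame,
    ld: pd.DataFrame,
    gene_regions: Sequence[GenomicRegion],
    n_maf_bins: int = 10,
    n_dist_bins: int = 3,
) -> pd.DataFrame:
    """Matching covariates per pool SNP: MAF bin, proxy-count bin, gene-distance bin."""
    df = variants.set_index("id").copy()
    maf = np.minimum(df["af"], 1.0 - df["af"])
    df["maf_bin"] = _bin_series(maf, n_maf_bins)

    counts = pd.concat([ld["snp_a"], ld["snp_b"]]).value_counts()
    n_prox = df.index.map(counts).fillna(0).astype(int)
    df["proxy_bin"] = pd.cut(n_prox, bins=[-1, 0, 2, 5, np.inf], labels=False)

    if gene_regions:
        from collections import defaultdict
        mids = defaultdict(list)
        for g in gene_regions:
            mids[g.chrom].append(g.midpoint)
        dist = np.full(len(df), np.inf)
        for chrom, ms in mids.items():
            ms = np.sort(ms)
            sel = (df["chrom"] == chrom).to_numpy()
            pos = df.loc[sel, "pos"].to_numpy()
            i = np.clip(np.searchsorted(ms, pos), 1, len(ms) - 1) \
                if len(ms) > 1 else np.zeros(sel.sum(), dtype=int)
            left = np.abs(pos - ms[np.maximum(i - 1, 0)])
            right = np.abs(ms[i] - pos)
            dist[sel] = np.minimum(left, right)
        df["gene_dist_bin"] = _bin_series(
            pd.Series(dist, index=df.index), n_dist_bins)
    else:
        df["gene_dist_bin"] = 0
    return df


def match_controls(
    index_snps: Sequence[str],
    covariates: pd.DataFrame,
    proxies: Mapping[str, set[str]] | None = None,
    min_neighbors: int = 500,
) -> dict[str, np.ndarray]:
    """Matched control SNPs per index SNP.

    Controls share the index SNP's covariate bin; the index and its LD
    proxies are excluded.  When a bin holds fewer than ``min_neighbors``
    candidates, matching is widened covariate by covariate (gene distance
    first, then proxy count, then MAF) with a warning.
    """
    if len(covariates) < min_neighbors:
        raise ValueError(
            f"SNP pool ({len(covariates)}) smaller than min_neighbors "
            f"({min_neighbors})")
    levels = [
        ["maf_bin", "proxy_bin", "gene_dist_bin"],
        ["maf_bin", "proxy_bin"],
        ["maf_bin"],
        [],
    ]
    out: dict[str, np.ndarray] = {}
    for snp in index_snps:
        if snp not in covariates.index:
            raise KeyError(f"index SNP {snp} missing from the pool")
        excluded = {snp} | set(proxies.get(snp, ())) if proxies else {snp}
        row = covariates.loc[snp]
        for i, cols in enumerate(levels):
            mask = np.ones(len(covariates), dtype=bool)
            for c in cols:
                mask &= (covariates[c] == row[c]).to_numpy()
            ids = covariates.index[mask]
            ids = ids[~ids.isin(excluded)]
            if len(ids) >= min_neighbors or not cols:
                if i > 0:
                    warnings.warn(f"widened matching bins for {snp}")
                if len(ids) < min_neighbors:
                    warnings.warn(f"fewer than {min_neighbors} controls for {snp}")
                out[snp] = ids.to_numpy()
                break
    return out


# ---------------------------------------------------------------------------
# Permutation enrichment test


def _snps_in_regions(variants: pd.DataFrame,
                     regions: Sequence[GenomicRegion]) -> pd.Series:
    """Boolean per variant id: does the SNP fall inside any region?"""
    from collections import defaultdict
    by_chrom = defaultdict(list)
    for r in regions:
        by_chrom[r.chrom].append(r)
    hit = np.zeros(len(variants), dtype=bool)
    for chrom, rs in by_chrom.items():
        starts = np.sort(np.array([r.start for r in rs]))
        ends = np.array([r.end for r in sorted(rs, key=lambda r: r.start)])
        sel = (variants["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        pos = variants.loc[sel, "pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        h = np.zeros(len(pos), dtype=bool)
        h[ok] = pos[ok] < ends[idx[ok]]
        hit[sel] = h
    return pd.Series(hit, index=variants["id"].to_numpy())


def enrichment_test(
    loci: Sequence[GWASLocus],
    regions: Sequence[GenomicRegion],
    controls: Mapping[str, np.ndarray],
    variants: pd.DataFrame,
    ld: pd.DataFrame,
    r2_threshold: float = 0.7,
    window: int = 1_000_000,
    n_permutations: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Matched-control permutation test of GWAS-locus overlap with regions.

    observed: loci with >= 1 proxy inside the regions.  Each permutation
    replaces every index SNP with a random matched control, expands it by
    its own LD proxies, and recounts.  p = (#permutations >= observed + 1)
    / (n + 1); fold = observed / permutation mean.
    """
    if n_permutations == 0:
        raise ValueError("n_permutations must be positive")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations; p resolution is coarse")
    rng = np.random.default_rng(seed)

    snp_hit = _snps_in_regions(variants, regions)
    # hit-with-proxies per pool SNP (proxies of controls computed lazily)
    all_ids = list(snp_hit.index)
    pm = proxy_map(all_ids, ld, r2_threshold, window)
    hit_expanded = pd.Series(
        {s: bool(snp_hit.reindex(list(ps)).fillna(False).any())
         for s, ps in pm.items()})

    observed = sum(
        1 for l in loci if snp_hit.reindex(list(l.proxies)).fillna(False).any())

    # permutations: per index SNP draw a control column of length n_perm
    counts = np.zeros(n_permutations, dtype=int)
    locus_hits = np.zeros((n_permutations, len(loci)), dtype=bool)
    for j, locus in enumerate(loci):
        for snp in locus.index_snps:
            pool = controls[snp]
            if len(pool) == 0:
                raise ValueError(f"no matched controls for {snp}")
            draw = pool[rng.integers(len(pool), size=n_permutations)]
            locus_hits[:, j] |= hit_expanded.reindex(draw).fillna(False).to_numpy()
    counts = locus_hits.sum(axis=1)

    expected = float(counts.mean())
    p = float((np.sum(counts >= observed) + 1) / (n_permutations + 1))
    fold = observed / expected if expected > 0 else float("nan")
    return EnrichmentResult(observed=int(observed), expected=expected,
                            fold=float(fold), p=p,
                            n_permutations=n_permutations, n_loci=len(loci))


# ---------------------------------------------------------------------------
# Matched random regions


def sample_matched_regions(
    template: Sequence[GenomicRegion],
    chrom_sizes: Mapping[str, int],
    excluded: Sequence[GenomicRegion] = (),
    seed: int = 0,
    max_retries: int = 1000,
) -> list[GenomicRegion]:
    """Random regions with exactly the template's length multiset.

    Placements are uniform over the genome, rejected while overlapping any
    excluded region (telomere/centromere stand-ins, etc.).  Reproducible
    by seed; raises when a length cannot be placed within ``max_retries``.
    """
    rng = np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    from collections import defaultdict
    excl = defaultdict(list)
    for r in excluded:
        excl[r.chrom].append((r.start, r.end))
    out: list[GenomicRegion] = []
    for i, t in enumerate(template):
        length = t.length
        for attempt in range(max_retries):
            ci = rng.choice(len(chroms), p=probs)
            chrom = chroms[ci]
            limit = chrom_sizes[chrom] - length
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            end = start + length
            if any(start < e and end > s for s, e in excl[chrom]):
                continue
            out.append(GenomicRegion(chrom, start, end, ".", f"rand_{i}"))
            break
        else:
            raise RuntimeError(
                f"could not place a region of length {length} after "
                f"{max_retries} attempts")
    return out


# ---------------------------------------------------------------------------
# Conservation


def region_mean_scores(
    regions: Sequence[GenomicRegion],
    track: pd.DataFrame,
) -> pd.Series:
    """Base-weighted mean track score per region (uncovered bases excluded)."""
    if track.empty:
        raise ValueError("empty score track")
    out = {}
    by_chrom = {c: g.sort_values("start") for c, g in track.groupby("chrom")}
    arrays = {c: (g["start"].to_numpy(), g["end"].to_numpy(),
                  g["score"].to_numpy()) for c, g in by_chrom.items()}
    for r in regions:
        entry = arrays.get(r.chrom)
        if entry is None:
            out[r.id] = np.nan
            continue
        starts, ends, scores = entry
        lo = np.searchsorted(ends, r.start, side="right")
        hi = np.searchsorted(starts, r.end, side="left")
        if hi <= lo:
            out[r.id] = np.nan
            continue
        s = np.maximum(starts[lo:hi], r.start)
        e = np.minimum(ends[lo:hi], r.end)
        w = np.maximum(e - s, 0)
        out[r.id] = float((scores[lo:hi] * w).sum() / w.sum()) if w.sum() else np.nan
    return pd.Series(out)


def conservation_compare(
    template: Sequence[GenomicRegion],
    random_sets: Mapping[str, Sequence[GenomicRegion]],
    track: pd.DataFrame,
) -> pd.DataFrame:
    """Mean conservation of the template set vs each random set.

    Per-region base-weighted means; group difference by two-sided Wilcoxon
    rank-sum.  The template row carries the reference mean with p = NaN.
    """
    t_scores = region_mean_scores(template, track).dropna()
    rows = [("template", float(t_scores.mean()), np.nan)]
    for name, regions in random_sets.items():
        scores = region_mean_scores(regions, track).dropna()
        if len(scores) == 0:
            rows.append((name, np.nan, np.nan))
            continue
        if t_scores.nunique() <= 1 and scores.nunique() <= 1 \
                and np.isclose(t_scores.mean(), scores.mean()):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(t_scores, scores,
                                         alternative="two-sided").pvalue)
        rows.append((name, float(scores.mean()), p))
    return pd.DataFrame(rows, columns=["set", "mean_score", "p"]).set_index("set")


# ---------------------------------------------------------------------------
# Nucleotide diversity and eQTLs


def nucleotide_diversity(
    regions: Sequence[GenomicRegion],
    variants: pd.DataFrame,
) -> pd.DataFrame:
    """Per-region SNP count and mean nucleotide diversity.

    pi = 2 * AF * (1 - AF) per SNP (so pi <= 0.5, symmetric in AF); the
    per-region mean is 0 for SNP-free regions.  ``log_mean_pi`` is log10
    of the mean after adding the smallest non-zero regional mean to every
    region, so the log is always defined.
    """
    if ((variants["af"] < 0) | (variants["af"] > 1)).any():
        raise ValueError("allele frequency outside [0, 1]")
    v = variants.copy()
    v["pi"] = 2.0 * v["af"] * (1.0 - v["af"])

    from collections import defaultdict
    by_chrom = defaultdict(list)
    for r in regions:
        by_chrom[r.chrom].append(r)
    n_snps = {r.id: 0 for r in regions}
    pi_sum = {r.id: 0.0 for r in regions}
    for chrom, rs in by_chrom.items():
        sub = v[v["chrom"] == chrom]
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy()
        pis = sub["pi"].to_numpy()
        order = np.argsort(pos)
        pos, pis = pos[order], pis[order]
        cum = np.concatenate([[0.0], np.cumsum(pis)])
        for r in rs:
            lo = np.searchsorted(pos, r.start, side="left")
            hi = np.searchsorted(pos, r.end, side="left")
            n_snps[r.id] = int(hi - lo)
            pi_sum[r.id] = float(cum[hi] - cum[lo])

    ids = [r.id for r in regions]
    n = np.array([n_snps[i] for i in ids], dtype=float)
    mean_pi = np.where(n > 0, [pi_sum[i] for i in ids] / np.maximum(n, 1), 0.0)
    nonzero = mean_pi[mean_pi > 0]
    offset = float(nonzero.min()) if len(nonzero) else np.nan
    log_mean = np.log10(mean_pi + offset) if len(nonzero) else np.full(len(ids), np.nan)
    return pd.DataFrame({
        "region_id": ids,
        "n_snps": n.astype(int),
        "mean_pi": mean_pi,
        "log_mean_pi": log_mean,
    }).set_index("region_id")


def eqtl_enrichment(
    region_snps: Sequence[str],
    eqtl_snps: Sequence[str],
    random_snps: Sequence[str],
) -> tuple[float, float]:
    """eQTL enrichment of in-region SNPs vs random-set SNPs (Fisher's exact)."""
    if len(random_snps) == 0:
        raise ValueError("empty random SNP set")
    eqtl = set(eqtl_snps)
    a = sum(1 for s in region_snps if s in eqtl)
    b = len(region_snps) - a
    c = sum(1 for s in random_snps if s in eqtl)
    d = len(random_snps) - c
    rate_r = a / len(region_snps) if region_snps else np.nan
    rate_c = c / len(random_snps)
    fold = rate_r / rate_c if rate_c > 0 else float("inf")
    p = float(stats.fisher_exact([[a, b], [c, d]])[1])
    return fold, p
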