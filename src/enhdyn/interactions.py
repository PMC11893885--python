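"""Chromatin-interaction calling and interactome dynamics.

The caller mirrors capture-style interaction detection with an *empirical*
background: the contact-frequency distribution of negative-control probes
(regions with no regulatory annotation) at matched genomic distance, rather
than a theoretical decay model.  An interaction must have at least
``min_support`` supporting pairs and a Bonferroni-adjusted empirical
P <= alpha in both replicates.  Significant contacts per timepoint induce
per-node networks whose rewiring is quantified with the Jaccard index
JI_x = |A n B| / |A u B| and the overlap coefficient
OCE_x = |A n B| / min(|A|, |B|) of the neighbor sets A, B of node x in the
two networks (OCE defined as 1 when the smaller set is empty, so OCE >= JI
always).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from enhdyn.regions import (
    GenomicRegion,
    merge_regions,
    nearest_region,
    overlap_bp,
    overlaps_any,
)

PROBE_COLUMNS = ["id", "chrom", "start", "end", "probe_class"]


# ---------------------------------------------------------------------------
# Support binning


def bin_pairs(
    pairs: pd.DataFrame,
    probes: pd.DataFrame,
    bin_size: int = 2_000,
    max_distance: int = 2_000_000,
) -> pd.DataFrame:
    """Anchor-level supporting-pair counts per fixed-width other-end bin.

    A valid pair supports (anchor, bin) when one end falls inside the
    anchor's probe region and the other in that genomic bin; a pair with
    both ends in probe regions is counted once for each anchor.  Trans
    pairs and contacts beyond ``max_distance`` are dropped.

    Returns columns: anchor_id, chrom, bin_start, distance, support.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    cis = pairs[pairs["chrom1"] == pairs["chrom2"]]
    rows = []
    for chrom, probes_c in probes.groupby("chrom"):
        sub = cis[cis["chrom1"] == chrom]
        if sub.empty:
            continue
        p1 = sub["pos1"].to_numpy()
        p2 = sub["pos2"].to_numpy()
        starts = probes_c["start"].to_numpy()
        ends = probes_c["end"].to_numpy()
        ids = probes_c["id"].to_numpy()
        order = np.argsort(starts)
        starts, ends, ids = starts[order], ends[order], ids[order]
        mids = (starts + ends) // 2
        for anchor_end, other_end in ((p1, p2), (p2, p1)):
            idx = np.searchsorted(starts, anchor_end, side="right") - 1
            ok = idx >= 0
            hit = np.zeros(len(anchor_end), dtype=bool)
            hit[ok] = anchor_end[ok] < ends[idx[ok]]
            if not hit.any():
                continue
            a = idx[hit]
            bins = other_end[hit] // bin_size
            dist = np.abs(mids[a] - (bins * bin_size + bin_size // 2))
            keep = dist <= max_distance
            rows.append(pd.DataFrame({
                "anchor_id": ids[a[keep]],
                "chrom": chrom,
                "bin_start": bins[keep] * bin_size,
                "distance": dist[keep],
            }))
    if not rows:
        return pd.DataFrame(
            columns=["anchor_id", "chrom", "bin_start", "distance", "support"])
    df = pd.concat(rows, ignore_index=True)
    return (df.groupby(["anchor_id", "chrom", "bin_start", "distance"],
                       as_index=False).size().rename(columns={"size": "support"}))


# ---------------------------------------------------------------------------
# Empirical background


@dataclass
class BackgroundModel:
    """Distance-binned empirical support distributions of negative controls.

    Per distance bin: the number of candidate (negative anchor, other-end
    bin) slots N (zeros included) and the sorted non-zero support values.
    The tail probability of observing support >= k is
    p(k) = (#slots with support >= k, + 1) / (N + 1) — the +1 pseudocount
    keeps p > 0 with a finite control sample.
    """

    edges: np.ndarray  # distance-bin edges, len = n_bins + 1
    n_slots: np.ndarray  # N per distance bin
    nonzero_values: list[np.ndarray]  # sorted non-zero support values per bin

    def distance_bin(self, distance: np.ndarray | float) -> np.ndarray:
        idx = np.searchsorted(self.edges, np.atleast_1d(distance), side="right") - 1
        return np.clip(idx, 0, len(self.n_slots) - 1)

    def tail_p(self, support: np.ndarray | float,
               distance: np.ndarray | float) -> np.ndarray:
        """Empirical P(background support >= observed) with +1 pseudocount."""
        support = np.atleast_1d(support)
        bins = self.distance_bin(np.broadcast_to(
            np.atleast_1d(distance), support.shape).astype(float))
        out = np.empty(len(support))
        for i, (k, b) in enumerate(zip(support, bins)):
            vals = self.nonzero_values[b]
            n_ge = len(vals) - np.searchsorted(vals, k, side="left") if k > 0 \
                else self.n_slots[b]
            out[i] = (n_ge + 1) / (self.n_slots[b] + 1)
        return out


def _slot_counts_per_anchor(
    anchors: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    edges: np.ndarray,
    bin_size: int,
) -> np.ndarray:
    """Number of candidate other-end bins per distance bin, summed over anchors."""
    counts = np.zeros(len(edges) - 1, dtype=int)
    for r in anchors.itertuples():
        amid = (r.start + r.end) // 2
        size = chrom_sizes[r.chrom]
        lo = max(0, (amid - int(edges[-1])) // bin_size)
        hi = min(size // bin_size, (amid + int(edges[-1])) // bin_size)
        bins = np.arange(lo, hi + 1)
        dist = np.abs(amid - (bins * bin_size + bin_size // 2))
        idx = np.searchsorted(edges, dist, side="right") - 1
        ok = (idx >= 0) & (idx < len(counts)) & (dist <= edges[-1]) & (dist >= edges[0])
        counts += np.bincount(idx[ok], minlength=len(counts))
    return counts


def total_candidate_slots(
    anchors: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    bin_size: int = 2_000,
    max_distance: int = 2_000_000,
) -> int:
    """Number of testable (anchor, other-end bin) slots within max_distance."""
    edges = np.array([0.0, float(max_distance)])
    return int(_slot_counts_per_anchor(anchors, chrom_sizes, edges, bin_size).sum())


def fit_background(
    support: pd.DataFrame,
    negative_anchors: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    bin_size: int = 2_000,
    max_distance: int = 2_000_000,
    n_distance_bins: int = 20,
    min_obs: int = 50,
) -> BackgroundModel:
    """Fit the empirical background from negative-control probes.

    ``support`` is one replicate's binned support table; only rows whose
    anchor is a negative control are used.  Distance bins are log-spaced
    from ``bin_size`` to ``max_distance`` and merged upward while a bin
    holds fewer than ``min_obs`` candidate slots.  Every candidate slot of
    every negative anchor counts, including slots with zero support.
    """
    if negative_anchors.empty:
        raise ValueError("no negative-control anchors to build a background from")
    edges = np.unique(np.round(np.geomspace(bin_size, max_distance,
                                            n_distance_bins + 1)))
    slot_counts = _slot_counts_per_anchor(negative_anchors, chrom_sizes,
                                          edges, bin_size)
    # merge sparse bins upward
    while len(slot_counts) > 1 and (slot_counts < min_obs).any():
        i = int(np.argmax(slot_counts < min_obs))
        j = i + 1 if i + 1 < len(slot_counts) else i - 1
        slot_counts[min(i, j)] += slot_counts[max(i, j)]
        slot_counts = np.delete(slot_counts, max(i, j))
        edges = np.delete(edges, max(i, j))

    neg_ids = set(negative_anchors["id"])
    neg = support[support["anchor_id"].isin(neg_ids)
                  & (support["distance"] >= edges[0])
                  & (support["distance"] <= edges[-1])]
    idx = np.clip(np.searchsorted(edges, neg["distance"].to_numpy(),
                                  side="right") - 1, 0, len(slot_counts) - 1)
    values = [np.sort(neg["support"].to_numpy()[idx == b])
              for b in range(len(slot_counts))]
    return BackgroundModel(edges=edges, n_slots=slot_counts, nonzero_values=values)


# ---------------------------------------------------------------------------
# Interaction calling


def call_interactions(
    support_by_rep: Mapping[int, pd.DataFrame],
    background_by_rep: Mapping[int, BackgroundModel],
    probes: pd.DataFrame,
    timepoint: str,
    min_support: int = 5,
    alpha: float = 0.1,
    blacklist: Sequence[GenomicRegion] = (),
    bin_size: int = 2_000,
) -> pd.DataFrame:
    """Call significant interactions for one timepoint from two replicates.

    Candidate slots are (anchor, other-end bin) pairs with support >=
    ``min_support`` in *both* replicates.  Each candidate's empirical
    background tail p is Bonferroni-corrected per anchor (m = the anchor's
    candidate count); it passes in a replicate when p_bonf <= alpha, and
    is a significant interaction when it passes in both.  Candidates whose
    other-end bin overlaps the blacklist are removed before testing.

    Returns every candidate with per-replicate support, p, p_bonf and pass
    flags, plus the combined ``passes`` flag.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    reps = sorted(support_by_rep)
    if len(reps) < 2:
        raise ValueError("need at least two replicates")
    keyed = {}
    for rep in reps:
        df = support_by_rep[rep]
        keyed[rep] = df.set_index(["anchor_id", "chrom", "bin_start"])

    # candidates: support >= min_support in every replicate
    idx = None
    for rep in reps:
        df = support_by_rep[rep]
        s = df.loc[df["support"] >= min_support,
                   ["anchor_id", "chrom", "bin_start", "distance"]]
        mi = pd.MultiIndex.from_frame(s[["anchor_id", "chrom", "bin_start"]])
        idx = mi if idx is None else idx.intersection(mi)
    if idx is None or len(idx) == 0:
        cols = (["anchor_id", "chrom", "bin_start", "distance", "timepoint"]
                + [f"support_r{r}" for r in reps] + [f"p_r{r}" for r in reps]
                + [f"p_bonf_r{r}" for r in reps] + [f"pass_r{r}" for r in reps]
                + ["passes"])
        return pd.DataFrame(columns=cols)

    cand = pd.DataFrame(index=idx.unique()).reset_index()
    mids = dict(zip(probes["id"], (probes["start"] + probes["end"]) // 2))
    amid = cand["anchor_id"].map(mids).to_numpy()
    cand["distance"] = np.abs(
        amid - (cand["bin_start"].to_numpy() + bin_size // 2))
    cand["timepoint"] = timepoint

    if len(blacklist):
        bins = [GenomicRegion(c, int(b), int(b) + bin_size, ".", "bin")
                for c, b in zip(cand["chrom"], cand["bin_start"])]
        cand = cand[~overlaps_any(bins, blacklist)].reset_index(drop=True)
        if cand.empty:
            return cand.assign(passes=pd.Series(dtype=bool))

    key = pd.MultiIndex.from_frame(cand[["anchor_id", "chrom", "bin_start"]])
    m_per_anchor = cand.groupby("anchor_id")["bin_start"].transform("size").to_numpy()
    passes = np.ones(len(cand), dtype=bool)
    for rep in reps:
        sup = keyed[rep]["support"].reindex(key, fill_value=0).to_numpy()
        p = background_by_rep[rep].tail_p(sup, cand["distance"].to_numpy())
        p_bonf = np.minimum(1.0, p * m_per_anchor)
        ok = (sup >= min_support) & (p_bonf <= alpha)
        cand[f"support_r{rep}"] = sup
        cand[f"p_r{rep}"] = p
        cand[f"p_bonf_r{rep}"] = p_bonf
        cand[f"pass_r{rep}"] = ok
        passes &= ok
    cand["passes"] = passes
    assert not (cand["passes"]
                & np.any([cand[f"support_r{r}"] < min_support for r in reps],
                         axis=0)).any()
    return cand


def enrichment_vs_negative(
    calls_target: int, candidates_target: int,
    calls_negative: int, candidates_negative: int,
) -> tuple[float, float]:
    """Fold and p for target vs negative-control interaction frequency.

    Two-sample test for equality of proportions with continuity correction
    (Yates-corrected chi-square on the 2x2 table).  Fold is the ratio of
    per-candidate call proportions; NaN with a warning when both groups
    have zero calls.
    """
    if candidates_negative <= 0:
        raise ValueError("no negative-control candidates")
    if candidates_target <= 0:
        raise ValueError("no target candidates")
    if calls_target == 0 and calls_negative == 0:
        warnings.warn("zero calls in both groups; fold undefined")
        return float("nan"), 1.0
    prop_t = calls_target / candidates_target
    prop_n = calls_negative / candidates_negative
    fold = prop_t / prop_n if prop_n > 0 else float("inf")
    table = np.array([
        [calls_target, candidates_target - calls_target],
        [calls_negative, candidates_negative - calls_negative],
    ])
    if table.min() < 0:
        raise ValueError("calls exceed candidates")
    if (table.sum(axis=0) == 0).any():
        return fold, 1.0
    _, p, _, _ = stats.chi2_contingency(table, correction=True)
    return fold, float(p)


def interaction_stats(calls: pd.DataFrame,
                      probe_classes: Mapping[str, str] | None = None) -> dict:
    """Distance summary of passing calls: mean, fraction > 100 kb, per-class counts."""
    passing = calls[calls["passes"]] if "passes" in calls.columns else calls
    if passing.empty:
        return {"n": 0, "mean_distance": float("nan"),
                "frac_gt_100kb": float("nan"), "per_class": {}}
    d = passing["distance"].abs().to_numpy(dtype=float)
    per_class: dict[str, int] = {}
    if probe_classes:
        per_class = (passing["anchor_id"].map(probe_classes)
                     .value_counts().to_dict())
    return {
        "n": int(len(d)),
        "mean_distance": float(d.mean()),
        "frac_gt_100kb": float((d > 100_000).mean()),
        "per_class": per_class,
    }


def nearest_gene_fraction(
    calls: pd.DataFrame,
    promoters: Sequence[GenomicRegion],
    promoter_ids: set[str] | None = None,
    bin_size: int = 2_000,
) -> float:
    """Fraction of promoter-anchored calls contacting their nearest promoter.

    For each passing promoter-anchored call, the distal bin's nearest
    promoter (midpoint distance) is compared with the anchored promoter.
    NaN when there are no promoter-anchored calls.
    """
    if promoter_ids is None:
        promoter_ids = {p.id for p in promoters}
    passing = calls[calls["passes"] & calls["anchor_id"].isin(promoter_ids)]
    if passing.empty:
        return float("nan")
    bins = [GenomicRegion(c, int(b), int(b) + bin_size, ".", f"q{i}")
            for i, (c, b) in enumerate(zip(passing["chrom"],
                                           passing["bin_start"]))]
    nearest = nearest_region(bins, promoters)
    hits = [nearest[f"q{i}"] == a
            for i, a in enumerate(passing["anchor_id"])]
    return float(np.mean(hits))


# ---------------------------------------------------------------------------
# Networks and dynamics


def map_bins_to_features(
    calls: pd.DataFrame,
    features: Sequence[GenomicRegion],
    bin_size: int = 2_000,
) -> pd.DataFrame:
    """Annotate each call's other-end bin with overlapping feature ids.

    Bins overlapping no feature keep a synthetic ``bin:<chrom>:<start>``
    node id, so distal unannotated regions remain in the network.
    """
    from collections import defaultdict

    trees: dict[str, list[GenomicRegion]] = defaultdict(list)
    for f in features:
        trees[f.chrom].append(f)
    out_nodes: list[list[str]] = []
    for c, b in zip(calls["chrom"], calls["bin_start"]):
        b = int(b)
        hits = [f.id for f in trees.get(c, ())
                if overlap_bp(b, b + bin_size, f.start, f.end) >= 1]
        out_nodes.append(hits if hits else [f"bin:{c}:{b}"])
    annotated = calls.copy()
    annotated["other_nodes"] = out_nodes
    return annotated


def build_network(annotated_calls: pd.DataFrame, timepoint: str) -> nx.Graph:
    """Undirected network of one timepoint's interactions.

    A call contributes an edge when it passes in at least one replicate;
    duplicate pairs collapse to one edge; self-loops are skipped.
    """
    g = nx.Graph(timepoint=timepoint)
    rep_cols = [c for c in annotated_calls.columns if c.startswith("pass_r")]
    sub = annotated_calls[annotated_calls["timepoint"] == timepoint]
    any_pass = sub[rep_cols].any(axis=1) if rep_cols else sub["passes"]
    for row, ok in zip(sub.itertuples(), any_pass):
        if not ok:
            continue
        for other in row.other_nodes:
            if other != row.anchor_id:
                g.add_edge(row.anchor_id, other)
    return g


def node_dynamics(net_a: nx.Graph, net_b: nx.Graph, node: str) -> tuple[float, float]:
    """JI and OCE of a node's neighbor sets between two networks.

    JI = |A n B| / |A u B| (1 when both sets are empty); OCE =
    |A n B| / min(|A|, |B|), defined as 1 when the smaller set is empty —
    a node that loses its single neighbor has JI 0 but OCE 1.
    Symmetric in the network order, and OCE >= JI always.
    """
    a = set(net_a.neighbors(node)) if node in net_a else set()
    b = set(net_b.neighbors(node)) if node in net_b else set()
    union = a | b
    inter = a & b
    ji = len(inter) / len(union) if union else 1.0
    m = min(len(a), len(b))
    oce = len(inter) / m if m > 0 else 1.0
    return ji, oce


def all_node_dynamics(net_a: nx.Graph, net_b: nx.Graph) -> pd.DataFrame:
    nodes = sorted(set(net_a.nodes) | set(net_b.nodes))
    rows = [(n, *node_dynamics(net_a, net_b, n)) for n in nodes]
    return pd.DataFrame(rows, columns=["node", "ji", "oce"]).set_index("node")


def compare_de_dynamics(
    dynamics: pd.DataFrame,
    de_status: Mapping[str, bool],
    metric: str = "oce",
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum of JI/OCE between DE and non-DE nodes."""
    labels = dynamics.index.map(lambda n: de_status.get(n))
    de = dynamics.loc[labels == True, metric]  # noqa: E712
    non = dynamics.loc[labels == False, metric]  # noqa: E712
    if len(de) < 2 or len(non) < 2:
        raise ValueError("need at least two nodes per group")
    res = stats.mannwhitneyu(de, non, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def dynamic_expression_correlation(
    pairs: pd.DataFrame,
    promoter_expr: pd.DataFrame,
    enhancer_expr: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Timepoint-resolved expression coupling of single-timepoint contacts.

    ``pairs`` has one row per promoter-enhancer contact observed at exactly
    one timepoint (columns promoter_id, enhancer_id, timepoint).  The
    expression frames hold per-timepoint log2 CPM (features x timepoints).
    Entry (t_int, t_expr): correlation across the contacts active only at
    t_int between promoter and enhancer expression at t_expr; NaN when a
    cell has fewer than 3 pairs.
    """
    tps = list(promoter_expr.columns)
    mat = pd.DataFrame(np.nan, index=pd.Index(tps, name="interaction_tp"),
                       columns=pd.Index(tps, name="expression_tp"))
    for t_int, g in pairs.groupby("timepoint"):
        if len(g) < 3:
            continue
        pe = promoter_expr.loc[g["promoter_id"]]
        ee = enhancer_expr.loc[g["enhancer_id"]]
        for t_expr in tps:
            x = pe[t_expr].to_numpy(dtype=float)
            y = ee[t_expr].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                mat.loc[t_int, t_expr] = 1.0 if np.allclose(x - x.mean(),
                                                            y - y.mean()) else np.nan
                continue
            if method == "pearson":
                mat.loc[t_int, t_expr] = float(stats.pearsonr(x, y)[0])
            else:
                mat.loc[t_int, t_expr] = float(stats.spearmanr(x, y)[0])
    return mat


# ---------------------------------------------------------------------------
# Distal peak enrichment


def _total_bp(regions: Sequence[GenomicRegion]) -> int:
    return sum(r.length for r in merge_regions(regions)) if regions else 0


def _intersection_bp(a: Sequence[GenomicRegion], b: Sequence[GenomicRegion]) -> int:
    if not a or not b:
        return 0
    am = merge_regions(a)
    bm = merge_regions(b)
    total = 0
    from collections import defaultdict
    by_chrom = defaultdict(list)
    for r in bm:
        by_chrom[r.chrom].append(r)
    for r in am:
        for o in by_chrom.get(r.chrom, ()):
            total += overlap_bp(r.start, r.end, o.start, o.end)
    return total


def distal_peak_enrichment(
    distal_regions: Sequence[GenomicRegion],
    peak_sets: Mapping[str, Sequence[GenomicRegion]],
    universe_regions: Sequence[GenomicRegion],
) -> pd.DataFrame:
    """Functional-peak enrichment of promoter-interacting distal regions.

    For each peak set: percentage of distal regions overlapping it, fold
    over the rate in the candidate-bin universe, base-pair Jaccard between
    the sets, and Fisher's exact p on the 2x2 overlap table.  Empty peak
    sets yield an all-NaN row.
    """
    rows = []
    n_d = len(distal_regions)
    n_u = len(universe_regions)
    for name, peaks in peak_sets.items():
        if not len(peaks):
            rows.append((name, np.nan, np.nan, np.nan, np.nan))
            continue
        d_hits = int(overlaps_any(distal_regions, peaks).sum())
        u_hits = int(overlaps_any(universe_regions, peaks).sum())
        obs = d_hits / n_d if n_d else np.nan
        bg = u_hits / n_u if n_u else np.nan
        fold = obs / bg if bg else np.nan
        inter = _intersection_bp(distal_regions, peaks)
        union = _total_bp(list(distal_regions)) + _total_bp(list(peaks)) - inter
        ji = inter / union if union else np.nan
        table = [[d_hits, n_d - d_hits], [u_hits, n_u - u_hits]]
        p = float(stats.fisher_exact(table)[1]) if n_d and n_u else np.nan
        rows.append((name, 100.0 * obs if obs == obs else np.nan, fold, ji, p))
    return pd.DataFrame(rows, columns=["peak_set", "overlap_pct", "fold",
                                       "jaccard", "fisher_p"]).set_index("peak_set")
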