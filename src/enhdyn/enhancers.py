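"""Bidirectional enhancer calling from stranded CTSS signal.

Actively transcribed enhancers produce short, unstable eRNAs from both
strands in divergent orientation.  The caller (i) groups pooled CTSS tags
into strand-specific tag clusters by single-linkage gap clustering,
(ii) pairs a minus-strand cluster lying left of a plus-strand cluster into
a candidate locus, (iii) scores divergent balance with the directionality
score D = (F - R) / (F + R), where F and R are the plus- and minus-flank
tag counts, and keeps balanced loci (|D| below a threshold), and
(iv) classifies the calls against known enhancer catalogs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from enhdyn.regions import GenomicRegion, overlaps_any


@dataclass(frozen=True)
class TagCluster:
    """A run of same-strand CTSS positions separated by <= max_gap bases."""

    region: GenomicRegion
    total_count: int
    summit_pos: int


@dataclass
class BidirectionalLocus:
    """A divergent cluster pair: the operational enhancer signature.

    ``minus_count`` (R) and ``plus_count`` (F) are the flank tag totals;
    ``directionality`` D = (F - R) / (F + R) is near 0 for balanced
    bidirectional transcription.
    """

    region: GenomicRegion
    midpoint: int
    minus_count: int
    plus_count: int
    directionality: float
    novelty: str = "novel"

    @property
    def id(self) -> str:
        return self.region.id


def directionality_score(plus_count: int, minus_count: int) -> float:
    """D = (F - R) / (F + R); F, R must both be positive for a valid locus."""
    total = plus_count + minus_count
    if total <= 0:
        raise ValueError("directionality undefined without tags")
    return (plus_count - minus_count) / total


def pool_ctss(ctss_tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Sum per-position tag counts across samples."""
    frames = [df[["chrom", "pos", "strand", "count"]] for df in ctss_tables]
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "count"])
    pooled = pd.concat(frames, ignore_index=True)
    return (pooled.groupby(["chrom", "pos", "strand"], as_index=False)["count"]
            .sum().sort_values(["chrom", "strand", "pos"], ignore_index=True))


def cluster_ctss(ctss: pd.DataFrame, max_gap: int = 20,
                 min_count: int = 2) -> list[TagCluster]:
    """Single-linkage tag clustering per (chromosome, strand).

    Consecutive same-strand positions <= ``max_gap`` apart share a cluster;
    clusters with fewer than ``min_count`` total tags are dropped.  Tags on
    opposite strands never merge.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    clusters: list[TagCluster] = []
    if ctss.empty:
        return clusters
    for (chrom, strand), g in ctss.groupby(["chrom", "strand"], sort=True):
        g = g.sort_values("pos")
        pos = g["pos"].to_numpy()
        cnt = g["count"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for seg_pos, seg_cnt in zip(np.split(pos, breaks), np.split(cnt, breaks)):
            total = int(seg_cnt.sum())
            if total < min_count:
                continue
            summit = int(seg_pos[np.argmax(seg_cnt)])
            region = GenomicRegion(chrom, int(seg_pos[0]), int(seg_pos[-1]) + 1,
                                   strand, f"tc_{chrom}_{strand}_{seg_pos[0]}")
            clusters.append(TagCluster(region, total, summit))
    return clusters


def call_bidirectional(
    clusters: Sequence[TagCluster],
    pairing_window: int = 400,
    directionality_threshold: float = 0.8,
    promoter_mask: Sequence[GenomicRegion] = (),
    promoter_pad: int = 500,
) -> list[BidirectionalLocus]:
    """Pair divergent tag clusters into bidirectional loci.

    A minus-strand cluster pairs with the nearest plus-strand cluster whose
    start lies at or right of the minus cluster's end, with the inner gap
    <= ``pairing_window``.  Only balanced loci (|D| strictly below the
    threshold) are emitted; loci overlapping the padded promoter mask are
    discarded; overlapping loci are merged keeping the most balanced one.
    """
    if pairing_window <= 0:
        raise ValueError("pairing_window must be positive")
    by_chrom: dict[str, dict[str, list[TagCluster]]] = {}
    for c in clusters:
        by_chrom.setdefault(c.region.chrom, {"+": [], "-": []})[c.region.strand].append(c)

    mask = [GenomicRegion(m.chrom, max(0, m.start - promoter_pad),
                          m.end + promoter_pad, ".", m.id or "mask")
            for m in promoter_mask]

    loci: list[BidirectionalLocus] = []
    for chrom, strands in by_chrom.items():
        minus = sorted(strands["-"], key=lambda c: c.region.start)
        plus = sorted(strands["+"], key=lambda c: c.region.start)
        if not minus or not plus:
            continue
        plus_starts = np.array([p.region.start for p in plus])
        for mc in minus:
            i = int(np.searchsorted(plus_starts, mc.region.end, side="left"))
            if i >= len(plus):
                continue
            pc = plus[i]  # nearest divergent partner (tie rule: nearest wins)
            gap = pc.region.start - mc.region.end
            if gap > pairing_window:
                continue
            F, R = pc.total_count, mc.total_count
            D = directionality_score(F, R)
            if abs(D) >= directionality_threshold:
                continue
            region = GenomicRegion(chrom, mc.region.start, pc.region.end, ".",
                                   f"bid_{chrom}_{mc.region.start}")
            loci.append(BidirectionalLocus(
                region=region,
                midpoint=(mc.region.end + pc.region.start) // 2,
                minus_count=R, plus_count=F, directionality=D,
            ))

    if mask:
        keep = ~overlaps_any([l.region for l in loci], mask)
        loci = [l for l, k in zip(loci, keep) if k]

    # merge overlapping loci, keeping the more balanced (smaller |D|)
    merged: list[BidirectionalLocus] = []
    for locus in sorted(loci, key=lambda l: (l.region.chrom, l.region.start)):
        if merged and merged[-1].region.chrom == locus.region.chrom \
                and locus.region.start < merged[-1].region.end:
            if abs(locus.directionality) < abs(merged[-1].directionality):
                merged[-1] = locus
        else:
            merged.append(locus)

    for l in merged:
        assert l.plus_count > 0 and l.minus_count > 0
        assert abs(l.directionality) < directionality_threshold
    return merged


def classify_novelty(
    loci: Sequence[BidirectionalLocus],
    known_sets: Mapping[str, Sequence[GenomicRegion]],
    min_bp: int = 1,
) -> pd.DataFrame:
    """Flag loci as known (>= min_bp overlap with any known catalog) or novel.

    Returns one row per locus with its novelty and per-catalog hit flags;
    also mutates each locus's ``novelty`` field.
    """
    regions = [l.region for l in loci]
    per_set = {name: overlaps_any(regions, catalog, min_bp=min_bp)
               for name, catalog in known_sets.items()}
    any_known = np.zeros(len(loci), dtype=bool)
    for hits in per_set.values():
        any_known |= hits
    for locus, known in zip(loci, any_known):
        locus.novelty = "known" if known else "novel"
    out = pd.DataFrame({
        "id": [l.id for l in loci],
        "novelty": np.where(any_known, "known", "novel"),
    })
    for name, hits in per_set.items():
        out[f"in_{name}"] = hits
    return out


def combine_universe(known_set_sizes: Sequence[int],
                     loci: Sequence[BidirectionalLocus]) -> int:
    """Total enhancer universe: all known catalogs plus the novel calls."""
    n_novel = sum(1 for l in loci if l.novelty == "novel")
    return int(sum(known_set_sizes) + n_novel)


def loci_to_frame(loci: Sequence[BidirectionalLocus]) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [l.region.chrom for l in loci],
        "start": [l.region.start for l in loci],
        "end": [l.region.end for l in loci],
        "id": [l.id for l in loci],
        "midpoint": [l.midpoint for l in loci],
        "plus_count": [l.plus_count for l in loci],
        "minus_count": [l.minus_count for l in loci],
        "directionality": [l.directionality for l in loci],
        "novelty": [l.novelty for l in loci],
    })
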