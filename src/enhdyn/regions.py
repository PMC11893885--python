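"""Genomic intervals and interval arithmetic.

All coordinates are 0-based half-open (BED convention) everywhere in the
package: a region ``[start, end)`` contains positions ``start .. end-1``.
Adjacent intervals (``a.end == b.start``) never overlap.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicRegion:
    """A half-open genomic interval, optionally stranded.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicRegion", min_bp: int = 1) -> bool:
        return (
            self.chrom == other.chrom
            and overlap_bp(self.start, self.end, other.start, other.end) >= min_bp
        )

    def with_id(self, new_id: str) -> "GenomicRegion":
        return replace(self, id=new_id)


def overlap_bp(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Shared bases of two half-open intervals on the same chromosome."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _trees_by_chrom(regions: Sequence[GenomicRegion]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for r in regions:
        trees[r.chrom].addi(r.start, r.end, r)
    return dict(trees)


def overlap_pairs(
    a: Sequence[GenomicRegion],
    b: Sequence[GenomicRegion],
    min_bp: int = 1,
) -> list[tuple[str, str, int]]:
    """All region pairs (one from ``a``, one from ``b``) sharing >= min_bp bases.

    Returns tuples ``(a_id, b_id, overlap_bp)``.  Half-open semantics:
    ``[0,10)`` and ``[10,20)`` do not overlap.  Symmetric in the sense that
    swapping the catalogs swaps the id columns but preserves every pair.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    trees = _trees_by_chrom(b)
    out: list[tuple[str, str, int]] = []
    for ra in a:
        tree = trees.get(ra.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(ra.start, ra.end)):
            bp = overlap_bp(ra.start, ra.end, iv.begin, iv.end)
            if bp >= min_bp:
                out.append((ra.id, iv.data.id, bp))
    return out


def overlaps_any(
    query: Sequence[GenomicRegion],
    catalog: Sequence[GenomicRegion],
    min_bp: int = 1,
) -> np.ndarray:
    """Boolean array: does each query region overlap the catalog by >= min_bp?"""
    trees = _trees_by_chrom(catalog)
    hits = np.zeros(len(query), dtype=bool)
    for i, r in enumerate(query):
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(r.start, r.end):
            if overlap_bp(r.start, r.end, iv.begin, iv.end) >= min_bp:
                hits[i] = True
                break
    return hits


def merge_regions(regions: Sequence[GenomicRegion]) -> list[GenomicRegion]:
    """Union of intervals: merge overlapping or touching regions per chromosome."""
    out: list[GenomicRegion] = []
    by_chrom: dict[str, list[GenomicRegion]] = defaultdict(list)
    for r in regions:
        by_chrom[r.chrom].append(r)
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur_start, cur_end = rs[0].start, rs[0].end
        for r in rs[1:]:
            if r.start <= cur_end:
                cur_end = max(cur_end, r.end)
            else:
                out.append(GenomicRegion(chrom, cur_start, cur_end, ".", f"m{len(out)}"))
                cur_start, cur_end = r.start, r.end
        out.append(GenomicRegion(chrom, cur_start, cur_end, ".", f"m{len(out)}"))
    return out


def coverage_regions(
    region_sets: Sequence[Sequence[GenomicRegion]], min_sets: int
) -> list[GenomicRegion]:
    """Genomic stretches covered by at least ``min_sets`` of the given sets.

    Each input set is flattened to its union first, so a set counts at most
    once per base.  Used to build composite peak sets (bases where >= k
    functional marks co-occur).
    """
    if min_sets < 1:
        raise ValueError("min_sets must be >= 1")
    events: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for rs in region_sets:
        for r in merge_regions(rs) if rs else []:
            events[r.chrom].append((r.start, +1))
            events[r.chrom].append((r.end, -1))
    out: list[GenomicRegion] = []
    for chrom in sorted(events):
        ev = sorted(events[chrom])
        depth = 0
        open_start: int | None = None
        for pos, delta in ev:
            new_depth = depth + delta
            if depth < min_sets <= new_depth:
                open_start = pos
            elif new_depth < min_sets <= depth and open_start is not None:
                if pos > open_start:
                    out.append(
                        GenomicRegion(chrom, open_start, pos, ".", f"c{len(out)}")
                    )
                open_start = None
            depth = new_depth
    return out


def regions_to_frame(regions: Iterable[GenomicRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, r.id, r.strand) for r in regions],
        columns=["chrom", "start", "end", "id", "strand"],
    )


def frame_to_regions(df: pd.DataFrame) -> list[GenomicRegion]:
    strand = df["strand"] if "strand" in df.columns else ["."] * len(df)
    return [
        GenomicRegion(c, int(s), int(e), st, str(i))
        for c, s, e, i, st in zip(df["chrom"], df["start"], df["end"], df["id"], strand)
    ]


def nearest_region(
    query: Sequence[GenomicRegion], catalog: Sequence[GenomicRegion]
) -> dict[str, str | None]:
    """Nearest catalog region for each query, by midpoint-to-midpoint distance.

    Ties are broken toward the lower start coordinate.  Queries on a
    chromosome with no catalog entries map to ``None``.
    """
    by_chrom: dict[str, list[GenomicRegion]] = defaultdict(list)
    for r in catalog:
        by_chrom[r.chrom].append(r)
    mids: dict[str, tuple[np.ndarray, list[GenomicRegion]]] = {}
    for chrom, rs in by_chrom.items():
        rs = sorted(rs, key=lambda r: (r.midpoint, r.start))
        mids[chrom] = (np.array([r.midpoint for r in rs]), rs)
    out: dict[str, str | None] = {}
    for q in query:
        if q.chrom not in mids:
            out[q.id] = None
            continue
        arr, rs = mids[q.chrom]
        dists = np.abs(arr - q.midpoint)
        best = np.flatnonzero(dists == dists.min())
        # ties: lowest start coordinate wins
        winner = min((rs[i] for i in best), key=lambda r: (r.start, r.id))
        out[q.id] = winner.id
    return out
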