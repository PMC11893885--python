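"""Readers and writers for the plain-text formats the pipeline consumes.

Formats: BED3/BED6 region catalogs, CTSS tag tables (chrom, pos, strand,
count), Hi-C valid-pair tables, variant tables with allele frequencies,
LD pair tables, bedGraph score tracks and chrom-size tables.  All tables
are tab-separated; all coordinates are 0-based half-open on read (a CTSS
dialect flag converts 1-based inputs).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from enhdyn.regions import GenomicRegion

TIMEPOINTS = ("D1", "D3", "D6")
ASSAYS = ("total", "nascent")
PROBE_CLASSES = ("promoter", "enhancer", "gwas", "negative_control")


@dataclass(frozen=True)
class CTSSRecord:
    """One CAGE TSS position: per-base, per-strand tag count for a sample."""

    chrom: str
    pos: int
    strand: str
    count: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"CTSS strand must be + or -, got {self.strand!r}")
        if self.count < 0:
            raise ValueError(f"negative CTSS count at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class SampleMetadata:
    """Identity of one library: differentiation day, assay and replicate.

    ``assay`` separates total-RNA (CAGE, promoter signal) from nascent-RNA
    (NET-CAGE, enhancer signal) libraries.
    """

    sample_id: str
    timepoint: str
    assay: str
    replicate: int

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")


@dataclass(frozen=True)
class ValidPair:
    """A deduplicated Hi-C contact with both ends mapped.

    Ends are canonicalized so (chrom1, pos1) <= (chrom2, pos2).
    """

    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    sample_id: str

    def __post_init__(self) -> None:
        for s in (self.strand1, self.strand2):
            if s not in ("+", "-"):
                raise ValueError(f"unknown strand symbol {s!r}")
        if (self.chrom1, self.pos1) > (self.chrom2, self.pos2):
            raise ValueError("valid pair not canonicalized; use canonical_pair()")


def canonical_pair(
    chrom1: str, pos1: int, strand1: str,
    chrom2: str, pos2: int, strand2: str,
    sample_id: str,
) -> ValidPair:
    if (chrom1, pos1) > (chrom2, pos2):
        chrom1, pos1, strand1, chrom2, pos2, strand2 = (
            chrom2, pos2, strand2, chrom1, pos1, strand1,
        )
    return ValidPair(chrom1, pos1, strand1, chrom2, pos2, strand2, sample_id)


@dataclass(frozen=True)
class ProbeTarget:
    """A capture-probe target region with its design class."""

    region: GenomicRegion
    probe_class: str

    def __post_init__(self) -> None:
        if self.probe_class not in PROBE_CLASSES:
            raise ValueError(f"unknown probe class {self.probe_class!r}")


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int
    ref: str
    alt: str
    af: float
    id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.af <= 1.0):
            raise ValueError(f"allele frequency {self.af} outside [0, 1]")


@dataclass(frozen=True)
class LDPair:
    snp_a: str
    snp_b: str
    r2: float
    distance: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError(f"r2 {self.r2} outside [0, 1]")
        if self.distance < 0:
            raise ValueError("LD pair distance must be non-negative")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicRegion]:
    """Read a BED3/BED6 file into regions.

    Column 4 supplies the region id when present (auto ids otherwise);
    column 6 supplies the strand when present, else unstranded.
    Malformed lines raise with their 1-based line number.
    """
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else f"region_{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            try:
                regions.append(GenomicRegion(chrom, start, end, strand, name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_bed(regions: Sequence[GenomicRegion], path: str | Path,
              extra: pd.DataFrame | None = None) -> None:
    """Write BED6 (+ optional extra columns aligned by row order)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fields = [r.chrom, str(r.start), str(r.end), r.id, "0", r.strand]
            if extra is not None:
                fields.extend(str(v) for v in extra.iloc[i])
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# CTSS

CTSS_COLUMNS = ["chrom", "pos", "strand", "count"]


def read_ctss(path: str | Path, sample_id: str, one_based: bool = False) -> list[CTSSRecord]:
    """Read a 4-column CTSS table (chrom, pos, strand, count).

    Set ``one_based=True`` for 1-based dialects; positions are converted to
    0-based on read.  Negative counts raise.
    """
    df = read_ctss_frame(path, sample_id, one_based=one_based)
    return [
        CTSSRecord(c, int(p), s, int(n), sample_id)
        for c, p, s, n in zip(df["chrom"], df["pos"], df["strand"], df["count"])
    ]


def read_ctss_frame(path: str | Path, sample_id: str, one_based: bool = False) -> pd.DataFrame:
    """Frame-based CTSS reader used by the pipeline (columns + sample_id)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=CTSS_COLUMNS,
                         dtype={"chrom": str, "pos": int, "strand": str, "count": int})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=CTSS_COLUMNS).astype(
            {"pos": int, "count": int, "chrom": str, "strand": str})
    if not df["strand"].isin(["+", "-"]).all():
        bad = df.loc[~df["strand"].isin(["+", "-"]), "strand"].iloc[0]
        raise ValueError(f"{path}: unknown strand symbol {bad!r}")
    if (df["count"] < 0).any():
        raise ValueError(f"{path}: negative CTSS count")
    if one_based:
        df["pos"] = df["pos"] - 1
    df["sample_id"] = sample_id
    return df


def write_ctss(records: Iterable[CTSSRecord] | pd.DataFrame, path: str | Path) -> None:
    if isinstance(records, pd.DataFrame):
        records[CTSS_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
        return
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.strand}\t{r.count}\n")


# ---------------------------------------------------------------------------
# Valid pairs

PAIR_COLUMNS = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]


def read_pairs(path: str | Path, sample_id: str) -> list[ValidPair]:
    """Read a 6-column valid-pair table, canonicalizing end order."""
    df = read_pairs_frame(path, sample_id)
    return [
        ValidPair(*row, sample_id)
        for row in zip(*(df[c] for c in PAIR_COLUMNS))
    ]


def read_pairs_frame(path: str | Path, sample_id: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=PAIR_COLUMNS,
                         dtype={"chrom1": str, "chrom2": str, "pos1": int, "pos2": int,
                                "strand1": str, "strand2": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=PAIR_COLUMNS + ["sample_id"])
    if df.isna().any().any():
        raise ValueError(f"{path}: short line (expected 6 columns)")
    for col in ("strand1", "strand2"):
        if not df[col].isin(["+", "-"]).all():
            bad = df.loc[~df[col].isin(["+", "-"]), col].iloc[0]
            raise ValueError(f"{path}: unknown strand symbol {bad!r}")
    flip = (df["chrom1"] > df["chrom2"]) | (
        (df["chrom1"] == df["chrom2"]) & (df["pos1"] > df["pos2"]))
    if flip.any():
        f = df.loc[flip]
        df.loc[flip, PAIR_COLUMNS] = f[
            ["chrom2", "pos2", "strand2", "chrom1", "pos1", "strand1"]
        ].to_numpy()
        df["pos1"] = df["pos1"].astype(int)
        df["pos2"] = df["pos2"].astype(int)
    df["sample_id"] = sample_id
    return df


def write_pairs(pairs: Iterable[ValidPair] | pd.DataFrame, path: str | Path) -> None:
    if isinstance(pairs, pd.DataFrame):
        pairs[PAIR_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
        return
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.chrom1}\t{p.pos1}\t{p.strand1}\t{p.chrom2}\t{p.pos2}\t{p.strand2}\n")


# ---------------------------------------------------------------------------
# Variants / LD / scores / genome

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "af"]


def read_variants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing variant columns {sorted(missing)}")
    if ((df["af"] < 0) | (df["af"] > 1)).any():
        raise ValueError(f"{path}: allele frequency outside [0, 1]")
    return df


def write_variants(df: pd.DataFrame, path: str | Path) -> None:
    df[VARIANT_COLUMNS].to_csv(path, sep="\t", index=False)


LD_COLUMNS = ["snp_a", "snp_b", "r2", "distance"]


def read_ld(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
    missing = set(LD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing LD columns {sorted(missing)}")
    if ((df["r2"] < 0) | (df["r2"] > 1)).any():
        raise ValueError(f"{path}: r2 outside [0, 1]")
    return df


def write_ld(df: pd.DataFrame, path: str | Path) -> None:
    df[LD_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph score track into (chrom, start, end, score)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "score"],
                         dtype={"chrom": str, "start": int, "end": int, "score": float},
                         comment="t")  # skips 'track' lines
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty score track")
    if df.empty:
        raise ValueError(f"{path}: empty score track")
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "score"]].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")
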