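"""Synthetic input generator with planted ground truth.

Emulates the pipeline's study design: a small two-chromosome genome carrying
promoters (strand-biased, high TSS signal in total-RNA libraries) and
enhancers (balanced bidirectional, low signal in nascent-RNA libraries),
four planted temporal expression patterns over a Day 1/3/6 time course,
Capture Hi-C valid pairs with power-law distance decay plus planted
enhancer-promoter contacts that negative-control probes never receive,
LD-structured variants with a planted GWAS enrichment inside enhancers,
and a conservation track elevated in enhancers.

Every generator is deterministic given ``SimulationConfig.seed``; each stage
derives its own child stream so stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from enhdyn.io import (
    SampleMetadata,
    TIMEPOINTS,
    write_bed,
    write_bedgraph,
    write_chrom_sizes,
    write_ctss,
    write_ld,
    write_pairs,
    write_variants,
)
from enhdyn.regions import GenomicRegion, frame_to_regions

# temporal mean multipliers per cluster over (D1, D3, D6); `fold` separates
# the high from the low level. 1: down from Day 3, 2: down at Day 6,
# 3: up from Day 3, 4: up at Day 6.
_CLUSTER_SHAPES = {
    "1": (1.0, 0.0, 0.0),
    "2": (1.0, 1.0, 0.0),
    "3": (0.0, 1.0, 1.0),
    "4": (0.0, 0.0, 1.0),
    "flat": (1.0, 1.0, 1.0),
}

_STAGE_LANDSCAPE, _STAGE_CTSS, _STAGE_HIC, _STAGE_VAR, _STAGE_CONS = range(5)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic landscape.

    Defaults are the package's standing study conditions: a 2 x 10 Mb
    genome, 3 timepoints x 2 replicates x 2 assays, negative-binomial
    expression noise, 4-fold temporal effects, power-law Hi-C decay with
    planted contacts at ``planted_lambda``-fold background, and a 3x
    planted GWAS enrichment inside enhancers.
    """

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    # features
    n_promoters: int = 300
    n_enhancers: int = 200
    promoter_width: int = 40
    enhancer_flank: int = 180
    enhancer_gap: int = 40
    frac_de: float = 0.5
    cluster_proportions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    frac_known_enhancers: float = 0.25
    # expression
    n_replicates: int = 2
    promoter_mean: float = 300.0
    enhancer_mean: float = 60.0
    dispersion: float = 0.1
    temporal_fold: float = 4.0
    promoter_strand_purity: float = 0.95
    enhancer_balance_conc: float = 40.0  # Beta(c/2, c/2) around 0.5
    mean_log_sd: float = 0.4
    noise_rate: float = 5e-6  # background tags per bp per sample
    enhancer_total_rate: float = 0.05  # eRNA leakage into total-RNA libraries
    expression_coupling_sd: float = 0.5  # shared log-noise of contacting pairs
    # Hi-C
    pairs_per_anchor: float = 1200.0
    decay_exponent: float = 1.0
    hic_bin_size: int = 2_000
    hic_max_distance: int = 2_000_000
    n_negative_controls: int = 100
    n_planted_interactions: int = 80
    planted_lambda: float = 8.0
    planted_min_dist: int = 20_000
    planted_max_dist: int = 300_000
    frac_enhancers_targeted: float = 0.6
    frac_probes_gwas: float = 0.3  # targeted enhancers whose probe tags a GWAS hit
    # variants
    variant_density: float = 2e-4  # SNPs per bp
    af_alpha: float = 1.0
    af_beta: float = 3.0
    ld_block_size: int = 50_000
    snp_enrichment_factor: float = 1.0  # SNP *density* factor inside enhancers
    n_gwas_snps: int = 60
    gwas_enrichment: float = 3.0  # planted GWAS-in-enhancer enrichment
    eqtl_base_rate: float = 0.05
    eqtl_enrichment: float = 2.0
    # conservation
    conservation_base_mean: float = 0.2
    conservation_shift: float = 0.3
    conservation_sd: float = 0.08
    conservation_window: int = 500

    def __post_init__(self) -> None:
        if min(self.n_chroms, self.chrom_length, self.n_promoters + self.n_enhancers,
               self.n_replicates) <= 0:
            raise ValueError("counts must be positive")
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-9:
            raise ValueError("cluster proportions must sum to 1")
        if self.planted_lambda < 1.0:
            raise ValueError("planted interaction effect lambda must be >= 1")
        if self.snp_enrichment_factor < 0 or self.gwas_enrichment < 0:
            raise ValueError("enrichment factors must be non-negative")
        if not (0.0 <= self.conservation_base_mean <= 1.0):
            raise ValueError("conservation base mean must lie in [0, 1]")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}

    @property
    def enhancer_width(self) -> int:
        return 2 * self.enhancer_flank + self.enhancer_gap

    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), stage])


@dataclass
class LandscapeTruth:
    """Planted ground truth shared by all generators.

    ``promoters``/``enhancers`` carry the true temporal cluster label
    (``1..4`` or ``flat``), per-feature base expression, strand bias or
    bidirectional balance, and (for enhancers) the novelty flag.
    ``planted_interactions`` lists enhancer/GWAS-promoter contacts, the
    timepoints at which each is active, and its fold effect ``lam``.
    """

    promoters: pd.DataFrame
    enhancers: pd.DataFrame
    probes: pd.DataFrame
    planted_interactions: pd.DataFrame
    known_enhancers: list[GenomicRegion]
    chrom_sizes: dict[str, int]

    def promoter_regions(self) -> list[GenomicRegion]:
        return frame_to_regions(self.promoters)

    def enhancer_regions(self) -> list[GenomicRegion]:
        return frame_to_regions(self.enhancers)

    def probe_regions(self) -> list[GenomicRegion]:
        return frame_to_regions(self.probes)


def cage_samples(config: SimulationConfig) -> list[SampleMetadata]:
    """Sample sheet: timepoints x assays x replicates."""
    out = []
    for t in TIMEPOINTS:
        for assay in ("total", "nascent"):
            for r in range(1, config.n_replicates + 1):
                out.append(SampleMetadata(f"{t}_{assay}_r{r}", t, assay, r))
    return out


def hic_samples(config: SimulationConfig) -> list[tuple[str, int]]:
    return [(t, r) for t in TIMEPOINTS for r in range(1, config.n_replicates + 1)]


def _quota_assign(n: int, proportions: Sequence[float], rng: np.random.Generator) -> np.ndarray:
    """Assign exactly round-share counts per cluster (largest remainder)."""
    raw = np.asarray(proportions, dtype=float) * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    labels = np.concatenate([
        np.full(c, str(i + 1)) for i, c in enumerate(counts)
    ]) if n else np.array([], dtype=object)
    rng.shuffle(labels)
    return labels


def gen_landscape(config: SimulationConfig) -> LandscapeTruth:
    """Place promoters, enhancers, probes and planted contacts on the genome."""
    rng = config._rng(_STAGE_LANDSCAPE)
    n_feat = config.n_promoters + config.n_enhancers
    per_chrom = int(np.ceil(n_feat / config.n_chroms))
    spacing = config.chrom_length // (per_chrom + 1)
    max_width = max(config.promoter_width, config.enhancer_width)
    if spacing < 4 * max_width + 2000:
        raise ValueError(
            f"genome too small to place {n_feat} features without overlap "
            f"(spacing {spacing} bp)"
        )

    kinds = np.array(["P"] * config.n_promoters + ["E"] * config.n_enhancers)
    rng.shuffle(kinds)
    jitter_max = max(1, spacing // 4)

    rows_p, rows_e = [], []
    for i, kind in enumerate(kinds):
        chrom = f"chr{i % config.n_chroms + 1}"
        slot = i // config.n_chroms
        center = (slot + 1) * spacing + int(rng.integers(-jitter_max, jitter_max + 1))
        center = int(np.clip(center, max_width, config.chrom_length - max_width))
        if kind == "P":
            start = center - config.promoter_width // 2
            strand = "+" if rng.random() < 0.5 else "-"
            rows_p.append((f"prom{len(rows_p):04d}", chrom, start,
                           start + config.promoter_width, strand))
        else:
            start = center - config.enhancer_width // 2
            rows_e.append((f"enh{len(rows_e):04d}", chrom, start,
                           start + config.enhancer_width, "."))

    promoters = pd.DataFrame(rows_p, columns=["id", "chrom", "start", "end", "strand"])
    enhancers = pd.DataFrame(rows_e, columns=["id", "chrom", "start", "end", "strand"])

    for df, mean in ((promoters, config.promoter_mean), (enhancers, config.enhancer_mean)):
        n = len(df)
        n_de = int(round(config.frac_de * n))
        de_labels = _quota_assign(n_de, config.cluster_proportions, rng)
        labels = np.concatenate([de_labels, np.full(n - n_de, "flat")])
        rng.shuffle(labels)
        df["cluster"] = labels
        df["base_mean"] = mean * np.exp(
            rng.normal(0.0, config.mean_log_sd, size=n) - config.mean_log_sd**2 / 2
        )

    c = config.enhancer_balance_conc
    enhancers["balance"] = rng.beta(c / 2, c / 2, size=len(enhancers))
    n_known = int(round(config.frac_known_enhancers * len(enhancers)))
    novel = np.array([False] * n_known + [True] * (len(enhancers) - n_known))
    rng.shuffle(novel)
    enhancers["novel"] = novel

    # known-catalog regions: jittered copies of the non-novel enhancers
    known_regions = [
        GenomicRegion(r.chrom, max(0, int(r.start) - int(rng.integers(0, 100))),
                      int(r.end) + int(rng.integers(0, 100)), ".", f"known_{r.id}")
        for r in enhancers[~enhancers["novel"]].itertuples()
    ]

    # probe set: every promoter, a targeted subset of enhancers, negative controls
    probe_rows = [(r.id, r.chrom, r.start, r.end, "promoter")
                  for r in promoters.itertuples()]
    n_target = int(round(config.frac_enhancers_targeted * len(enhancers)))
    target_ids = set(rng.choice(enhancers["id"], size=n_target, replace=False)) \
        if n_target else set()
    # some targeted enhancers carry a GWAS variant and are probed as such
    probe_rows += [
        (r.id, r.chrom, r.start, r.end,
         "gwas" if rng.random() < config.frac_probes_gwas else "enhancer")
        for r in enhancers.itertuples() if r.id in target_ids
    ]

    # negative controls: slot midpoints between feature slots, away from features
    neg = []
    tries = 0
    occupied = pd.concat([promoters, enhancers])[["chrom", "start", "end"]]
    occ_by_chrom = {c: g[["start", "end"]].to_numpy()
                    for c, g in occupied.groupby("chrom")}
    width = config.enhancer_width
    while len(neg) < config.n_negative_controls:
        tries += 1
        if tries > 100 * config.n_negative_controls:
            raise ValueError("genome too crowded to place negative controls")
        chrom = f"chr{int(rng.integers(config.n_chroms)) + 1}"
        start = int(rng.integers(width, config.chrom_length - 2 * width))
        occ = occ_by_chrom.get(chrom)
        if occ is not None and np.any(
            (start < occ[:, 1] + 2000) & (start + width > occ[:, 0] - 2000)
        ):
            continue
        neg.append((f"neg{len(neg):04d}", chrom, start, start + width, "negative_control"))
    probe_rows += neg
    probes = pd.DataFrame(probe_rows,
                          columns=["id", "chrom", "start", "end", "probe_class"])
    probes["strand"] = "."

    # planted interactions: each selected promoter contacts two targeted
    # enhancers on its chromosome.  Flat promoters keep both contacts at
    # every timepoint; DE promoters swap partners — one enhancer is active
    # at the promoter's high timepoints, the other at the complementary
    # ones — so differentially expressed genes rewire their interactomes.
    targeted = enhancers[enhancers["id"].isin(target_ids)]
    enh_by_chrom = {c: g for c, g in targeted.groupby("chrom")}
    planted = []
    prom_order = promoters.sample(frac=1.0,
                                  random_state=int(rng.integers(2**31)))
    for p in prom_order.itertuples():
        if len(planted) >= config.n_planted_interactions:
            break
        enh_c = enh_by_chrom.get(p.chrom)
        if enh_c is None or len(enh_c) < 2:
            continue
        pmid = (p.start + p.end) // 2
        emid = (enh_c["start"] + enh_c["end"]) // 2
        dist = (emid - pmid).abs()
        ok = enh_c[(dist >= config.planted_min_dist)
                   & (dist <= config.planted_max_dist)]
        if len(ok) < 2:
            continue
        pick = ok.sample(2, random_state=int(rng.integers(2**31)))
        shape = _CLUSTER_SHAPES[str(p.cluster)]
        high = [t for t, lev in zip(TIMEPOINTS, shape) if lev > 0]
        low = [t for t in TIMEPOINTS if t not in high] or high
        for enh_row, active in zip(pick.itertuples(), (high, low)):
            planted.append((enh_row.id, p.id, "|".join(active),
                            config.planted_lambda))
    planted_df = pd.DataFrame(planted,
                              columns=["anchor_id", "other_id", "timepoints", "lam"])

    return LandscapeTruth(promoters, enhancers, probes, planted_df,
                          known_regions, config.chrom_sizes)


# ---------------------------------------------------------------------------
# CTSS signal


def _temporal_mean(base: np.ndarray, cluster: np.ndarray, timepoint: str,
                   fold: float) -> np.ndarray:
    """Per-feature expected count at a timepoint, mean over timepoints == base."""
    ti = TIMEPOINTS.index(timepoint)
    mult = np.empty(len(cluster))
    for lab, shape in _CLUSTER_SHAPES.items():
        sel = cluster == lab
        if not sel.any():
            continue
        levels = 1.0 + (fold - 1.0) * np.asarray(shape)
        mult[sel] = levels[ti] / levels.mean()
    return base * mult


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-9)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def gen_ctss(truth: LandscapeTruth, config: SimulationConfig,
             samples: Sequence[SampleMetadata] | None = None) -> dict[str, pd.DataFrame]:
    """Per-sample CTSS tables.

    Promoters emit >= ``promoter_strand_purity`` of their tags on the
    annotated strand in both assays; enhancers emit balanced divergent
    signal (minus tags on the left flank, plus tags on the right flank)
    in nascent libraries and only a trickle in total libraries.  Feature
    counts are negative-binomial around cluster-specific temporal means;
    uniform background noise is sprinkled on top.
    """
    if samples is None:
        samples = cage_samples(config)
    timepoints = {s.timepoint for s in samples}
    unknown = timepoints - set(TIMEPOINTS)
    if unknown:
        raise ValueError(f"unknown timepoint(s) {sorted(unknown)}")
    rng = config._rng(_STAGE_CTSS)
    out: dict[str, pd.DataFrame] = {}

    proms, enhs = truth.promoters, truth.enhancers

    # shared per-(contact, timepoint) expression factor: features joined by
    # an active planted contact co-fluctuate at that timepoint only
    factor: dict[tuple[str, str], float] = {}
    sd = config.expression_coupling_sd
    for pi in truth.planted_interactions.itertuples():
        for t in pi.timepoints.split("|"):
            f = float(np.exp(rng.normal(0.0, sd) - sd**2 / 2)) if sd > 0 else 1.0
            for fid in (pi.anchor_id, pi.other_id):
                factor.setdefault((fid, t), f)

    def _coupling(ids: np.ndarray, timepoint: str) -> np.ndarray:
        return np.array([factor.get((i, timepoint), 1.0) for i in ids])

    for s in samples:
        chroms, poss, strands = [], [], []

        # promoters
        p_mean = _temporal_mean(proms["base_mean"].to_numpy(),
                                proms["cluster"].to_numpy(), s.timepoint,
                                config.temporal_fold)
        p_mean = p_mean * _coupling(proms["id"].to_numpy(), s.timepoint)
        p_counts = _nb_counts(rng, p_mean, config.dispersion)
        for row, total in zip(proms.itertuples(), p_counts):
            if total == 0:
                continue
            sense = int(rng.binomial(total, config.promoter_strand_purity))
            summit = (row.start + row.end) // 2
            for n_tags, strand in ((sense, row.strand),
                                   (total - sense, "-" if row.strand == "+" else "+")):
                if n_tags == 0:
                    continue
                pos = np.clip(np.round(rng.normal(summit, 6, size=n_tags)),
                              row.start, row.end - 1).astype(int)
                chroms.append(np.full(n_tags, row.chrom, dtype=object))
                poss.append(pos)
                strands.append(np.full(n_tags, strand, dtype=object))

        # enhancers
        e_mean = _temporal_mean(enhs["base_mean"].to_numpy(),
                                enhs["cluster"].to_numpy(), s.timepoint,
                                config.temporal_fold)
        e_mean = e_mean * _coupling(enhs["id"].to_numpy(), s.timepoint)
        if s.assay == "total":
            e_mean = e_mean * config.enhancer_total_rate
        e_counts = _nb_counts(rng, e_mean, config.dispersion)
        half_gap = config.enhancer_gap // 2
        for row, total, bal in zip(enhs.itertuples(), e_counts, enhs["balance"]):
            if total == 0:
                continue
            mid = (row.start + row.end) // 2
            n_plus = int(rng.binomial(total, bal))
            for n_tags, strand, center, lo, hi in (
                (n_plus, "+", mid + half_gap + config.enhancer_flank // 2,
                 mid + half_gap, row.end - 1),
                (total - n_plus, "-", mid - half_gap - config.enhancer_flank // 2,
                 row.start, mid - half_gap),
            ):
                if n_tags == 0 or hi < lo:
                    continue
                pos = np.clip(np.round(rng.normal(center, 15, size=n_tags)),
                              lo, hi).astype(int)
                chroms.append(np.full(n_tags, row.chrom, dtype=object))
                poss.append(pos)
                strands.append(np.full(n_tags, strand, dtype=object))

        # uniform background noise
        n_noise = rng.poisson(config.noise_rate * config.chrom_length * config.n_chroms)
        if n_noise:
            chroms.append(np.array(
                [f"chr{i + 1}" for i in rng.integers(config.n_chroms, size=n_noise)],
                dtype=object))
            poss.append(rng.integers(0, config.chrom_length, size=n_noise))
            strands.append(np.where(rng.random(n_noise) < 0.5, "+", "-").astype(object))

        if chroms:
            df = pd.DataFrame({
                "chrom": np.concatenate(chroms),
                "pos": np.concatenate(poss).astype(int),
                "strand": np.concatenate(strands),
            })
            df = (df.groupby(["chrom", "pos", "strand"], as_index=False)
                    .size().rename(columns={"size": "count"})
                    .sort_values(["chrom", "pos", "strand"], ignore_index=True))
        else:
            df = pd.DataFrame(columns=["chrom", "pos", "strand", "count"])
        df["sample_id"] = s.sample_id
        out[s.sample_id] = df
    return out


# ---------------------------------------------------------------------------
# Hi-C


def _decay_probs(config: SimulationConfig) -> np.ndarray:
    """Distance-bin probabilities p_k over k = 1..K (distance k * bin_size)."""
    k = np.arange(1, config.hic_max_distance // config.hic_bin_size + 1)
    w = (k * config.hic_bin_size).astype(float) ** (-config.decay_exponent)
    return w / w.sum()


def expected_background_support(config: SimulationConfig, distance: float) -> float:
    """Expected supporting pairs at one (anchor, other-end bin) slot.

    Background pairs split evenly between the two sides of the anchor.
    """
    probs = _decay_probs(config)
    k = int(round(distance / config.hic_bin_size))
    k = min(max(k, 1), len(probs))
    return config.pairs_per_anchor * probs[k - 1] / 2.0


def expected_planted_support(config: SimulationConfig, distance: float) -> float:
    return config.planted_lambda * expected_background_support(config, distance)


def gen_hic(truth: LandscapeTruth, config: SimulationConfig,
            samples: Sequence[tuple[str, int]] | None = None) -> dict[str, pd.DataFrame]:
    """Per-(timepoint, replicate) valid-pair tables.

    Background contact counts at distance d fall off as d^-decay_exponent,
    identically for every probe class, so negative controls carry pure
    background.  A planted interaction (a, b) active at timepoint t adds
    Poisson((lambda - 1) x expected background) extra pairs between a's
    probe and the 2 kb bin containing b's midpoint, in both replicates.
    """
    if samples is None:
        samples = hic_samples(config)
    rng = config._rng(_STAGE_HIC)
    probs = _decay_probs(config)
    ks = np.arange(1, len(probs) + 1)
    bin_size = config.hic_bin_size

    probes = truth.probes
    feat_loc = {}
    for df in (truth.promoters, truth.enhancers, probes):
        for r in df.itertuples():
            feat_loc[r.id] = (r.chrom, r.start, r.end)

    a_chrom = probes["chrom"].to_numpy()
    a_start = probes["start"].to_numpy()
    a_end = probes["end"].to_numpy()
    a_mid = (a_start + a_end) // 2

    out: dict[str, pd.DataFrame] = {}
    for timepoint, rep in samples:
        c1, p1, c2, p2 = [], [], [], []

        # background: Poisson counts over (anchor, side, distance bin)
        lam = np.broadcast_to(config.pairs_per_anchor * probs / 2.0,
                              (len(probes), 2, len(probs)))
        counts = rng.poisson(lam)
        flat = counts.reshape(-1)
        nz = np.flatnonzero(flat)
        reps_n = flat[nz]
        anchor_idx = np.repeat(nz // (2 * len(probs)), reps_n)
        side = np.repeat(np.where((nz // len(probs)) % 2 == 0, -1, 1), reps_n)
        k_idx = np.repeat(nz % len(probs), reps_n)
        n_tot = len(anchor_idx)
        width = a_end[anchor_idx] - a_start[anchor_idx]
        end1 = a_start[anchor_idx] + (rng.random(n_tot) * width).astype(int)
        off = ks[k_idx] * bin_size + rng.integers(0, bin_size, size=n_tot)
        end2 = a_mid[anchor_idx] + side * off
        keep = (end2 >= 0) & (end2 < config.chrom_length)
        if keep.any():
            c1.append(a_chrom[anchor_idx[keep]])
            p1.append(end1[keep])
            c2.append(a_chrom[anchor_idx[keep]])
            p2.append(end2[keep])

        # planted contacts active at this timepoint: both ends inside the
        # partner features, so both anchors accumulate support
        for pi in truth.planted_interactions.itertuples():
            if timepoint not in pi.timepoints.split("|"):
                continue
            chrom_a, astart, aend = feat_loc[pi.anchor_id]
            chrom_b, bstart, bend = feat_loc[pi.other_id]
            if chrom_a != chrom_b:
                continue
            dist = abs((bstart + bend) // 2 - (astart + aend) // 2)
            extra_mean = (pi.lam - 1.0) * expected_background_support(config, dist)
            n = rng.poisson(extra_mean)
            if n == 0:
                continue
            end1 = rng.integers(astart, aend, size=n)
            end2 = rng.integers(bstart, bend, size=n)
            c1.append(np.full(n, chrom_a, dtype=object))
            p1.append(end1)
            c2.append(np.full(n, chrom_b, dtype=object))
            p2.append(end2)

        if c1:
            df = pd.DataFrame({
                "chrom1": np.concatenate(c1), "pos1": np.concatenate(p1).astype(int),
                "chrom2": np.concatenate(c2), "pos2": np.concatenate(p2).astype(int),
            })
        else:
            df = pd.DataFrame(columns=["chrom1", "pos1", "chrom2", "pos2"])
        df["strand1"] = "+"
        df["strand2"] = "-"
        # canonicalize end order
        flip = df["pos1"] > df["pos2"]
        df.loc[flip, ["pos1", "pos2"]] = df.loc[flip, ["pos2", "pos1"]].to_numpy()
        sid = f"hic_{timepoint}_r{rep}"
        df["sample_id"] = sid
        out[sid] = df[["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2",
                       "sample_id"]]
    return out


# ---------------------------------------------------------------------------
# Variants, LD, GWAS, eQTL


def gen_variants(truth: LandscapeTruth, config: SimulationConfig
                 ) -> tuple[pd.DataFrame, pd.DataFrame, list[str], list[str]]:
    """Variant table, LD pair table, GWAS index-SNP ids and eQTL SNP ids.

    SNP density inside enhancers is ``snp_enrichment_factor`` x background;
    GWAS index SNPs land inside enhancers ``gwas_enrichment`` times more
    often than a random pool SNP would; eQTL flags are elevated inside
    enhancers by ``eqtl_enrichment``.
    """
    rng = config._rng(_STAGE_VAR)
    genome_bp = config.n_chroms * config.chrom_length
    enh = truth.enhancers
    enh_bp = int((enh["end"] - enh["start"]).sum())

    n_bg = rng.poisson(config.variant_density * genome_bp)
    chroms = np.array([f"chr{i + 1}" for i in rng.integers(config.n_chroms, size=n_bg)],
                      dtype=object)
    poss = rng.integers(0, config.chrom_length, size=n_bg)

    extra_rate = max(0.0, config.snp_enrichment_factor - 1.0) * config.variant_density
    n_extra = rng.poisson(extra_rate * enh_bp) if enh_bp else 0
    if n_extra:
        widths = (enh["end"] - enh["start"]).to_numpy()
        pick = rng.choice(len(enh), size=n_extra, p=widths / widths.sum())
        e = enh.iloc[pick]
        chroms = np.concatenate([chroms, e["chrom"].to_numpy()])
        poss = np.concatenate([
            poss,
            (e["start"].to_numpy()
             + (rng.random(n_extra) * widths[pick]).astype(int)),
        ])

    order = np.lexsort((poss, chroms))
    chroms, poss = chroms[order], poss[order]
    n = len(poss)
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(4, size=n)]
    alt_off = rng.integers(1, 4, size=n)
    alt = bases[(np.searchsorted(bases, ref) + alt_off) % 4]
    variants = pd.DataFrame({
        "id": [f"snp{i:06d}" for i in range(n)],
        "chrom": chroms, "pos": poss, "ref": ref, "alt": alt,
        "af": rng.beta(config.af_alpha, config.af_beta, size=n),
    })

    # in-enhancer flag
    in_enh = np.zeros(n, dtype=bool)
    for c, g in enh.groupby("chrom"):
        sel = variants["chrom"] == c
        if not sel.any():
            continue
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        srt = np.argsort(starts)
        starts, ends = starts[srt], ends[srt]
        pos = variants.loc[sel, "pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(len(pos), dtype=bool)
        hit[ok] = pos[ok] < ends[idx[ok]]
        in_enh[sel.to_numpy()] = hit
    variants["in_enhancer"] = in_enh

    # LD: pairs within a block, r2 decaying with distance
    ld_rows = []
    block = config.ld_block_size
    if block > 1:
        variants["_block"] = variants["pos"] // block
        for (_, _), g in variants.groupby(["chrom", "_block"]):
            ids = g["id"].to_numpy()
            pos = g["pos"].to_numpy()
            for i in range(len(g)):
                for j in range(i + 1, len(g)):
                    d = int(abs(pos[j] - pos[i]))
                    r2 = float(np.exp(-d / (block / 4.0)) * rng.uniform(0.85, 1.0))
                    if r2 >= 0.05:
                        ld_rows.append((ids[i], ids[j], r2, d))
        variants = variants.drop(columns="_block")
    ld = pd.DataFrame(ld_rows, columns=["snp_a", "snp_b", "r2", "distance"])

    # GWAS index SNPs with planted enhancer enrichment
    pool_frac = in_enh.mean() if n else 0.0
    p_enh = min(0.95, config.gwas_enrichment * pool_frac)
    enh_ids = variants.loc[variants["in_enhancer"], "id"].to_numpy()
    bg_ids = variants.loc[~variants["in_enhancer"], "id"].to_numpy()
    gwas: list[str] = []
    n_gwas = min(config.n_gwas_snps, n)
    n_in = min(rng.binomial(n_gwas, p_enh), len(enh_ids))
    if n_in:
        gwas += list(rng.choice(enh_ids, size=n_in, replace=False))
    n_out = min(n_gwas - n_in, len(bg_ids))
    if n_out:
        gwas += list(rng.choice(bg_ids, size=n_out, replace=False))

    # eQTLs
    p_eqtl = np.where(in_enh,
                      min(1.0, config.eqtl_base_rate * config.eqtl_enrichment),
                      config.eqtl_base_rate)
    eqtl = list(variants.loc[rng.random(n) < p_eqtl, "id"])

    return variants, ld, gwas, eqtl


# ---------------------------------------------------------------------------
# Conservation


def gen_conservation(truth: LandscapeTruth, config: SimulationConfig) -> pd.DataFrame:
    """Piecewise-constant conservation track as a bedGraph frame.

    Windowed background scores around ``conservation_base_mean``; inside
    enhancers the mean is shifted up by ``conservation_shift``.  All
    scores clipped into [0, 1].
    """
    rng = config._rng(_STAGE_CONS)
    w = config.conservation_window
    rows = []
    enh_by_chrom = {c: g.sort_values("start")
                    for c, g in truth.enhancers.groupby("chrom")}
    for chrom, size in truth.chrom_sizes.items():
        starts = np.arange(0, size, w)
        ends = np.minimum(starts + w, size)
        scores = np.clip(rng.normal(config.conservation_base_mean,
                                    config.conservation_sd, size=len(starts)), 0, 1)
        segs = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                             "score": scores})
        enh = enh_by_chrom.get(chrom)
        if enh is not None and len(enh):
            pieces = []
            cursor = segs
            for r in enh.itertuples():
                # punch out the enhancer span from background windows
                before = cursor[cursor["end"] <= r.start]
                after = cursor[cursor["start"] >= r.end]
                straddle = cursor[(cursor["start"] < r.end) & (cursor["end"] > r.start)]
                clipped = []
                for srow in straddle.itertuples():
                    if srow.start < r.start:
                        clipped.append((chrom, srow.start, r.start, srow.score))
                    if srow.end > r.end:
                        clipped.append((chrom, r.end, srow.end, srow.score))
                pieces.append(before)
                if clipped:
                    pieces.append(pd.DataFrame(
                        clipped, columns=["chrom", "start", "end", "score"]))
                score = float(np.clip(
                    rng.normal(config.conservation_base_mean + config.conservation_shift,
                               config.conservation_sd), 0, 1))
                pieces.append(pd.DataFrame(
                    [(chrom, r.start, r.end, score)],
                    columns=["chrom", "start", "end", "score"]))
                cursor = after
            pieces.append(cursor)
            segs = pd.concat(pieces, ignore_index=True).sort_values("start")
        rows.append(segs)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# One-call bundle


@dataclass
class SimulatedData:
    config: SimulationConfig
    truth: LandscapeTruth
    samples: list[SampleMetadata]
    ctss: dict[str, pd.DataFrame]
    hic: dict[str, pd.DataFrame]
    variants: pd.DataFrame
    ld: pd.DataFrame
    gwas_snps: list[str]
    eqtl_snps: list[str]
    conservation: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "truth").mkdir(exist_ok=True)
        write_chrom_sizes(self.truth.chrom_sizes, outdir / "genome.chrom.sizes")
        t = self.truth
        write_bed(frame_to_regions(t.promoters), outdir / "promoters.bed")
        write_bed(frame_to_regions(t.enhancers), outdir / "enhancers.bed")
        write_bed(frame_to_regions(t.probes), outdir / "probes.bed",
                  extra=t.probes[["probe_class"]])
        write_bed(t.known_enhancers, outdir / "known_enhancers.bed")
        for sid, df in self.ctss.items():
            write_ctss(df, outdir / f"ctss_{sid}.tsv")
        for sid, df in self.hic.items():
            write_pairs(df, outdir / f"pairs_{sid}.tsv")
        write_variants(self.variants, outdir / "variants.tsv")
        write_ld(self.ld, outdir / "ld.tsv")
        (outdir / "gwas_snps.txt").write_text("\n".join(self.gwas_snps) + "\n")
        (outdir / "eqtl_snps.txt").write_text("\n".join(self.eqtl_snps) + "\n")
        write_bedgraph(self.conservation, outdir / "conservation.bedgraph")
        pd.DataFrame([asdict(s) for s in self.samples]).to_csv(
            outdir / "samples.tsv", sep="\t", index=False)
        t.promoters.to_csv(outdir / "truth" / "promoters.tsv", sep="\t", index=False)
        t.enhancers.to_csv(outdir / "truth" / "enhancers.tsv", sep="\t", index=False)
        t.planted_interactions.to_csv(
            outdir / "truth" / "planted_interactions.tsv", sep="\t", index=False)


def simulate_all(config: SimulationConfig, outdir: str | Path | None = None
                 ) -> SimulatedData:
    """Generate every pipeline input with planted ground truth."""
    truth = gen_landscape(config)
    samples = cage_samples(config)
    data = SimulatedData(
        config=config,
        truth=truth,
        samples=samples,
        ctss=gen_ctss(truth, config, samples),
        hic=gen_hic(truth, config),
        conservation=gen_conservation(truth, config),
        **dict(zip(("variants", "ld", "gwas_snps", "eqtl_snps"),
                   gen_variants(truth, config))),
    )
    if outdir is not None:
        data.write(outdir)
    return data
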