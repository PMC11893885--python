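"""Headline summary arithmetic, qPCR fold-change arithmetic, run reports.

Every percentage in a run report is stored beside the integer numerator
and denominator it came from, so the report is self-consistent by
construction and re-checkable after the fact.  Rounding is half-up, to
one decimal for enhancer-catalog style fractions and to the nearest
integer for interaction-involvement style fractions.
"""

from __future__ import annotations

import hashlib
import json
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int, ndigits: int = 1) -> dict:
    """A percentage bundled with the integers that produced it."""
    value = (round_half_up(100.0 * numerator / denominator, ndigits)
             if denominator else float("nan"))
    if denominator and ndigits == 0:
        value = int(value)
    return {"value": value, "numerator": int(numerator),
            "denominator": int(denominator), "ndigits": ndigits}


def summarize_universe(
    known_set_sizes: Sequence[int],
    n_loci: int,
    n_known_loci: int,
    n_retained: int,
    n_novel_retained: int,
) -> dict:
    """Catalog arithmetic: overlap %, novel %, combined enhancer universe.

    overlap % = known loci / all bidirectional loci (1 decimal);
    novel % = novel retained enhancers / retained enhancers (1 decimal);
    universe = sum of known catalog sizes + novel loci.
    """
    n_novel_loci = n_loci - n_known_loci
    return {
        "overlap_pct": percentage(n_known_loci, n_loci, 1),
        "novel_pct": percentage(n_novel_retained, n_retained, 1),
        "universe_total": int(sum(known_set_sizes) + n_novel_loci),
        "n_loci": int(n_loci),
        "n_novel_loci": int(n_novel_loci),
    }


def summarize_interactions(
    n_interactions: int,
    n_de_involved: int,
    n_de_enhancers: int,
    n_de_enhancers_interacting: int,
    n_gwas_anchors: int,
    n_gwas_interacting: int,
) -> dict:
    """Interaction involvement ratios.

    % interactions involving a DE feature (integer rounding); % DE
    enhancers with >= 1 interaction (1 decimal); % GWAS anchors with
    >= 1 interaction (integer rounding).
    """
    return {
        "de_involved_pct": percentage(n_de_involved, n_interactions, 0),
        "de_enhancers_interacting_pct": percentage(
            n_de_enhancers_interacting, n_de_enhancers, 1),
        "gwas_interacting_pct": percentage(n_gwas_interacting, n_gwas_anchors, 0),
    }


# ---------------------------------------------------------------------------
# qPCR relative quantification


QPCR_COLUMNS = ["condition", "target_ct", "reference_ct", "replicate"]


def fold_change_ddct(qpcr: pd.DataFrame, control: str) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference per replicate; ddCt = mean dCt of the
    condition minus mean dCt of the control; fold = 2^-ddCt.  Per-replicate
    folds (each replicate's dCt against the control mean) give the SEM.
    """
    missing = set(QPCR_COLUMNS) - set(qpcr.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns {sorted(missing)}")
    if (qpcr[["target_ct", "reference_ct"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")
    if control not in set(qpcr["condition"]):
        raise ValueError(f"control condition {control!r} missing")
    df = qpcr.copy()
    df["dct"] = df["target_ct"] - df["reference_ct"]
    control_mean = df.loc[df["condition"] == control, "dct"].mean()
    rows = []
    for cond, g in df.groupby("condition", sort=False):
        ddct = g["dct"].mean() - control_mean
        rep_folds = 2.0 ** (-(g["dct"] - control_mean))
        sem = float(rep_folds.std(ddof=1) / np.sqrt(len(g))) if len(g) > 1 else np.nan
        rows.append((cond, float(ddct), float(2.0 ** (-ddct)),
                     float(rep_folds.mean()), sem, len(g)))
    return pd.DataFrame(rows, columns=["condition", "ddct", "fold",
                                       "mean_rep_fold", "sem", "n"]
                        ).set_index("condition")


def qpcr_anova_dunnett(qpcr: pd.DataFrame, control: str) -> dict:
    """One-way ANOVA on dCt across conditions, then Dunnett vs the control."""
    df = qpcr.copy()
    df["dct"] = df["target_ct"] - df["reference_ct"]
    if control not in set(df["condition"]):
        raise ValueError(f"control condition {control!r} missing")
    groups = {c: g["dct"].to_numpy() for c, g in df.groupby("condition", sort=False)}
    others = [c for c in groups if c != control]
    f, p = stats.f_oneway(*groups.values())
    res = stats.dunnett(*[groups[c] for c in others], control=groups[control])
    return {
        "anova_F": float(f),
        "anova_p": float(p),
        "dunnett": {c: float(pv) for c, pv in zip(others, res.pvalue)},
    }


# ---------------------------------------------------------------------------
# Run report


def config_hash(config: Mapping) -> str:
    payload = json.dumps({k: config[k] for k in sorted(config)}, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_report(report: Mapping) -> None:
    """Re-derive every percentage from its stored integers; raise on mismatch."""

    def walk(obj) -> None:
        if isinstance(obj, Mapping):
            if {"value", "numerator", "denominator", "ndigits"} <= set(obj):
                num, den, nd = obj["numerator"], obj["denominator"], obj["ndigits"]
                if den:
                    expect = round_half_up(100.0 * num / den, nd)
                    if nd == 0:
                        expect = int(expect)
                    if expect != obj["value"]:
                        raise AssertionError(
                            f"inconsistent percentage: {obj['value']} != "
                            f"100*{num}/{den} rounded to {nd} decimals")
                elif obj["value"] == obj["value"]:  # NaN expected
                    raise AssertionError("percentage with zero denominator "
                                         "must be NaN")
            else:
                for v in obj.values():
                    walk(v)
        elif isinstance(obj, (list, tuple)):
            for v in obj:
                walk(v)

    walk(report)
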