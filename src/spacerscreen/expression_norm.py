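"""Native-promoter expression analysis.

Relative expression from RNA-seq-like count tables (reads normalized by
CDS length and sequencing depth, then divided by the all-gene average, so
a value of 10 means ten-fold the average gene), promoter strength as the
maximum over timepoints, sigma70 consensus filtering of annotated
promoters, and spacer-length distributions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .sequence_features import SpacerSeq, consensus_mismatches

__all__ = [
    "relative_expression",
    "promoter_strength",
    "consensus_filter",
    "length_distribution",
    "expression_by_length",
    "read_promoter_table",
]

log = logging.getLogger(__name__)

PROMOTER_COLUMNS = ["promoter_id", "gene", "minus35", "spacer", "minus10", "sigma"]


def _timepoint_columns(counts: pd.DataFrame) -> list[str]:
    return [c for c in counts.columns if c not in ("gene", "cds_length")]


def relative_expression(counts: pd.DataFrame) -> pd.DataFrame:
    """Depth- and CDS-length-normalized expression relative to the average gene.

    For each timepoint: v_g = (counts_g / total) / cds_length_g, then
    divided by the mean of v over genes, so the gene average is exactly 1.
    Genes with zero counts everywhere keep relative expression 0.
    """
    tps = _timepoint_columns(counts)
    if not tps:
        raise ValueError("counts table has no timepoint columns")
    if (counts["cds_length"] <= 0).any():
        raise ValueError("cds_length must be positive")
    out = counts[["gene"]].copy()
    for tp in tps:
        c = counts[tp].to_numpy(dtype=float)
        if (c < 0).any():
            raise ValueError(f"negative counts at {tp}")
        total = c.sum()
        if total == 0:
            raise ValueError(f"timepoint {tp} has zero total counts")
        v = c / total / counts["cds_length"].to_numpy(dtype=float)
        out[tp] = v / v.mean()
    return out


def promoter_strength(rel: pd.DataFrame) -> pd.Series:
    """Promoter strength: maximal relative expression over timepoints, per gene."""
    tps = _timepoint_columns(rel)
    if not tps:
        raise ValueError("no timepoint columns")
    return rel.set_index("gene")[tps].max(axis=1).rename("strength")


def consensus_filter(
    promoters: pd.DataFrame, max_mismatches: int = 3, per_element: bool = False
) -> pd.DataFrame:
    """Keep promoters close to the sigma70 consensus (TTGACA / TATAAT).

    By default the mismatch budget is summed over the two hexamers
    (<= max_mismatches in total); per_element applies it to each hexamer
    separately.  Malformed hexamers reject the record with a log entry.
    """
    keep = []
    for i, row in promoters.iterrows():
        try:
            total = consensus_mismatches(row["minus10"], row["minus35"])
            if per_element:
                d10 = sum(a != b for a, b in zip(row["minus10"].upper(), "TATAAT"))
                d35 = sum(a != b for a, b in zip(row["minus35"].upper(), "TTGACA"))
                ok = d10 <= max_mismatches and d35 <= max_mismatches
            else:
                ok = total <= max_mismatches
        except ValueError as exc:
            log.warning("promoter %s rejected: %s", row.get("promoter_id", i), exc)
            continue
        if ok:
            keep.append(i)
    return promoters.loc[keep].copy()


def length_distribution(promoters: pd.DataFrame) -> pd.Series:
    """Histogram of spacer lengths (counts per length, sorted by length)."""
    if len(promoters) == 0:
        raise ValueError("empty promoter table")
    lengths = promoters["spacer"].str.len()
    return lengths.value_counts().sort_index().rename("count")


def expression_by_length(promoters: pd.DataFrame, strengths: pd.Series) -> pd.DataFrame:
    """Per-spacer-length distribution of promoter strengths.

    ``strengths`` is indexed by gene (see promoter_strength); promoters
    whose gene lacks a strength value are ignored.
    """
    df = promoters.copy()
    df["length"] = df["spacer"].str.len()
    df = df[df["gene"].isin(strengths.index)]
    df["strength"] = strengths.loc[df["gene"]].to_numpy()
    rows = []
    for length, sub in df.groupby("length"):
        v = sub["strength"]
        rows.append(
            {
                "length": int(length),
                "n": len(v),
                "mean": v.mean(),
                "median": v.median(),
                "q25": v.quantile(0.25),
                "q75": v.quantile(0.75),
            }
        )
    return pd.DataFrame(rows).sort_values("length").reset_index(drop=True)


def read_promoter_table(path) -> pd.DataFrame:
    """Read the minimal RegulonDB-dialect promoter TSV and validate its schema."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = set(PROMOTER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"promoter table missing columns: {sorted(missing)}")
    bad_len = ~df["spacer"].str.len().between(10, 30)
    if bad_len.any():
        raise ValueError(f"{int(bad_len.sum())} promoters have spacer length outside 10..30")
    for s in df["spacer"]:
        SpacerSeq(s)
    return df
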