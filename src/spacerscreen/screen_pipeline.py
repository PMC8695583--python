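"""Statistics for promoter-library plate screens.

The pipeline consumes tidy endpoint or time-course tables (one row per
well) and computes the screen's derived quantities: blank-corrected
RFU/OD600, per-length summaries, weak/strong extreme groups, TG-motif
enrichment, melting-energy group comparisons, treated/untreated
supercoiling-sensitivity ratios with strength-bias correction, GC-bin
up/down ratios, and growth-phase timing preference.

Sensitivity convention: ratio = treated / untreated RFU/OD600; 1 is
neutral, >1 means the promoter gains activity upon DNA relaxation
(relaxation preference), <1 means it loses activity (relaxation
intolerance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .sequence_features import (
    LogoMatrix,
    extended_minus10,
    gc_content,
    logo,
    melting_profile,
)
from .synthetic_library import PlateSeries

__all__ = [
    "TimingRecord",
    "normalize",
    "summarize_by_length",
    "select_extremes",
    "motif_enrichment",
    "melting_group_compare",
    "sensitivity",
    "bias_correct",
    "spearman_strength_sensitivity",
    "gc_bin_ratio",
    "timing_preference",
    "DEFAULT_GC_EDGES",
]

log = logging.getLogger(__name__)

DEFAULT_GC_EDGES = np.linspace(0.2, 0.8, 6)


@dataclass(frozen=True)
class TimingRecord:
    """Fraction of final reporter signal already present at the OD600=0.3 crossing."""

    clone_id: str
    expo_fraction: float
    flagged: bool = False


def normalize(endpoints: pd.DataFrame, od_floor: float = 0.05) -> pd.DataFrame:
    """Blank-corrected RFU/OD600 per well.

    Expects columns od600, rfu, blank_od, blank_rfu.  Wells whose
    blank-corrected OD600 is at or below ``od_floor`` are flagged invalid
    (rfu_per_od NaN) rather than silently dropped.
    """
    out = endpoints.copy()
    od_corr = out["od600"] - out["blank_od"]
    rfu_corr = out["rfu"] - out["blank_rfu"]
    valid = od_corr > od_floor
    with np.errstate(divide="ignore", invalid="ignore"):
        out["rfu_per_od"] = np.where(valid, rfu_corr / od_corr, np.nan)
    out["valid"] = valid
    n_bad = int((~valid).sum())
    if n_bad:
        log.info("normalize: %d wells below od_floor=%.3g flagged invalid", n_bad, od_floor)
    return out


def summarize_by_length(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-spacer-length distribution of RFU/OD600; controls as the 'c' row."""
    df = normalized[normalized["valid"]].copy()
    df["group"] = np.where(df.get("is_control", False), "c", df["length"].astype(str))
    rows = []
    for group, sub in df.groupby("group"):
        v = sub["rfu_per_od"]
        rows.append(
            {
                "length": group,
                "n": len(v),
                "mean": v.mean(),
                "median": v.median(),
                "q25": v.quantile(0.25),
                "q75": v.quantile(0.75),
            }
        )
    out = pd.DataFrame(rows)
    key = out["length"].apply(lambda s: (1, 0) if s == "c" else (0, int(s)))
    return out.iloc[np.argsort(key.to_numpy())].reset_index(drop=True)


def select_extremes(normalized: pd.DataFrame, k: int = 48) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bottom-k (weak) and top-k (strong) clones by RFU/OD600.

    Ties are broken by clone id, so the partition is invariant to input
    order.  Raises if fewer than 2k valid clones are supplied.
    """
    df = normalized[normalized["valid"]]
    if len(df) < 2 * k:
        raise ValueError(f"need at least {2 * k} valid clones, got {len(df)}")
    ranked = df.sort_values(["rfu_per_od", "clone_id"], kind="mergesort")
    return ranked.head(k).copy(), ranked.tail(k).copy()


def motif_enrichment(weak_seqs, strong_seqs) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, LogoMatrix]]:
    """TG-motif composition of the weak and strong extreme groups.

    Returns (per-position TG-start frequencies, extended -10 summary with
    95% binomial confidence intervals, sequence logos per group).  All
    spacers within a group must share one length.
    """
    groups = {"weak": [str(s) for s in weak_seqs], "strong": [str(s) for s in strong_seqs]}
    pos_rows, ext_rows, logos = [], [], {}
    for name, seqs in groups.items():
        if len({len(s) for s in seqs}) != 1:
            raise ValueError(f"{name} group has ragged spacer lengths")
        L = len(seqs[0])
        n = len(seqs)
        for pos in range(1, L):  # TG starting at 1-based position pos
            cnt = sum(s[pos - 1 : pos + 1] == "TG" for s in seqs)
            pos_rows.append({"group": name, "position": pos, "tg_freq": cnt / n, "n": n})
        ext = sum(extended_minus10(s).has_extended_minus10 for s in seqs)
        tandem = sum(extended_minus10(s).tandem_len >= 2 for s in seqs)
        lo, hi = proportion_confint(ext, n, alpha=0.05, method="wilson")
        ext_rows.append(
            {
                "group": name,
                "n": n,
                "extended_minus10_freq": ext / n,
                "ci_low": lo,
                "ci_high": hi,
                "tandem_freq": tandem / n,
                "mean_tg_count": float(np.mean([extended_minus10(s).tg_count for s in seqs])),
            }
        )
        logos[name] = logo(seqs)
    return pd.DataFrame(pos_rows), pd.DataFrame(ext_rows), logos


def melting_group_compare(weak_seqs, strong_seqs) -> pd.DataFrame:
    """Position-wise Welch test of melting energies between extreme groups.

    One row per dinucleotide step: group means/SEs, Welch t, raw and
    Benjamini-Hochberg-adjusted p.  Identical groups give p = 1 everywhere.
    """
    w = np.array([melting_profile(s).step_energies for s in weak_seqs])
    s = np.array([melting_profile(s).step_energies for s in strong_seqs])
    if w.shape[0] < 2 or s.shape[0] < 2:
        raise ValueError("each group needs at least 2 sequences")
    if w.shape[1] != s.shape[1]:
        raise ValueError("groups must share one spacer length")
    rows = []
    for j in range(w.shape[1]):
        a, b = w[:, j], s[:, j]
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            t, p = 0.0, 1.0 if a.mean() == b.mean() else 0.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "step": j + 1,
                "mean_weak": a.mean(),
                "se_weak": a.std(ddof=1) / np.sqrt(a.size),
                "mean_strong": b.mean(),
                "se_strong": b.std(ddof=1) / np.sqrt(b.size),
                "effect": a.mean() - b.mean(),
                "t": float(t),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def sensitivity(normalized: pd.DataFrame) -> pd.DataFrame:
    """Treated/untreated RFU/OD600 ratio per clone.

    Expects a normalized endpoint table with exactly two conditions
    (0 = untreated and one treated dose).  Clones missing a valid
    measurement in either condition are skipped with a log entry.
    Returns one row per clone: strength (untreated RFU/OD600), ratio,
    gc, length.
    """
    conds = sorted(normalized["condition"].unique())
    if len(conds) != 2 or conds[0] != 0.0:
        raise ValueError(f"expected untreated (0) plus one treated condition, got {conds}")
    df = normalized[normalized["valid"]]
    untreated = df[df["condition"] == conds[0]].set_index("clone_id")
    treated = df[df["condition"] == conds[1]].set_index("clone_id")
    common = untreated.index.intersection(treated.index)
    skipped = set(untreated.index).symmetric_difference(treated.index)
    if skipped:
        log.info("sensitivity: %d clones missing one condition, skipped", len(skipped))
    u = untreated.loc[common]
    rows = pd.DataFrame(
        {
            "clone_id": common,
            "strength": u["rfu_per_od"].to_numpy(),
            "ratio": treated.loc[common, "rfu_per_od"].to_numpy() / u["rfu_per_od"].to_numpy(),
            "length": u["length"].to_numpy(),
            "gc": [gc_content(s) for s in u["spacer"]],
            "is_control": u.get("is_control", pd.Series(False, index=common)).to_numpy(),
        }
    )
    bad = (rows["ratio"] <= 0) | (rows["strength"] <= 0)
    if bad.any():
        log.info("sensitivity: %d clones with non-positive signal dropped", int(bad.sum()))
    return rows[~bad].reset_index(drop=True)


def bias_correct(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Remove the promoter-strength bias from sensitivity ratios.

    Fits OLS of log2(ratio) on log10(strength) and divides each ratio by
    the fitted trend, so corrected_ratio is neutral at 1 and carries only
    the strength-independent supercoiling response.
    """
    if len(records) < 10:
        raise ValueError("bias correction needs at least 10 records")
    s = records["strength"].to_numpy(dtype=float)
    if np.log10(s.max() / s.min()) <= 1.0:
        raise ValueError("strength spread must exceed one decade for a stable regression")
    x = np.log10(s)
    y = np.log2(records["ratio"].to_numpy(dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    out = records.copy()
    out["corrected_ratio"] = 2.0**resid
    fit = {"slope": float(slope), "intercept": float(intercept), "n": len(records)}
    return out, fit


def spearman_strength_sensitivity(records: pd.DataFrame, value: str = "ratio") -> tuple[float, float]:
    """Spearman rank correlation of promoter strength vs a sensitivity column."""
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    s = records["strength"].to_numpy()
    v = records[value].to_numpy()
    if np.unique(s).size == 1 or np.unique(v).size == 1:
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = stats.spearmanr(s, v)
    return float(rho), float(p)


def gc_bin_ratio(records: pd.DataFrame, bin_edges=DEFAULT_GC_EDGES) -> pd.DataFrame:
    """Up/down-regulated promoter count ratio per spacer GC-content bin.

    Up means corrected_ratio > 1, down < 1; ratios exactly 1 count in
    neither.  A zero denominator yields the Haldane-adjusted value
    (n_up + 0.5)/(n_down + 0.5), flagged in the ``adjusted`` column;
    empty bins report NaN.
    """
    if "corrected_ratio" not in records:
        raise ValueError("records must carry corrected_ratio (run bias_correct first)")
    edges = np.asarray(bin_edges, dtype=float)
    gc = records["gc"].to_numpy()
    if gc.min() < edges[0] or gc.max() > edges[-1]:
        raise ValueError("bin edges do not cover the observed GC range")
    idx = np.clip(np.digitize(gc, edges) - 1, 0, len(edges) - 2)
    cr = records["corrected_ratio"].to_numpy()
    rows = []
    for b in range(len(edges) - 1):
        in_bin = idx == b
        n_up = int(((cr > 1) & in_bin).sum())
        n_down = int(((cr < 1) & in_bin).sum())
        if not in_bin.any():
            ratio, adjusted = np.nan, False
        elif n_down == 0 or n_up == 0:
            ratio, adjusted = (n_up + 0.5) / (n_down + 0.5), True
        else:
            ratio, adjusted = n_up / n_down, False
        rows.append(
            {
                "gc_low": edges[b],
                "gc_high": edges[b + 1],
                "gc_mid": (edges[b] + edges[b + 1]) / 2,
                "n": int(in_bin.sum()),
                "n_up": n_up,
                "n_down": n_down,
                "ratio": ratio,
                "adjusted": adjusted,
            }
        )
    return pd.DataFrame(rows)


def timing_preference(series: PlateSeries, od_threshold: float = 0.3) -> TimingRecord:
    """Share of total expression already performed in exponential phase.

    Linearly interpolates the time at which blank-corrected OD600 crosses
    ``od_threshold`` and returns blank-corrected RFU at that time divided
    by blank-corrected RFU at the last timepoint.  Wells whose OD never
    reaches the threshold are flagged.
    """
    od = series.od600 - series.blank_od
    rfu = series.rfu - series.blank_rfu
    above = np.nonzero(od >= od_threshold)[0]
    if above.size == 0:
        log.warning("timing_preference: %s never reaches OD %.2f", series.clone_id, od_threshold)
        return TimingRecord(series.clone_id, float("nan"), flagged=True)
    i = int(above[0])
    if i == 0:
        t_cross = series.time[0]
    else:
        f = (od_threshold - od[i - 1]) / (od[i] - od[i - 1])
        t_cross = series.time[i - 1] + f * (series.time[i] - series.time[i - 1])
    rfu_cross = float(np.interp(t_cross, series.time, rfu))
    rfu_end = float(rfu[-1])
    if rfu_end <= 0:
        log.warning("timing_preference: %s has non-positive final signal", series.clone_id)
        return TimingRecord(series.clone_id, float("nan"), flagged=True)
    return TimingRecord(series.clone_id, rfu_cross / rfu_end, flagged=False)
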