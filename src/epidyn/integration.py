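"""Joint analyses of promoter marking and gene expression.

The headline analysis is lead/lag concordance: for genes whose promoter
(PLS-covering) peak of the focal mark changes significantly at transition T,
how often does the sign of that marking change agree with the gene's
expression change at the previous transition (T-1, "past"), the same
transition ("current"), and the next one (T+1, "future")? A mark that is
instructive for expression should show higher future than past concordance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

OFFSETS = ("past", "current", "future")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN for constant input. Needs length >= 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("pearson_r needs two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def mann_whitney_u(x: Sequence[float], y: Sequence[float]):
    """(U statistic of x, two-sided p).

    Exact enumeration when n_x * n_y <= 400 and there are no ties; otherwise
    the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# gene-level promoter (PLS) marking


def gene_pls_level(
    pairs: Sequence[tuple],
    peak_levels: pd.DataFrame,
    peak_diffs: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Per-gene promoter peak level (and inherited differential statistics).

    ``pairs`` are (peak_id, gene_id) for promoter-overlapping peaks, with
    peak ids indexing rows of ``peak_levels``. A gene's level per sample is
    the max over its promoter-overlapping peaks. When ``peak_diffs`` is
    given, each gene inherits log2FC/fdr/status from its max-|log2FC|
    covering peak. Genes without any promoter peak are simply absent.
    """
    diff_by_id = {d.peak_id: d for d in peak_diffs} if peak_diffs else {}
    gene_peaks: Dict[str, list] = {}
    for pid, gid in pairs:
        gene_peaks.setdefault(gid, []).append(pid)
    rows = {}
    for gid in sorted(gene_peaks):
        pids = [p for p in gene_peaks[gid] if p in peak_levels.index]
        if not pids:
            continue
        level = peak_levels.loc[pids].max(axis=0)
        row = dict(level)
        row["n_promoter_peaks"] = len(pids)
        if diff_by_id:
            cands = [diff_by_id[p] for p in pids if p in diff_by_id]
            if cands:
                best = max(cands, key=lambda d: (abs(d.log2fc), d.peak_id))
                row.update(
                    log2fc=best.log2fc,
                    p_value=best.p_value,
                    fdr=best.fdr,
                    status=best.status,
                    peak_id=best.peak_id,
                )
        rows[gid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    if not df.empty:
        peak_use: Dict[str, int] = {}
        for pid, _ in pairs:
            peak_use[pid] = peak_use.get(pid, 0) + 1
        df["shared_peak"] = pd.Series(
            {
                gid: any(
                    peak_use.get(p, 0) > 1
                    for p in gene_peaks[gid]
                    if p in peak_levels.index
                )
                for gid in df.index
            }
        )
    df.index.name = "gene_id"
    return df


# ---------------------------------------------------------------------------
# expression stratified by promoter/enhancer peak level


@dataclass
class StratificationReport:
    grouping: str
    bins: list
    summary: pd.DataFrame  # per-bin n, median, q1, q3
    pairwise_p: dict  # (bin_i, bin_j) -> two-sided Mann-Whitney p
    trend_rho: float
    trend_p: float


def stratify_expression_by_level(
    levels: pd.Series,
    expression: pd.Series,
    n_bins: int = 4,
    grouping: str = "PLS",
) -> StratificationReport:
    """Split genes into a no-peak bin plus level-quantile bins.

    ``levels`` holds a per-gene peak level with NaN for genes without a peak;
    ``expression`` a per-gene expression value on the same index. Quantile
    bins are rank-based and near-equal sized (sizes differ by at most 1);
    consecutive bins are compared by two-sided Mann-Whitney U and the trend is
    the Spearman correlation of bin index vs per-bin median.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    levels = levels.reindex(expression.index)
    with_peak = levels.dropna().index
    if len(with_peak) < n_bins:
        raise ValueError("fewer genes with peaks than bins")
    ordered = sorted(with_peak, key=lambda g: (levels[g], g))
    chunks = np.array_split(np.array(ordered, dtype=object), n_bins)
    bin_of: Dict[str, str] = {g: "no_peak" for g in expression.index.difference(with_peak)}
    labels = []
    for b, chunk in enumerate(chunks, start=1):
        lab = f"Q{b}"
        labels.append(lab)
        for g in chunk:
            bin_of[g] = lab
    all_labels = ["no_peak"] + labels
    groups = {
        lab: expression[[g for g in expression.index if bin_of[g] == lab]]
        for lab in all_labels
    }
    summary = pd.DataFrame(
        {
            lab: {
                "n": len(vals),
                "median": float(np.median(vals)) if len(vals) else float("nan"),
                "q1": float(np.percentile(vals, 25)) if len(vals) else float("nan"),
                "q3": float(np.percentile(vals, 75)) if len(vals) else float("nan"),
            }
            for lab, vals in groups.items()
        }
    ).T
    pairwise = {}
    for a, b in zip(all_labels[:-1], all_labels[1:]):
        if len(groups[a]) and len(groups[b]):
            _, p = mann_whitney_u(groups[a].to_numpy(), groups[b].to_numpy())
            pairwise[(a, b)] = p
    medians = [summary.loc[lab, "median"] for lab in labels]
    if len(set(medians)) == 1:
        rho, trend_p = 0.0, 1.0
    else:
        rho, trend_p = stats.spearmanr(np.arange(1, n_bins + 1), medians)
    return StratificationReport(
        grouping, all_labels, summary, pairwise, float(rho), float(trend_p)
    )


# ---------------------------------------------------------------------------
# lead/lag concordance


@dataclass
class ConcordanceReport:
    transition: str
    universe: int
    counts: dict  # offset -> {"concordant": int, "discordant": int, "unchanged": int}
    fractions: dict  # offset -> float or NaN
    mode: str


def lead_lag_concordance(
    gene_marking: pd.DataFrame,
    expression_de: Dict[str, pd.DataFrame],
    transition: str = "",
    mode: str = "sign",
    epsilon: float = 0.0,
) -> ConcordanceReport:
    """Sign concordance of promoter marking changes with expression changes.

    ``gene_marking``: per-gene frame with ``log2fc`` and ``status``
    (hyper/hypo/ns) at the focal transition T. ``expression_de`` maps offsets
    ("past", "current", "future") to per-gene frames with ``log2fc`` and
    ``status`` (up/down/ns); a missing offset (edge transition) is reported
    as NaN. Universe: genes with significant marking (status hyper or hypo).

    mode "sign": concordant when sign(marking log2FC) == sign(expression
    log2FC) and |expression log2FC| > epsilon; unchanged when
    |expression log2FC| <= epsilon. mode "deg_status": concordant when DEG
    status matches marking direction; unchanged when status is ns.
    """
    if mode not in ("sign", "deg_status"):
        raise ValueError("mode must be 'sign' or 'deg_status'")
    uni = gene_marking[gene_marking["status"].isin(["hyper", "hypo"])]
    counts: dict = {}
    fractions: dict = {}
    for off in OFFSETS:
        if off not in expression_de or expression_de[off] is None:
            counts[off] = None
            fractions[off] = float("nan")
            continue
        de = expression_de[off]
        c = d = u = 0
        for gid, row in uni.iterrows():
            msign = 1 if row["log2fc"] > 0 else -1
            if gid not in de.index:
                u += 1  # not tested on the expression side: no change evidence
                continue
            if mode == "sign":
                e = float(de.loc[gid, "log2fc"])
                if abs(e) <= epsilon:
                    u += 1
                elif (e > 0) == (msign > 0):
                    c += 1
                else:
                    d += 1
            else:
                st = de.loc[gid, "status"]
                if st == "ns":
                    u += 1
                elif (st == "up") == (msign > 0):
                    c += 1
                else:
                    d += 1
        counts[off] = {"concordant": c, "discordant": d, "unchanged": u}
        fractions[off] = c / len(uni) if len(uni) else float("nan")
    return ConcordanceReport(transition, len(uni), counts, fractions, mode)


# ---------------------------------------------------------------------------
# pairwise mark correlation and DEG overlap


@dataclass
class PairwiseMarkReport:
    mark_a: str
    mark_b: str
    n_genes: int
    pearson: float
    quadrants: dict  # direction -> {"UR": f, "UL": f, "LL": f, "LR": f}
    zero_counts: dict  # direction -> genes with an exact-zero change


def pairwise_mark_change_correlation(
    lfc_a: pd.Series,
    lfc_b: pd.Series,
    up_degs: Sequence[str],
    down_degs: Sequence[str],
    mark_a: str = "A",
    mark_b: str = "B",
) -> PairwiseMarkReport:
    """Pearson r of per-gene PLS log2FCs of two marks over the DEGs, plus
    quadrant fractions per DEG direction (zero changes count as positive)."""
    degs = [g for g in itertools.chain(up_degs, down_degs)]
    common = [g for g in degs if g in lfc_a.index and g in lfc_b.index
              and np.isfinite(lfc_a[g]) and np.isfinite(lfc_b[g])]
    if len(common) < 3:
        raise ValueError("need >= 3 genes with both marks quantified")
    a = lfc_a[common].to_numpy(dtype=float)
    b = lfc_b[common].to_numpy(dtype=float)
    r = pearson_r(a, b)
    quadrants = {}
    zeros = {}
    for direction, members in (("up", up_degs), ("down", down_degs)):
        sel = [g for g in members if g in common]
        if not sel:
            quadrants[direction] = {q: float("nan") for q in ("UR", "UL", "LL", "LR")}
            zeros[direction] = 0
            continue
        av = lfc_a[sel].to_numpy(dtype=float)
        bv = lfc_b[sel].to_numpy(dtype=float)
        pos_a, pos_b = av >= 0, bv >= 0  # ties to the positive side
        n = len(sel)
        quadrants[direction] = {
            "UR": float(np.sum(pos_a & pos_b)) / n,
            "UL": float(np.sum(~pos_a & pos_b)) / n,
            "LL": float(np.sum(~pos_a & ~pos_b)) / n,
            "LR": float(np.sum(pos_a & ~pos_b)) / n,
        }
        zeros[direction] = int(np.sum((av == 0) | (bv == 0)))
    return PairwiseMarkReport(mark_a, mark_b, len(common), r, quadrants, zeros)


def deg_marking_overlap(
    deg_sets: Dict[str, set],
    gene_marking: pd.DataFrame,
) -> pd.DataFrame:
    """Contingency of DEG direction vs promoter-marking direction.

    ``deg_sets``: {"up": set, "down": set}. ``gene_marking``: per-gene frame
    with ``log2fc`` and ``status`` (hyper/hypo/ns). For each direction,
    reports DEGs with any matching-direction marking change, with significant
    matching change, and the reverse conditioning (significantly marked genes
    that are DEGs).
    """
    rows = []
    for direction, wanted in (("up", "hyper"), ("down", "hypo")):
        degs = deg_sets.get(direction, set())
        marked = gene_marking.index.intersection(degs)
        sub = gene_marking.loc[marked]
        sign_ok = sub["log2fc"] > 0 if direction == "up" else sub["log2fc"] < 0
        any_match = int(sign_ok.sum())
        sig_match = int((sign_ok & (sub["status"] == wanted)).sum())
        sig_marked = gene_marking[gene_marking["status"] == wanted]
        rows.append(
            {
                "direction": direction,
                "n_degs": len(degs),
                "degs_with_matching_change": any_match,
                "degs_with_significant_matching_change": sig_match,
                "n_significantly_marked": len(sig_marked),
                "marked_genes_that_are_degs": int(
                    sig_marked.index.isin(list(degs)).sum()
                ),
            }
        )
    return pd.DataFrame(rows)
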