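"""Master-peak construction, fragment quantification and differential marking.

The master (union) peak list of one mark merges all replicate/timepoint peak
sets by single-linkage (>= 1 shared bp, transitive), so every condition is
quantified against one shared reference and log2 fold-changes are comparable.
Fragments are the counting unit (paired-end CUT&Tag); a fragment increments a
master peak's count when it overlaps it by >= 1 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, NormalizationFactors, PeakRecord
from .expression import differential_test, log_cpm, tmm_factors
from .intervals import IntervalIndex, count_cover, merge_single_linkage


@dataclass
class MasterPeak:
    interval: GenomicInterval
    mark: str
    source_peaks: list = field(default_factory=list)  # (sample_id, PeakRecord)

    @property
    def peak_id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}"


@dataclass
class PeakDifferential:
    peak_id: str
    log2fc: float
    p_value: float
    fdr: float
    status: str  # hyper / hypo / ns


def build_master_peaks(peak_sets: Sequence[Sequence[PeakRecord]], mark: str) -> list:
    """Single-linkage union of per-sample peak sets into master peaks.

    Every input peak maps to exactly one master peak; the output is sorted by
    (chrom, start) and invariant to the order of the input peak sets.
    """
    flat = [p for ps in peak_sets for p in ps]
    for p in flat:
        if p.mark != mark:
            raise ValueError(f"peak with mark {p.mark!r} in a {mark!r} master build")
    if not flat:
        return []
    triples = [(p.interval.chrom, p.interval.start, p.interval.end) for p in flat]
    merged = merge_single_linkage(triples)
    out = []
    for chrom, start, end, members in merged:
        mp = MasterPeak(GenomicInterval(chrom, start, end), mark)
        for i in sorted(
            members,
            key=lambda i: (triples[i], flat[i].sample_id),
        ):
            mp.source_peaks.append((flat[i].sample_id, flat[i]))
        out.append(mp)
    out.sort(key=lambda m: (m.interval.chrom, m.interval.start, m.interval.end))
    return out


def count_fragments(
    master_peaks: Sequence[MasterPeak], fragments: Mapping[str, object]
) -> pd.DataFrame:
    """Fragment counts over master peaks, one column per sample.

    ``fragments`` maps sample id to either a list of FragmentRecord or a
    DataFrame with chrom/start/end columns. Master peaks must be pairwise
    non-overlapping; a fragment is counted at most once per peak.
    """
    targets = [
        (m.interval.chrom, m.interval.start, m.interval.end) for m in master_peaks
    ]
    for i in range(1, len(master_peaks)):
        a, b = master_peaks[i - 1].interval, master_peaks[i].interval
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError("master peaks must be non-overlapping and sorted")
    cols = {}
    for sample_id in sorted(fragments):
        frags = fragments[sample_id]
        if isinstance(frags, pd.DataFrame):
            grouped = {
                chrom: (g["start"].to_numpy(np.int64), g["end"].to_numpy(np.int64))
                for chrom, g in frags.groupby("chrom", sort=True)
            }
        else:
            tmp: dict = {}
            for f in frags:
                iv = f.interval
                tmp.setdefault(iv.chrom, ([], []))
                tmp[iv.chrom][0].append(iv.start)
                tmp[iv.chrom][1].append(iv.end)
            grouped = {
                c: (np.array(s, dtype=np.int64), np.array(e, dtype=np.int64))
                for c, (s, e) in tmp.items()
            }
        cols[sample_id] = count_cover(targets, grouped)
    ids = [m.peak_id for m in master_peaks]
    return pd.DataFrame(cols, index=ids)


def differential_peaks(
    peak_counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    lfc_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
    factors: Optional[NormalizationFactors] = None,
    dispersion: Optional[float] = None,
    prior_n: float = 10.0,
):
    """Differential marking between conditions (later vs earlier).

    Reuses the NB exact test on the fragment-count matrix with TMM factors
    computed on the peak counts themselves; hyper when log2FC > threshold and
    FDR below cutoff, hypo for the mirror image, else ns.
    """
    results, filtered = differential_test(
        peak_counts,
        group_a,
        group_b,
        factors=factors,
        dispersion=dispersion,
        prior_n=prior_n,
        lfc_threshold=lfc_threshold,
        fdr_threshold=fdr_threshold,
    )
    rename = {"up": "hyper", "down": "hypo", "ns": "ns"}
    return [
        PeakDifferential(r.feature_id, r.log2fc, r.p_value, r.fdr, rename[r.status])
        for r in results
    ], filtered


def peak_level_logcpm(
    peak_counts: pd.DataFrame,
    factors: Optional[NormalizationFactors] = None,
    prior: float = 2.0,
) -> pd.DataFrame:
    """Peak-level log2-CPM with the same formula used for genes."""
    if factors is None:
        factors = tmm_factors(peak_counts)
    return log_cpm(peak_counts, factors, prior=prior)


def peak_width_stats(peaks: Sequence[PeakRecord]) -> dict:
    """min/q1/median/q3/max of peak widths (end - start)."""
    if not peaks:
        raise ValueError("peak_width_stats needs a non-empty peak list")
    widths = np.array(
        [p.interval.width if hasattr(p, "interval") else (p.end - p.start) for p in peaks],
        dtype=float,
    )
    q = np.percentile(widths, [0, 25, 50, 75, 100])
    return {"min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4]}


def peak_set_detection_overlap(set_a: Sequence, set_b: Sequence) -> dict:
    """Fraction of set-A peaks not detected (>= 1 bp overlap) in set B."""
    def _iv(p):
        return p.interval if hasattr(p, "interval") else p

    if not set_a:
        return {"n": 0, "undetected": 0, "fraction_undetected": float("nan")}
    index = IntervalIndex((_iv(p).chrom, _iv(p).start, _iv(p).end) for p in set_b)
    undetected = sum(
        1
        for p in set_a
        if not index.query(_iv(p).chrom, _iv(p).start, _iv(p).end)
    )
    return {
        "n": len(set_a),
        "undetected": undetected,
        "fraction_undetected": undetected / len(set_a),
    }
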