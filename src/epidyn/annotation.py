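"""Peak annotation: promoters, TSS distances, cCRE classes, enhancer links.

cCRE classes follow the ENCODE-style grouping (PLS, pELS, dELS, CTCF-only,
DNase-H3K4me3). A peak overlapping several classes takes the highest-priority
one: PLS > dELS > pELS > other cCREs — proximal enhancers sitting next to a
promoter are absorbed by the promoter class. Distal enhancers (dELS) are
linked to their closest non-overlapping gene as an in-silico stand-in for
experimentally determined enhancer-gene contacts.

Distance conventions (documented choices, exercised by oracle tests):
* TSS distance: 0 when the peak covers the TSS base, else bases from the TSS
  to the nearest covered base; sign positive when the peak lies downstream of
  the TSS in the gene's orientation.
* gene gap (closest-gene linking): bases strictly between peak and gene body,
  0 for half-open adjacency; genes whose body overlaps the peak are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import CCRERecord, GeneModel, GenomicInterval
from .intervals import IntervalIndex, interval_gap, point_interval_distance

GENOMIC_FEATURES = ("promoter", "exon", "intron", "distal_intergenic")
_CLASS_PRIORITY = {"PLS": 0, "dELS": 1, "pELS": 2, "CTCF_only": 3, "DNase_H3K4me3": 3}


@dataclass
class AnnotatedPeak:
    peak_id: str
    interval: GenomicInterval
    nearest_gene_id: Optional[str]
    distance_to_tss: Optional[int]
    genomic_feature: str
    ccre_class: str  # PLS / dELS / pELS / other_cCRE / none
    promoter_gene_ids: list = field(default_factory=list)
    linked_gene_id: Optional[str] = None  # dELS peaks only
    link_distance: Optional[int] = None


def promoter_window(gene: GeneModel, flank: int = 2000) -> GenomicInterval:
    """[tss - flank, tss + flank), clipped at 0; strand-independent."""
    if flank <= 0:
        raise ValueError("flank must be > 0")
    return GenomicInterval(
        gene.interval.chrom, max(0, gene.tss - flank), gene.tss + flank
    )


def distance_to_tss(peak: GenomicInterval, genes: Sequence[GeneModel]):
    """(nearest gene id, signed bp distance); 0 when the peak covers the TSS.

    Sign is + when the peak lies downstream of the TSS in the gene's
    orientation, - when upstream. Nearest gene by magnitude, ties by gene id.
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    best = None
    for g in genes:
        if g.interval.chrom != peak.chrom:
            continue
        mag = point_interval_distance(g.tss, peak.start, peak.end)
        key = (mag, g.gene_id)
        if best is None or key < best[0]:
            if mag == 0:
                signed = 0
            else:
                peak_right_of_tss = peak.start > g.tss
                downstream = peak_right_of_tss == (g.strand == "+")
                signed = mag if downstream else -mag
            best = (key, g.gene_id, signed)
    if best is None:
        return None, None
    return best[1], best[2]


def annotate_genomic_feature(
    peak: GenomicInterval,
    genes: Sequence[GeneModel],
    exons: Optional[Sequence[GenomicInterval]] = None,
    flank: int = 2000,
) -> str:
    """promoter > exon/intron (gene body) > distal_intergenic."""
    for g in genes:
        if g.interval.chrom == peak.chrom and promoter_window(g, flank).overlaps(peak):
            return "promoter"
    in_body = any(g.interval.overlaps(peak) for g in genes)
    if in_body:
        if exons is not None and any(e.overlaps(peak) for e in exons):
            return "exon"
        return "intron"
    return "distal_intergenic"


def assign_ccre(peak: GenomicInterval, ccres: Sequence[CCRERecord]) -> str:
    """Highest-priority cCRE class overlapping the peak (>= 1 bp), else none."""
    best = None
    for c in ccres:
        if c.interval.overlaps(peak):
            pr = _CLASS_PRIORITY[c.ccre_class]
            if best is None or pr < best:
                best = pr
    if best is None:
        return "none"
    return ["PLS", "dELS", "pELS", "other_cCRE"][best]


def promoter_peak_pairs(
    peaks: Sequence, genes: Sequence[GeneModel], flank: int = 2000
) -> list:
    """All (peak index, gene_id) pairs whose promoter windows the peaks overlap.

    A peak may pair with several genes (shared promoter peak) and a gene with
    several peaks.
    """
    windows = [promoter_window(g, flank) for g in genes]
    index = IntervalIndex((w.chrom, w.start, w.end) for w in windows)
    pairs = []
    for i, p in enumerate(peaks):
        iv = p.interval if hasattr(p, "interval") else p
        for j in index.query(iv.chrom, iv.start, iv.end):
            pairs.append((i, genes[j].gene_id))
    return pairs


def link_dels_to_closest_gene(peak: GenomicInterval, genes: Sequence[GeneModel]):
    """Closest gene whose body does not overlap the peak.

    Returns (gene_id, gap bp) or (None, None) when no eligible gene shares the
    chromosome. Ties broken by smaller TSS distance, then gene id.
    """
    best = None
    for g in genes:
        if g.interval.chrom != peak.chrom:
            continue
        gap = interval_gap(peak.start, peak.end, g.interval.start, g.interval.end)
        if gap < 0:  # body overlaps the peak: ineligible
            continue
        tss_gap = point_interval_distance(g.tss, peak.start, peak.end)
        key = (gap, tss_gap, g.gene_id)
        if best is None or key < best:
            best = key
    if best is None:
        return None, None
    return best[2], best[0]


def annotate_peaks(
    peaks: Sequence,
    genes: Sequence[GeneModel],
    ccres: Sequence[CCRERecord],
    exons: Optional[Sequence[GenomicInterval]] = None,
    flank: int = 2000,
) -> list:
    """Full annotation of a peak list; one AnnotatedPeak per input peak."""
    pair_list = promoter_peak_pairs(peaks, genes, flank=flank)
    by_peak: dict = {}
    for i, gid in pair_list:
        by_peak.setdefault(i, []).append(gid)
    out = []
    for i, p in enumerate(peaks):
        iv = p.interval if hasattr(p, "interval") else p
        peak_id = getattr(p, "peak_id", f"{iv.chrom}:{iv.start}-{iv.end}")
        gid, dist = distance_to_tss(iv, genes) if genes else (None, None)
        cls = assign_ccre(iv, ccres)
        linked, link_d = (None, None)
        if cls == "dELS":
            linked, link_d = link_dels_to_closest_gene(iv, genes)
        out.append(
            AnnotatedPeak(
                peak_id=peak_id,
                interval=iv,
                nearest_gene_id=gid,
                distance_to_tss=dist,
                genomic_feature=annotate_genomic_feature(iv, genes, exons, flank),
                ccre_class=cls,
                promoter_gene_ids=sorted(by_peak.get(i, [])),
                linked_gene_id=linked,
                link_distance=link_d,
            )
        )
    return out


#: TSS-distance bins used in summaries: overlap, then log-spaced shells
DISTANCE_BINS = ((0, "overlap"), (1000, "0-1kb"), (10000, "1-10kb"),
                 (100000, "10-100kb"), (np.inf, ">100kb"))


def distance_bin(distance: int) -> str:
    mag = abs(distance)
    if mag == 0:
        return "overlap"
    for bound, label in DISTANCE_BINS[1:]:
        if mag <= bound:
            return label
    return ">100kb"


def annotation_frame(annotated: Sequence[AnnotatedPeak]) -> pd.DataFrame:
    rows = []
    for a in annotated:
        rows.append(
            {
                "peak_id": a.peak_id,
                "chrom": a.interval.chrom,
                "start": a.interval.start,
                "end": a.interval.end,
                "nearest_gene": a.nearest_gene_id,
                "distance_to_tss": a.distance_to_tss,
                "distance_bin": distance_bin(a.distance_to_tss)
                if a.distance_to_tss is not None
                else "NA",
                "genomic_feature": a.genomic_feature,
                "ccre_class": a.ccre_class,
                "promoter_genes": ",".join(a.promoter_gene_ids),
                "linked_gene": a.linked_gene_id if a.linked_gene_id else "",
                "link_distance": a.link_distance if a.link_distance is not None else "",
            }
        )
    return pd.DataFrame(rows)


def top_dels_genes(
    annotated: Sequence[AnnotatedPeak],
    levels: pd.Series,
    n: int = 2000,
) -> list:
    """Distinct genes linked to the strongest dELS peaks.

    Ranks dELS-class peaks by mean level (descending; ties by coordinate) and
    collects distinct linked genes until ``n`` or exhaustion.
    """
    ranked = sorted(
        (
            a
            for a in annotated
            if a.ccre_class == "dELS" and a.linked_gene_id and a.peak_id in levels.index
        ),
        key=lambda a: (
            -float(levels[a.peak_id]),
            a.interval.chrom,
            a.interval.start,
            a.interval.end,
        ),
    )
    out: list = []
    seen: set = set()
    for a in ranked:
        if a.linked_gene_id not in seen:
            seen.add(a.linked_gene_id)
            out.append(a.linked_gene_id)
        if len(out) >= n:
            break
    return out
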