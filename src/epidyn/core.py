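"""Domain types shared across the pipeline.

All coordinates are 0-based half-open (BED convention). Adjacency
(``end == start``) is never an overlap, anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

CCRE_CLASSES = ("PLS", "pELS", "dELS", "CTCF_only", "DNase_H3K4me3")

#: priority used when a peak overlaps several cCRE classes
CCRE_PRIORITY = ("PLS", "dELS", "pELS", "other_cCRE")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>= 1 shared bp; half-open adjacency is not an overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class PeakRecord:
    """One called peak (SEACR-style) with its signal statistics."""

    interval: GenomicInterval
    total_signal: float
    max_signal: float
    sample_id: str
    mark: str

    def __post_init__(self) -> None:
        if self.total_signal < 0 or self.max_signal < 0:
            raise ValueError("peak signals must be non-negative")


@dataclass
class FragmentRecord:
    """A sequenced fragment (paired-end insert) as a genomic interval."""

    interval: GenomicInterval
    sample_id: str


@dataclass
class GeneModel:
    """Gene body with strand; the TSS anchors promoters and distance metrics."""

    gene_id: str
    interval: GenomicInterval
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        expected = self.interval.start if self.strand == "+" else self.interval.end - 1
        if self.tss != expected:
            raise ValueError(
                f"gene {self.gene_id}: tss {self.tss} inconsistent with "
                f"{self.strand} strand body [{self.interval.start}, {self.interval.end})"
            )


@dataclass
class CCRERecord:
    """ENCODE-style candidate cis-regulatory element with class label."""

    interval: GenomicInterval
    ccre_class: str
    linked_gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ccre_class not in CCRE_CLASSES:
            raise ValueError(
                f"ccre_class must be one of {CCRE_CLASSES}, got {self.ccre_class!r}"
            )


@dataclass
class DifferentialResult:
    """Per-feature differential-test outcome (genes and peaks share this)."""

    feature_id: str
    log2fc: float
    p_value: float
    fdr: float
    status: str  # up / down / ns  (peaks rename to hyper / hypo / ns)


@dataclass
class NormalizationFactors:
    """Library sizes and TMM scaling factors (geometric mean 1)."""

    sample_ids: list
    lib_size: "np.ndarray"  # type: ignore[name-defined]
    factor: "np.ndarray"  # type: ignore[name-defined]

    @property
    def effective_lib_size(self):
        return self.lib_size * self.factor
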