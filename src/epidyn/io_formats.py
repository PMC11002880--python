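"""Readers and writers for the plain-text formats the pipeline consumes.

Supported dialects: BED3+ interval files, 6-column SEACR stringent-mode peak
files, BED6 gene models (name = gene id, strand column drives the TSS), cCRE
BED with a class-label column, TSV count matrices with ``tp<d>_rep<r>`` sample
names, and GMT gene-set collections. All coordinates are parsed as 0-based
half-open and validated on the way in.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core import (
    CCRERecord,
    FragmentRecord,
    GeneModel,
    GenomicInterval,
    PeakRecord,
)
from .intervals import IntervalIndex


class ParseError(ValueError):
    """A file did not conform to its declared dialect."""


@dataclass
class BedRecord:
    interval: GenomicInterval
    fields: tuple  # extra columns beyond chrom/start/end, as strings


_SAMPLE_RE = re.compile(r"^tp(\d+)_rep(\d+)$")


def _lines(path) -> Iterable[tuple]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _parse_interval(parts, path, lineno) -> GenomicInterval:
    try:
        start, end = int(parts[1]), int(parts[2])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
    try:
        return GenomicInterval(parts[0], start, end)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from exc


def read_bed(path, min_columns: int = 3) -> list:
    """Read a BED-like file into ``BedRecord``s, preserving file order."""
    out = []
    for lineno, line in _lines(path):
        parts = line.split("\t")
        if len(parts) < min_columns:
            raise ParseError(
                f"{path}:{lineno}: expected >= {min_columns} tab-separated fields, "
                f"got {len(parts)}"
            )
        out.append(BedRecord(_parse_interval(parts, path, lineno), tuple(parts[3:])))
    return out


def write_bed(path, records: Iterable) -> None:
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval if hasattr(rec, "interval") else rec
            extra = getattr(rec, "fields", ())
            cols = [iv.chrom, str(iv.start), str(iv.end), *extra]
            fh.write("\t".join(cols) + "\n")


def read_peak_file(path, sample_id: str, mark: str) -> list:
    """Read a 6-column SEACR stringent-mode peak file.

    Columns: chrom, start, end, total signal, max signal, max-signal region
    (the region column is tolerated but ignored). A peak whose printed total
    is below its max triggers a warning but is kept as printed.
    """
    out = []
    for lineno, line in _lines(path):
        parts = line.split("\t")
        if len(parts) < 6:
            raise ParseError(
                f"{path}:{lineno}: expected 6-column SEACR stringent-mode dialect "
                f"(chrom, start, end, total, max, max region), got {len(parts)} columns"
            )
        iv = _parse_interval(parts, path, lineno)
        try:
            total, mx = float(parts[3]), float(parts[4])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric signal value") from exc
        if total < mx:
            warnings.warn(
                f"{path}:{lineno}: total signal {total} < max signal {mx}; "
                "record kept as printed"
            )
        out.append(PeakRecord(iv, total, mx, sample_id, mark))
    return out


def write_peak_file(path, peaks: Iterable) -> None:
    """Write peaks in the 6-column SEACR stringent-mode dialect."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            region = f"{iv.chrom}:{iv.start}-{iv.end}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.total_signal:.6g}"
                f"\t{p.max_signal:.6g}\t{region}\n"
            )


def filter_blacklist(peaks: list, blacklist: list) -> list:
    """Drop peaks overlapping (>= 1 bp) any blacklist interval; order kept."""
    if not blacklist:
        return list(peaks)
    index = IntervalIndex(
        (iv.chrom, iv.start, iv.end)
        for iv in (b.interval if hasattr(b, "interval") else b for b in blacklist)
    )
    out = []
    for p in peaks:
        iv = p.interval if hasattr(p, "interval") else p
        if not index.query(iv.chrom, iv.start, iv.end):
            out.append(p)
    return out


def parse_sample_name(name: str) -> tuple:
    """``tp<d>_rep<r>`` -> (timepoint, replicate)."""
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise ParseError(
            f"sample name {name!r} does not follow the tp<d>_rep<r> convention"
        )
    return int(m.group(1)), int(m.group(2))


def read_count_matrix(path, metadata: Optional[pd.DataFrame] = None):
    """Read a feature-by-sample TSV of counts.

    Returns (counts DataFrame with int64 values, sample metadata DataFrame
    with ``timepoint`` and ``replicate`` columns). Metadata is parsed from the
    ``tp<d>_rep<r>`` sample-name convention unless an explicit table indexed
    by sample id is supplied.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate feature ids {dups}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ParseError(f"{path}: non-numeric entries in count matrix")
    if (values < 0).any():
        raise ParseError(f"{path}: negative counts present")
    if not np.allclose(values, np.round(values)):
        raise ParseError(f"{path}: non-integer counts present")
    counts = df.astype(np.int64)
    if metadata is not None:
        meta = metadata.loc[counts.columns]
    else:
        parsed = [parse_sample_name(s) for s in counts.columns]
        meta = pd.DataFrame(
            parsed, index=counts.columns, columns=["timepoint", "replicate"]
        )
    return counts, meta


def write_count_matrix(path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_gmt(path) -> dict:
    """Read a GMT file into an ordered {set name: set of members} mapping."""
    sets: dict = {}
    for lineno, line in _lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(
                f"{path}:{lineno}: GMT lines need >= 3 fields (name, description, members)"
            )
        name = parts[0]
        if name in sets:
            raise ParseError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        sets[name] = set(m for m in parts[2:] if m)
    return sets


def read_gene_bed(path) -> list:
    """BED6 gene models: name column = gene id, strand column derives the TSS."""
    genes = []
    seen = set()
    for lineno, line in _lines(path):
        parts = line.split("\t")
        if len(parts) < 6:
            raise ParseError(f"{path}:{lineno}: gene models need BED6 (6 columns)")
        iv = _parse_interval(parts, path, lineno)
        gene_id, strand = parts[3], parts[5]
        if gene_id in seen:
            raise ParseError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        tss = iv.start if strand == "+" else iv.end - 1
        try:
            genes.append(GeneModel(gene_id, iv, strand, tss))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_bed(path, genes: Iterable) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_ccre_bed(path) -> list:
    """cCRE BED: columns chrom, start, end, class label[, linked gene id]."""
    out = []
    for lineno, line in _lines(path):
        parts = line.split("\t")
        if len(parts) < 4:
            raise ParseError(f"{path}:{lineno}: cCRE records need >= 4 columns")
        iv = _parse_interval(parts, path, lineno)
        linked = parts[4] if len(parts) > 4 and parts[4] not in (".", "") else None
        try:
            out.append(CCRERecord(iv, parts[3], linked))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_ccre_bed(path, ccres: Iterable) -> None:
    with open(path, "w") as fh:
        for c in ccres:
            iv = c.interval
            linked = c.linked_gene_id if c.linked_gene_id else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.ccre_class}\t{linked}\n")


def read_fragments(path, sample_id: str) -> list:
    """BED3 fragment file -> list of FragmentRecord (file order preserved)."""
    return [
        FragmentRecord(rec.interval, sample_id) for rec in read_bed(path, min_columns=3)
    ]


def read_fragments_frame(path) -> pd.DataFrame:
    """Fast path: BED3 fragment file -> DataFrame (chrom, start, end)."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64}, comment="#",
    )
    if (df["end"] <= df["start"]).any():
        bad = int((df["end"] <= df["start"]).sum())
        raise ParseError(f"{path}: {bad} fragments with end <= start")
    return df


def write_fragments(path, frame: pd.DataFrame) -> None:
    frame[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)
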