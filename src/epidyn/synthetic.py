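"""Self-contained synthetic study with planted temporal structure.

Emulates a 4-timepoint (1/2/4/7 dpi) x 2-replicate design: a toy genome with
regularly spaced gene loci, ENCODE-style cCREs (one PLS per TSS, a pELS and a
dELS per locus), negative-binomial RNA-seq counts following planted archetype
time profiles, and per-mark CUT&Tag peak + fragment sets whose promoter peak
heights are coupled to expression changes with configurable lead/lag
strengths. Everything is deterministic under a fixed seed and every planted
effect is recorded in a machine-readable truth table.

Locus layout (per gene, within a window of ``spacing`` bp):

    [gene body 2-5 kb][pELS at TSS+600] ... [dELS >= 10 kb from all TSSs]
    ... [background-peak strip] [optional CTCF-only element]

The lead/lag coupling operates on planted log2 fold-changes: a gene with a
planted expression change e at transition U gets, independently with
probabilities lambda_future / lambda_current / lambda_past, a planted
promoter-marking change of e at transitions U-1 / U / U+1 (the mark leading,
concurrent, or lagging expression). The repressive mark (H3K27me3) receives
sign-flipped concurrent coupling. Archetype profiles are closed under time
reversal so that equal lead and lag strengths imply no lead/lag asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import CCRERecord, GeneModel, GenomicInterval, PeakRecord

DEFAULT_WIDTH_RANGES = {
    "H3K18la": (1000, 2000),
    "H3K4me3": (1500, 2500),
    "H3K27ac": (1000, 3500),
    "H3K27me3": (2000, 6000),
}

_MIN_SPACING = 32_000  # gene body + 10 kb dELS clearance on both sides + strips
_PLS_HALF = 175
_GENE_LEN = (2000, 5000)
_DELS_WIDTH = 300
_MAX_PEAK_HALF = 3000  # half of the widest mark range (H3K27me3)


@dataclass
class SimulationConfig:
    n_chroms: int = 2
    chrom_length: int = 32_000_000
    n_genes: int = 2000
    timepoints: Tuple[int, ...] = (1, 2, 4, 7)
    n_replicates: int = 2
    n_clusters: int = 9
    deg_fraction: float = 0.15
    lfc_magnitude: float = 2.0
    nb_dispersion: float = 0.05
    lib_size_range: Tuple[int, int] = (1_500_000, 2_500_000)
    frag_lib_size_range: Tuple[int, int] = (90_000, 110_000)
    peak_gene_coupling: float = 1.0
    peak_level_noise_sd: float = 0.5
    lambda_future: float = 0.8
    lambda_current: float = 0.6
    lambda_past: float = 0.1
    seed: int = 0
    marks: Tuple[str, ...] = ("H3K18la", "H3K4me3", "H3K27ac", "H3K27me3")
    focal_mark: str = "H3K18la"
    mark_width_ranges: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_WIDTH_RANGES)
    )
    no_peak_fraction: float = 0.10
    dels_peak_fraction: float = 0.60
    background_peak_fraction: float = 0.30  # background peaks per gene locus
    bg_fragment_fraction: float = 0.20  # scattered (off-peak) fragment mass
    presence_prob: float = 0.97  # per-sample peak detection probability
    boundary_jitter: float = 0.10  # replicate edge jitter, fraction of width
    n_shared_promoter_pairs: int = 0

    def __post_init__(self) -> None:
        for name in (
            "deg_fraction",
            "lambda_future",
            "lambda_current",
            "lambda_past",
            "no_peak_fraction",
            "dels_peak_fraction",
            "bg_fragment_fraction",
            "presence_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be > 0")
        if list(self.timepoints) != sorted(set(self.timepoints)):
            raise ValueError("timepoints must be strictly ordered")
        if len(self.timepoints) < 2:
            raise ValueError("need at least 2 timepoints")
        if self.focal_mark not in self.marks:
            raise ValueError("focal_mark must be one of marks")
        if self.spacing < _MIN_SPACING:
            raise ValueError(
                f"chrom_length {self.chrom_length} too small to place "
                f"{self.n_genes} genes on {self.n_chroms} chromosome(s): locus "
                f"spacing {self.spacing} < {_MIN_SPACING} bp"
            )

    @property
    def genes_per_chrom(self) -> int:
        return -(-self.n_genes // self.n_chroms)  # ceil

    @property
    def spacing(self) -> int:
        return self.chrom_length // self.genes_per_chrom

    @property
    def transitions(self):
        return [
            (self.timepoints[i], self.timepoints[i + 1])
            for i in range(len(self.timepoints) - 1)
        ]

    @property
    def sample_ids(self):
        return [
            f"tp{t}_rep{r}"
            for t in self.timepoints
            for r in range(1, self.n_replicates + 1)
        ]


@dataclass
class TruthTable:
    """Machine-readable record of every planted effect."""

    genes: pd.DataFrame  # cluster, baseline, per-transition expression log2FC
    peaks: pd.DataFrame = field(default_factory=pd.DataFrame)  # planted marking
    coupling: pd.DataFrame = field(default_factory=pd.DataFrame)  # lead/lag flags


def archetype_patterns(n_transitions: int, n_clusters: int):
    """Per-transition sign patterns for the expression archetypes.

    The first two are monotone up and monotone down. Further patterns are
    added in whole orbits under time reversal and sign negation: reversal
    closure makes equal lead/lag coupling imply no lead/lag asymmetry, and
    negation closure balances up- and down-mass per transition so that
    normalization does not see a systematic composition shift. When
    ``n_clusters`` cuts into an orbit the remainder is filled in canonical
    order (a documented, minor imbalance).
    """
    from itertools import product

    up = (1,) * n_transitions
    down = (-1,) * n_transitions
    patterns = [up, down]
    seen = {up, down}
    for cand in product((1, -1, 0), repeat=n_transitions):
        if len(patterns) >= n_clusters:
            break
        if not any(cand) or cand in seen:
            continue
        orbit = []
        for p in (
            cand,
            cand[::-1],
            tuple(-v for v in cand),
            tuple(-v for v in cand[::-1]),
        ):
            if p not in seen and p not in orbit:
                orbit.append(p)
        for p in orbit:
            if len(patterns) >= n_clusters:
                break
            patterns.append(p)
            seen.add(p)
    return patterns[:n_clusters]


# ---------------------------------------------------------------------------
# genome


def simulate_genome_and_genes(config: SimulationConfig):
    """Toy genome: (genes, cCREs) with one PLS per TSS, pELS and dELS per locus."""
    rng = np.random.default_rng([1, config.seed])
    spacing = config.spacing
    genes, ccres = [], []
    gid = 0
    shared_left = config.n_shared_promoter_pairs
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        for i in range(config.genes_per_chrom):
            if gid >= config.n_genes:
                break
            origin = i * spacing + 1000
            length = int(rng.integers(_GENE_LEN[0], _GENE_LEN[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            iv = GenomicInterval(chrom, origin, origin + length)
            tss = iv.start if strand == "+" else iv.end - 1
            name = f"g{gid:05d}"
            genes.append(GeneModel(name, iv, strand, tss))
            ccres.append(
                CCRERecord(
                    GenomicInterval(chrom, max(0, tss - _PLS_HALF), tss + _PLS_HALF),
                    "PLS",
                    name,
                )
            )
            ccres.append(
                CCRERecord(GenomicInterval(chrom, tss + 600, tss + 950), "pELS")
            )
            gid += 1
            add_twin = shared_left > 0 and gid < config.n_genes
            max_tss = tss
            if add_twin:
                # twin gene whose promoter window overlaps the previous one's
                twin_tss = tss + 1200
                tiv = GenomicInterval(chrom, twin_tss, twin_tss + 1500)
                tname = f"g{gid:05d}"
                genes.append(GeneModel(tname, tiv, "+", twin_tss))
                ccres.append(
                    CCRERecord(
                        GenomicInterval(
                            chrom, twin_tss - _PLS_HALF, twin_tss + _PLS_HALF
                        ),
                        "PLS",
                        tname,
                    )
                )
                shared_left -= 1
                gid += 1
                max_tss = twin_tss
            d_lo = max_tss + 10_000
            d_hi = origin + spacing - 16_500
            if d_hi < d_lo:
                raise ValueError(
                    "locus spacing too small for a dELS >= 10 kb from every TSS"
                )
            d0 = int(rng.integers(d_lo, d_hi + 1))
            ccres.append(
                CCRERecord(GenomicInterval(chrom, d0, d0 + _DELS_WIDTH), "dELS")
            )
            if rng.random() < 0.2:
                s = origin + spacing - 5_000
                ccres.append(
                    CCRERecord(GenomicInterval(chrom, s, s + 300), "CTCF_only")
                )
    return genes, ccres


# ---------------------------------------------------------------------------
# expression


def simulate_expression(config: SimulationConfig, genes: Sequence[GeneModel]):
    """(count matrix over timepoints x replicates, TruthTable)."""
    rng = np.random.default_rng([2, config.seed])
    n = len(genes)
    gene_ids = [g.gene_id for g in genes]
    n_trans = len(config.timepoints) - 1
    patterns = archetype_patterns(n_trans, config.n_clusters)
    # deg_fraction is the per-transition fraction of genes with a planted
    # change; archetypes touch several transitions, so the dynamic-gene count
    # is scaled by the mean number of nonzero transitions per pattern
    avg_nonzero = np.mean([sum(1 for v in p if v) for p in patterns])
    n_dynamic = min(
        n, int(round(config.deg_fraction * n * n_trans / max(avg_nonzero, 1e-9)))
    )

    baseline = rng.normal(0.0, 1.5, size=n)
    no_peak = np.zeros(n, dtype=bool)
    n_silent = int(round(config.no_peak_fraction * n))
    if n_silent:
        no_peak[rng.choice(n, size=n_silent, replace=False)] = True
    baseline = baseline - 2.0 * no_peak  # silent genes sit lower in expression

    cluster = np.zeros(n, dtype=int)
    lfc = np.zeros((n, n_trans))
    if n_dynamic:
        dyn = rng.choice(n, size=n_dynamic, replace=False)
        assigned = rng.integers(0, len(patterns), size=n_dynamic)
        for g, a in zip(dyn, assigned):
            cluster[g] = a + 1
            lfc[g] = np.array(patterns[a], dtype=float) * config.lfc_magnitude

    log2_w = baseline[:, None] + np.concatenate(
        [np.zeros((n, 1)), np.cumsum(lfc, axis=1)], axis=1
    )  # genes x timepoints
    w = 2.0**log2_w
    p = w / w.sum(axis=0, keepdims=True)

    cols = {}
    phi = config.nb_dispersion
    for j, t in enumerate(config.timepoints):
        for r in range(1, config.n_replicates + 1):
            lib = int(rng.integers(config.lib_size_range[0], config.lib_size_range[1] + 1))
            mu = p[:, j] * lib
            if phi > 0:
                counts = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))
            else:
                counts = rng.poisson(mu)
            cols[f"tp{t}_rep{r}"] = counts
    counts = pd.DataFrame(cols, index=gene_ids)

    tdf = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "cluster": cluster,
            "baseline_log2": baseline,
            "has_promoter_peak": ~no_peak,
        }
    ).set_index("gene_id")
    for j, (ta, tb) in enumerate(config.transitions):
        tdf[f"lfc_{ta}to{tb}"] = lfc[:, j]
    return counts, TruthTable(genes=tdf)


# ---------------------------------------------------------------------------
# peaks and fragments


def _plant_marking(
    rng, config: SimulationConfig, expr_lfc: np.ndarray, repressive: bool
):
    """Planted per-transition marking log2FCs from lead/lag coupling.

    Returns (marking lfc matrix genes x transitions, coupling flag rows).
    """
    n, n_trans = expr_lfc.shape
    marking = np.zeros_like(expr_lfc)
    flags = []
    lams = (
        [(0, "current", config.lambda_current)]
        if repressive
        else [
            (-1, "future", config.lambda_future),
            (0, "current", config.lambda_current),
            (1, "past", config.lambda_past),
        ]
    )
    sign = -1.0 if repressive else 1.0
    for g in range(n):
        for u in range(n_trans):
            e = expr_lfc[g, u]
            if e == 0:
                continue
            for shift, offset_name, lam in lams:
                t_mark = u + shift
                if not 0 <= t_mark < n_trans:
                    continue
                if rng.random() < lam:
                    marking[g, t_mark] += sign * e
                    flags.append((g, t_mark, offset_name, u, sign * e))
    return marking, flags


def simulate_peaks_and_fragments(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    ccres: Sequence[CCRERecord],
    truth: TruthTable,
):
    """Per-mark, per-sample peak and fragment sets coupled to the truth table.

    Returns {mark: {sample_id: {"peaks": [PeakRecord], "fragments": frame}}}
    and extends ``truth`` with the planted per-peak marking table and the
    lead/lag coupling flags.
    """
    rng = np.random.default_rng([3, config.seed])
    n = len(genes)
    gene_ids = [g.gene_id for g in genes]
    n_trans = len(config.timepoints) - 1
    lfc_cols = [f"lfc_{a}to{b}" for a, b in config.transitions]
    expr_lfc = truth.genes.loc[gene_ids, lfc_cols].to_numpy()
    has_peak_focal = truth.genes.loc[gene_ids, "has_promoter_peak"].to_numpy()
    baseline = truth.genes.loc[gene_ids, "baseline_log2"].to_numpy()
    dels_by_gene = _dels_by_gene(genes, ccres)

    peak_rows = []  # truth
    coupling_rows = []
    out: Dict[str, dict] = {}
    spacing = config.spacing
    for mark in config.marks:
        repressive = mark == "H3K27me3"
        wlo, whi = _draw_width_range(config, mark)
        if mark == config.focal_mark:
            marked = has_peak_focal.copy()
        else:
            marked = rng.random(n) >= config.no_peak_fraction
        marking, flags = _plant_marking(rng, config, expr_lfc, repressive)
        if mark == config.focal_mark:
            for g, t_mark, offset_name, u, val in flags:
                ta, tb = config.transitions[t_mark]
                ua, ub = config.transitions[u]
                coupling_rows.append(
                    {
                        "mark": mark,
                        "gene_id": gene_ids[g],
                        "marking_transition": f"{ta}to{tb}",
                        "offset": offset_name,
                        "expression_transition": f"{ua}to{ub}",
                        "planted_lfc": val,
                    }
                )

        # canonical (master-level) peaks for this mark
        canon = []  # (label, kind, gene_idx or -1, chrom, start, end, log2_base, lfc row)
        slope = config.peak_gene_coupling * (-0.5 if repressive else 1.0)
        for g_idx, g in enumerate(genes):
            if not marked[g_idx]:
                continue
            width = int(rng.integers(wlo, whi + 1))
            center = g.tss + int(rng.integers(-200, 201))
            start = max(0, center - width // 2)
            log2_base = slope * baseline[g_idx] + rng.normal(
                0.0, config.peak_level_noise_sd
            )
            canon.append(
                (
                    f"{mark}:prom:{g.gene_id}",
                    "promoter",
                    g_idx,
                    g.interval.chrom,
                    start,
                    start + width,
                    log2_base,
                    marking[g_idx],
                )
            )
            dels = dels_by_gene.get(g.gene_id)
            if dels is not None and rng.random() < config.dels_peak_fraction:
                dwidth = int(rng.integers(wlo, whi + 1))
                dcenter = (dels.start + dels.end) // 2 + int(rng.integers(-100, 101))
                dstart = max(0, dcenter - dwidth // 2)
                dmark = np.zeros(n_trans)
                for u in range(n_trans):
                    e = expr_lfc[g_idx, u]
                    if e != 0 and rng.random() < config.lambda_current:
                        dmark[u] += (-1.0 if repressive else 1.0) * e
                canon.append(
                    (
                        f"{mark}:dels:{g.gene_id}",
                        "dELS",
                        g_idx,
                        g.interval.chrom,
                        dstart,
                        dstart + dwidth,
                        slope * baseline[g_idx] - 0.5 + rng.normal(
                            0.0, config.peak_level_noise_sd
                        ),
                        dmark,
                    )
                )
        n_bg = int(round(config.background_peak_fraction * n))
        if n_bg:
            loci = rng.choice(n, size=min(n_bg, n), replace=False)
            for k, g_idx in enumerate(sorted(loci)):
                g = genes[g_idx]
                locus_origin = (g.interval.start // spacing) * spacing
                bwidth = int(rng.integers(wlo, whi + 1))
                bcenter = locus_origin + spacing - int(rng.integers(8_500, 9_501))
                bstart = max(0, bcenter - bwidth // 2)
                canon.append(
                    (
                        f"{mark}:bg:{k:04d}",
                        "background",
                        -1,
                        g.interval.chrom,
                        bstart,
                        bstart + bwidth,
                        rng.normal(-1.5, 1.0),
                        np.zeros(n_trans),
                    )
                )

        for label, kind, g_idx, chrom, start, end, log2_base, mk in canon:
            row = {
                "peak_label": label,
                "mark": mark,
                "kind": kind,
                "gene_id": gene_ids[g_idx] if g_idx >= 0 else "",
                "chrom": chrom,
                "start": start,
                "end": end,
                "log2_base_level": log2_base,
            }
            for j, (ta, tb) in enumerate(config.transitions):
                row[f"lfc_{ta}to{tb}"] = mk[j]
            peak_rows.append(row)

        # realize per-sample peak calls and fragments
        base = np.array([c[6] for c in canon])
        mk_mat = np.array([c[7] for c in canon]) if canon else np.zeros((0, n_trans))
        cum = np.concatenate(
            [np.zeros((len(canon), 1)), np.cumsum(mk_mat, axis=1)], axis=1
        )
        out[mark] = {}
        for j, t in enumerate(config.timepoints):
            for r in range(1, config.n_replicates + 1):
                sample_id = f"tp{t}_rep{r}"
                out[mark][sample_id] = _realize_sample(
                    rng, config, canon, base, cum[:, j], sample_id, mark
                )

    truth.peaks = pd.DataFrame(peak_rows)
    truth.coupling = pd.DataFrame(
        coupling_rows,
        columns=[
            "mark",
            "gene_id",
            "marking_transition",
            "offset",
            "expression_transition",
            "planted_lfc",
        ],
    )
    return out


def _draw_width_range(config: SimulationConfig, mark: str):
    """Canonical-width draw bounds so post-jitter widths stay in the mark range.

    Edge jitter moves each boundary by up to ``boundary_jitter``\\*width, so a
    canonical width w can become anything in [(1-2j)w, (1+2j)w]; drawing from
    the shrunk range keeps every emitted width inside the stated one.
    """
    wlo, whi = config.mark_width_ranges[mark]
    j = config.boundary_jitter
    lo = int(np.ceil(wlo / (1.0 - 2.0 * j)))
    hi = int(np.floor(whi / (1.0 + 2.0 * j)))
    if hi < lo:
        raise ValueError(
            f"width range {wlo}-{whi} for {mark} too narrow for "
            f"boundary jitter {j}"
        )
    return lo, hi


def _dels_by_gene(genes, ccres):
    """Each locus's dELS element, keyed by the gene of that locus."""
    out = {}
    # dELS records appear in locus order interleaved with PLS/pELS records;
    # map each dELS to the most recent preceding PLS-linked gene
    last_gene = None
    for c in ccres:
        if c.ccre_class == "PLS" and c.linked_gene_id:
            last_gene = c.linked_gene_id
        elif c.ccre_class == "dELS" and last_gene is not None:
            out[last_gene] = c.interval
    return out


def _realize_sample(rng, config, canon, base_log2, cum_lfc, sample_id, mark):
    """One sample's peak calls (jittered, detection noise) and fragments."""
    n_peaks = len(canon)
    present = rng.random(n_peaks) < config.presence_prob
    level = 2.0 ** (base_log2 + cum_lfc)
    noise = rng.gamma(1.0 / config.nb_dispersion, config.nb_dispersion, size=n_peaks) \
        if config.nb_dispersion > 0 else np.ones(n_peaks)
    weight = level * noise * present

    lib = int(
        rng.integers(config.frag_lib_size_range[0], config.frag_lib_size_range[1] + 1)
    )
    n_bg = int(round(config.bg_fragment_fraction * lib))
    n_peak_frags = lib - n_bg
    if weight.sum() > 0 and n_peak_frags > 0:
        alloc = rng.multinomial(n_peak_frags, weight / weight.sum())
    else:
        alloc = np.zeros(n_peaks, dtype=int)

    peaks = []
    frag_chrom, frag_start, frag_end = [], [], []
    for i, (label, kind, g_idx, chrom, start, end, _, _) in enumerate(canon):
        if not present[i]:
            continue
        width = end - start
        jit = int(config.boundary_jitter * width)
        s = max(0, start + int(rng.integers(-jit, jit + 1))) if jit else start
        e = end + int(rng.integers(-jit, jit + 1)) if jit else end
        if e <= s:
            e = s + 1
        total = float(weight[i] * 1000.0)
        peaks.append(
            PeakRecord(
                GenomicInterval(chrom, s, e),
                round(total, 3),
                round(total * float(rng.uniform(0.05, 0.2)), 3),
                sample_id,
                mark,
            )
        )
        k = int(alloc[i])
        if k > 0:
            flen = np.clip(rng.normal(180, 50, size=k), 60, 400).astype(int)
            lo = start
            hi = np.maximum(lo + 1, end - flen)
            fs = rng.integers(lo, hi + 1)
            frag_chrom.extend([chrom] * k)
            frag_start.extend(fs.tolist())
            frag_end.extend((fs + flen).tolist())
    if n_bg > 0:
        chroms = [f"chr{c + 1}" for c in range(config.n_chroms)]
        bg_c = rng.integers(0, config.n_chroms, size=n_bg)
        bg_s = rng.integers(0, config.chrom_length - 500, size=n_bg)
        bg_len = np.clip(rng.normal(180, 50, size=n_bg), 60, 400).astype(int)
        frag_chrom.extend(chroms[c] for c in bg_c)
        frag_start.extend(bg_s.tolist())
        frag_end.extend((bg_s + bg_len).tolist())
    frags = pd.DataFrame(
        {"chrom": frag_chrom, "start": frag_start, "end": frag_end}
    ).sort_values(["chrom", "start", "end"], kind="stable", ignore_index=True)
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    return {"peaks": peaks, "fragments": frags}


# ---------------------------------------------------------------------------
# full study + writing


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genes: list
    ccres: list
    counts: pd.DataFrame
    truth: TruthTable
    peakdata: dict  # mark -> sample -> {"peaks", "fragments"}


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    genes, ccres = simulate_genome_and_genes(config)
    counts, truth = simulate_expression(config, genes)
    peakdata = simulate_peaks_and_fragments(config, genes, ccres, truth)
    return SimulatedStudy(config, genes, ccres, counts, truth, peakdata)


def write_study(study: SimulatedStudy, outdir) -> None:
    """Emit the exact formats the io layer reads (all plain text)."""
    from . import io_formats as iof

    out = Path(outdir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    (out / "fragments").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    iof.write_gene_bed(out / "genes.bed", study.genes)
    iof.write_ccre_bed(out / "ccres.bed", study.ccres)
    iof.write_count_matrix(out / "expression_counts.tsv", study.counts)
    study.truth.genes.to_csv(out / "truth" / "genes.tsv", sep="\t", float_format="%.6g")
    study.truth.peaks.to_csv(
        out / "truth" / "peaks.tsv", sep="\t", index=False, float_format="%.6g"
    )
    study.truth.coupling.to_csv(
        out / "truth" / "coupling.tsv", sep="\t", index=False, float_format="%.6g"
    )
    for mark in study.config.marks:
        (out / "peaks" / mark).mkdir(exist_ok=True)
        (out / "fragments" / mark).mkdir(exist_ok=True)
        for sample_id, data in study.peakdata[mark].items():
            iof.write_peak_file(
                out / "peaks" / mark / f"{sample_id}.stringent.bed", data["peaks"]
            )
            iof.write_fragments(
                out / "fragments" / mark / f"{sample_id}.bed", data["fragments"]
            )
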