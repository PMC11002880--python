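"""End-to-end pipeline steps over a run directory.

Each ``run_*`` function is one pipeline stage operating on plain-text inputs
and writing plain-text tables, so the CLI subcommands, the numbered analysis
scripts and the acceptance script are all thin wrappers over the same code.
All tables are written with a fixed float format so that a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import annotation as ann
from . import expression as ex
from . import integration as integ
from . import io_formats as iof
from . import peaks as pk
from .synthetic import SimulationConfig, simulate_study, write_study

_FF = "%.6g"
_SAMPLE_FILE_RE = re.compile(r"(tp\d+_rep\d+)")


def _sample_id_from_path(path: Path) -> str:
    m = _SAMPLE_FILE_RE.search(path.name)
    if m is None:
        raise ValueError(f"cannot parse tp<d>_rep<r> sample id from {path.name!r}")
    return m.group(1)


def _transitions_from_meta(meta: pd.DataFrame):
    tps = sorted(meta["timepoint"].unique())
    return [(tps[i], tps[i + 1]) for i in range(len(tps) - 1)]


def _write(df: pd.DataFrame, path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format=_FF, **kw)


# ---------------------------------------------------------------------------


def run_simulate(config: SimulationConfig, outdir) -> None:
    write_study(simulate_study(config), outdir)


def run_expr(
    counts_path,
    outdir,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    k: int = 9,
    gmt_path=None,
    prior_n: float = 10.0,
    with_silhouette: bool = True,
) -> dict:
    """Normalize, test all consecutive transitions, cluster DEG profiles."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts, meta = iof.read_count_matrix(counts_path)
    factors = ex.tmm_factors(counts)
    logcpm = ex.log_cpm(counts, factors)
    _write(logcpm, out / "logcpm.tsv", index_label="gene_id")
    _write(
        pd.DataFrame(
            {"lib_size": factors.lib_size, "tmm_factor": factors.factor},
            index=factors.sample_ids,
        ),
        out / "factors.tsv",
        index_label="sample_id",
    )
    scores, varfrac = ex.pca_samples(logcpm)
    _write(scores, out / "pca.tsv", index_label="sample_id")
    _write(
        pd.DataFrame({"variance_fraction": varfrac},
                     index=[f"PC{i+1}" for i in range(len(varfrac))]),
        out / "pca_varfrac.tsv",
        index_label="component",
    )

    transitions = _transitions_from_meta(meta)
    deg_union: list = []
    summary_rows = []
    de_tables = {}
    for ta, tb in transitions:
        ga = list(meta.index[meta["timepoint"] == ta])
        gb = list(meta.index[meta["timepoint"] == tb])
        results, filtered = ex.differential_test(
            counts, ga, gb, factors=None, prior_n=prior_n,
            lfc_threshold=lfc_threshold, fdr_threshold=fdr_threshold,
        )
        df = pd.DataFrame(
            [
                {
                    "feature_id": r.feature_id,
                    "log2fc": r.log2fc,
                    "p_value": r.p_value,
                    "fdr": r.fdr,
                    "status": r.status,
                }
                for r in results
            ]
        ).set_index("feature_id")
        de_tables[(ta, tb)] = df
        _write(df, out / f"de_{ta}to{tb}.tsv", index_label="feature_id")
        up = list(df.index[df["status"] == "up"])
        down = list(df.index[df["status"] == "down"])
        deg_union.extend(up + down)
        summary_rows.append(
            {
                "transition": f"{ta}to{tb}",
                "n_up": len(up),
                "n_down": len(down),
                "n_filtered": len(filtered),
            }
        )
    summary = pd.DataFrame(summary_rows)
    _write(summary, out / "deg_summary.tsv", index=False)

    deg_ids = sorted(set(deg_union))
    if deg_ids:
        k_eff = min(k, len(deg_ids))
        assignments, means, z = ex.cluster_deg_profiles(
            logcpm, meta["timepoint"], deg_ids, k_eff
        )
        cl = pd.DataFrame(
            {
                "gene_id": [a.gene_id for a in assignments],
                "cluster": [a.cluster_id for a in assignments],
            }
        ).set_index("gene_id")
        _write(cl.join(z), out / "clusters.tsv", index_label="gene_id")
        _write(means, out / "cluster_means.tsv", index_label="cluster")
        if with_silhouette and len(deg_ids) > 15:
            _write(ex.silhouette_by_k(z), out / "silhouette.tsv", index=False)
        if gmt_path is not None:
            gene_sets = iof.read_gmt(gmt_path)
            enr = ex.gene_set_enrichment(
                set(deg_ids), set(counts.index), gene_sets
            )
            _write(enr, out / "enrichment.tsv", index=False)
    return {"summary": summary, "de_tables": de_tables, "n_deg": len(deg_ids)}


def run_peaks(
    peaks_dir,
    fragments_dir,
    mark: str,
    outdir,
    lfc_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
    blacklist_path=None,
    blacklist_after_merge: bool = False,
    prior_n: float = 10.0,
) -> dict:
    """Master peaks, fragment counts, differential marking for one mark."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    peak_files = sorted(Path(peaks_dir).glob("*.bed"))
    frag_files = {p.name: p for p in Path(fragments_dir).glob("*.bed")}
    if not peak_files:
        raise FileNotFoundError(f"no peak files under {peaks_dir}")
    blacklist = (
        [r.interval for r in iof.read_bed(blacklist_path)] if blacklist_path else []
    )
    per_sample: Dict[str, list] = {}
    for pf in peak_files:
        sid = _sample_id_from_path(pf)
        recs = iof.read_peak_file(pf, sid, mark)
        if blacklist and not blacklist_after_merge:
            recs = iof.filter_blacklist(recs, blacklist)
        per_sample[sid] = recs
    samples = sorted(per_sample)
    master = pk.build_master_peaks([per_sample[s] for s in samples], mark)
    if blacklist and blacklist_after_merge:
        master = iof.filter_blacklist(master, blacklist)

    fragments = {}
    for sid in samples:
        matches = [p for name, p in frag_files.items() if sid in name]
        if not matches:
            raise FileNotFoundError(f"no fragment file for sample {sid}")
        fragments[sid] = iof.read_fragments_frame(matches[0])
    counts = pk.count_fragments(master, fragments)

    mrows = pd.DataFrame(
        {
            "peak_id": [m.peak_id for m in master],
            "chrom": [m.interval.chrom for m in master],
            "start": [m.interval.start for m in master],
            "end": [m.interval.end for m in master],
            "n_source_peaks": [len(m.source_peaks) for m in master],
        }
    ).set_index("peak_id")
    _write(mrows.join(counts), out / "master_peaks.tsv", index_label="peak_id")
    factors = ex.tmm_factors(counts)
    levels = pk.peak_level_logcpm(counts, factors)
    _write(levels, out / "logcpm.tsv", index_label="peak_id")

    stats_rows = []
    for sid in samples:
        if per_sample[sid]:
            st = pk.peak_width_stats(per_sample[sid])
            stats_rows.append({"sample": sid, **st})
    st = pk.peak_width_stats(master)
    stats_rows.append({"sample": "master", **st})
    _write(pd.DataFrame(stats_rows), out / "width_stats.tsv", index=False)

    tps = sorted({int(s.split("_")[0][2:]) for s in samples})
    diffs = {}
    for ta, tb in [(tps[i], tps[i + 1]) for i in range(len(tps) - 1)]:
        ga = [s for s in samples if s.startswith(f"tp{ta}_")]
        gb = [s for s in samples if s.startswith(f"tp{tb}_")]
        results, _ = pk.differential_peaks(
            counts, ga, gb, lfc_threshold, fdr_threshold,
            factors=factors, prior_n=prior_n,
        )
        df = pd.DataFrame(
            [
                {
                    "peak_id": r.peak_id,
                    "log2fc": r.log2fc,
                    "p_value": r.p_value,
                    "fdr": r.fdr,
                    "status": r.status,
                }
                for r in results
            ]
        ).set_index("peak_id")
        diffs[(ta, tb)] = df
        _write(df, out / f"diff_{ta}to{tb}.tsv", index_label="peak_id")

    det_rows = []
    for ta, tb in [(tps[i], tps[i + 1]) for i in range(len(tps) - 1)]:
        set_a = [p for s in samples if s.startswith(f"tp{ta}_") for p in per_sample[s]]
        set_b = [p for s in samples if s.startswith(f"tp{tb}_") for p in per_sample[s]]
        fwd = pk.peak_set_detection_overlap(set_a, set_b)
        rev = pk.peak_set_detection_overlap(set_b, set_a)
        det_rows.append({"from": f"tp{ta}", "to": f"tp{tb}", **fwd})
        det_rows.append({"from": f"tp{tb}", "to": f"tp{ta}", **rev})
    _write(pd.DataFrame(det_rows), out / "detection_overlap.tsv", index=False)
    return {"master": master, "counts": counts, "levels": levels, "diffs": diffs}


def run_annotate(
    master_path,
    genes_path,
    ccre_path,
    outdir,
    flank: int = 2000,
    levels_path=None,
    top_n: int = 2000,
) -> dict:
    """cCRE-prioritised annotation of a master peak table."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mdf = pd.read_csv(master_path, sep="\t")
    from .core import GenomicInterval

    class _P:
        def __init__(self, pid, iv):
            self.peak_id, self.interval = pid, iv

    peaks = [
        _P(r.peak_id, GenomicInterval(r.chrom, int(r.start), int(r.end)))
        for r in mdf.itertuples()
    ]
    genes = iof.read_gene_bed(genes_path)
    ccres = iof.read_ccre_bed(ccre_path)
    annotated = ann.annotate_peaks(peaks, genes, ccres, flank=flank)
    adf = ann.annotation_frame(annotated)
    _write(adf, out / "annotation.tsv", index=False)

    n = len(adf)
    cls = adf["ccre_class"].value_counts()
    feat = adf["genomic_feature"].value_counts()
    dbin = adf["distance_bin"].value_counts()
    summary = pd.concat(
        [
            pd.DataFrame(
                {"category": "ccre_class", "label": cls.index, "count": cls.values}
            ),
            pd.DataFrame(
                {"category": "genomic_feature", "label": feat.index, "count": feat.values}
            ),
            pd.DataFrame(
                {"category": "distance_bin", "label": dbin.index, "count": dbin.values}
            ),
        ]
    )
    summary["fraction"] = summary["count"] / max(n, 1)
    summary = summary.sort_values(["category", "label"], kind="stable")
    _write(summary, out / "class_summary.tsv", index=False)

    if levels_path is not None:
        lv = pd.read_csv(levels_path, sep="\t", index_col=0)
        mean_level = lv.mean(axis=1)
        top = ann.top_dels_genes(annotated, mean_level, n=top_n)
        pd.DataFrame({"gene_id": top}).to_csv(
            out / "top_dels_genes.tsv", sep="\t", index=False
        )
    return {"annotation": adf, "summary": summary}


def _promoter_pairs_from_annotation(adf: pd.DataFrame):
    pairs = []
    for r in adf.itertuples():
        if isinstance(r.promoter_genes, str) and r.promoter_genes:
            for g in r.promoter_genes.split(","):
                pairs.append((r.peak_id, g))
    return pairs


def _peak_diffs_from_table(df: pd.DataFrame):
    return [
        pk.PeakDifferential(pid, row["log2fc"], row["p_value"], row["fdr"], row["status"])
        for pid, row in df.iterrows()
    ]


def run_integrate(
    expr_dir,
    peaks_root,
    annot_root,
    outdir,
    marks: Sequence[str],
    focal_mark: str,
    focal_transition: tuple,
    n_bins: int = 4,
    epsilon: float = 0.0,
) -> dict:
    """Join expression with promoter/enhancer marking for all marks."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    expr_dir, peaks_root, annot_root = Path(expr_dir), Path(peaks_root), Path(annot_root)
    logcpm = pd.read_csv(expr_dir / "logcpm.tsv", sep="\t", index_col=0)
    de_tables = {}
    for f in sorted(expr_dir.glob("de_*.tsv")):
        m = re.match(r"de_(\d+)to(\d+)\.tsv", f.name)
        if m:
            de_tables[(int(m.group(1)), int(m.group(2)))] = pd.read_csv(
                f, sep="\t", index_col=0
            )
    transitions = sorted(de_tables)
    ta, tb = focal_transition
    if (ta, tb) not in de_tables:
        raise ValueError(f"focal transition {ta}->{tb} not found in {expr_dir}")
    t_idx = transitions.index((ta, tb))
    offsets = {
        "past": transitions[t_idx - 1] if t_idx > 0 else None,
        "current": (ta, tb),
        "future": transitions[t_idx + 1] if t_idx + 1 < len(transitions) else None,
    }

    marking_frames = {}
    for mark in marks:
        adf = pd.read_csv(annot_root / mark / "annotation.tsv", sep="\t")
        levels = pd.read_csv(peaks_root / mark / "logcpm.tsv", sep="\t", index_col=0)
        dpath = peaks_root / mark / f"diff_{ta}to{tb}.tsv"
        diffs = _peak_diffs_from_table(pd.read_csv(dpath, sep="\t", index_col=0))
        pairs = _promoter_pairs_from_annotation(adf)
        gm = integ.gene_pls_level(pairs, levels, peak_diffs=diffs)
        marking_frames[mark] = (gm, adf, levels)
        _write(gm, out / f"gene_pls_{mark}.tsv", index_label="gene_id")

    # lead/lag concordance, both modes, per mark
    conc_rows = []
    for mark in marks:
        gm = marking_frames[mark][0]
        if gm.empty or "status" not in gm:
            continue
        expr_de = {
            off: (de_tables[tr] if tr is not None else None)
            for off, tr in offsets.items()
        }
        for mode in ("sign", "deg_status"):
            rep = integ.lead_lag_concordance(
                gm, expr_de, transition=f"{ta}to{tb}", mode=mode, epsilon=epsilon
            )
            for off in integ.OFFSETS:
                c = rep.counts.get(off)
                conc_rows.append(
                    {
                        "mark": mark,
                        "transition": rep.transition,
                        "mode": mode,
                        "offset": off,
                        "universe": rep.universe,
                        "concordant": c["concordant"] if c else "",
                        "discordant": c["discordant"] if c else "",
                        "unchanged": c["unchanged"] if c else "",
                        "fraction_concordant": rep.fractions[off],
                    }
                )
    _write(pd.DataFrame(conc_rows), out / "concordance.tsv", index=False)

    # expression stratified by promoter / enhancer peak level
    mean_expr = logcpm.mean(axis=1)
    strat_rows = []
    for mark in marks:
        gm, adf, levels = marking_frames[mark]
        level_cols = [c for c in gm.columns if c.startswith("tp")]
        pls_levels = gm[level_cols].mean(axis=1) if not gm.empty else pd.Series(dtype=float)
        for grouping, lv in (("PLS", pls_levels), ("dELS", _dels_levels(adf, levels))):
            lv = lv.reindex(mean_expr.index)
            try:
                rep = integ.stratify_expression_by_level(
                    lv, mean_expr, n_bins=n_bins, grouping=grouping
                )
            except ValueError:
                continue
            for lab in rep.bins:
                strat_rows.append(
                    {
                        "mark": mark,
                        "grouping": grouping,
                        "bin": lab,
                        "n": int(rep.summary.loc[lab, "n"]),
                        "median": rep.summary.loc[lab, "median"],
                        "q1": rep.summary.loc[lab, "q1"],
                        "q3": rep.summary.loc[lab, "q3"],
                        "trend_rho": rep.trend_rho,
                    }
                )
    _write(pd.DataFrame(strat_rows), out / "stratification.tsv", index=False)

    # pairwise mark-change correlation over the focal-transition DEGs
    de_focal = de_tables[(ta, tb)]
    up = list(de_focal.index[de_focal["status"] == "up"])
    down = list(de_focal.index[de_focal["status"] == "down"])
    pw_rows = []
    mark_list = list(marks)
    for i in range(len(mark_list)):
        for j in range(i + 1, len(mark_list)):
            ma, mb = mark_list[i], mark_list[j]
            gma, gmb = marking_frames[ma][0], marking_frames[mb][0]
            if "log2fc" not in gma or "log2fc" not in gmb:
                continue
            try:
                rep = integ.pairwise_mark_change_correlation(
                    gma["log2fc"], gmb["log2fc"], up, down, ma, mb
                )
            except ValueError:
                continue
            for direction in ("up", "down"):
                q = rep.quadrants[direction]
                pw_rows.append(
                    {
                        "mark_a": ma,
                        "mark_b": mb,
                        "direction": direction,
                        "n_genes": rep.n_genes,
                        "pearson_r": rep.pearson,
                        **{f"frac_{k}": v for k, v in q.items()},
                        "n_zero": rep.zero_counts[direction],
                    }
                )
    _write(pd.DataFrame(pw_rows), out / "pairwise_marks.tsv", index=False)

    # DEG vs marking overlap counts
    ov_rows = []
    for mark in marks:
        gm = marking_frames[mark][0]
        if "log2fc" not in gm:
            continue
        ov = integ.deg_marking_overlap({"up": set(up), "down": set(down)}, gm)
        ov.insert(0, "mark", mark)
        ov_rows.append(ov)
    if ov_rows:
        _write(pd.concat(ov_rows, ignore_index=True), out / "deg_overlap.tsv", index=False)
    return {"concordance": pd.DataFrame(conc_rows)}


def _dels_levels(adf: pd.DataFrame, levels: pd.DataFrame) -> pd.Series:
    """Per-gene level of the strongest linked dELS peak (mean over samples)."""
    mean_level = levels.mean(axis=1)
    best: Dict[str, float] = {}
    sub = adf[(adf["ccre_class"] == "dELS") & adf["linked_gene"].notna()]
    for r in sub.itertuples():
        g = r.linked_gene
        if not isinstance(g, str) or not g:
            continue
        lvl = mean_level.get(r.peak_id)
        if lvl is None:
            continue
        if g not in best or lvl > best[g]:
            best[g] = float(lvl)
    return pd.Series(best, dtype=float)


def study_concordance(
    study,
    focal_transition: Optional[tuple] = None,
    mode: str = "sign",
    prior_n: float = 10.0,
):
    """In-memory lead/lag concordance for a simulated study's focal mark.

    Runs the full analysis path (expression DE per transition, master peaks,
    fragment counting, differential marking, promoter pairing, gene-level
    marking, concordance) without touching the file system. Returns the
    ConcordanceReport for the focal transition (default: the middle one).
    """
    cfg = study.config
    transitions = cfg.transitions
    if focal_transition is None:
        focal_transition = transitions[(len(transitions) - 1) // 2]
    t_idx = transitions.index(tuple(focal_transition))
    meta = pd.DataFrame(
        {"timepoint": [int(s.split("_")[0][2:]) for s in study.counts.columns]},
        index=study.counts.columns,
    )
    de_tables = {}
    for ta, tb in transitions:
        ga = list(meta.index[meta["timepoint"] == ta])
        gb = list(meta.index[meta["timepoint"] == tb])
        results, _ = ex.differential_test(study.counts, ga, gb, prior_n=prior_n)
        de_tables[(ta, tb)] = pd.DataFrame(
            {
                "log2fc": [r.log2fc for r in results],
                "fdr": [r.fdr for r in results],
                "status": [r.status for r in results],
            },
            index=[r.feature_id for r in results],
        )

    mark = cfg.focal_mark
    per_sample = study.peakdata[mark]
    samples = sorted(per_sample)
    master = pk.build_master_peaks([per_sample[s]["peaks"] for s in samples], mark)
    counts = pk.count_fragments(
        master, {s: per_sample[s]["fragments"] for s in samples}
    )
    factors = ex.tmm_factors(counts)
    levels = pk.peak_level_logcpm(counts, factors)
    ta, tb = focal_transition
    ga = [s for s in samples if s.startswith(f"tp{ta}_")]
    gb = [s for s in samples if s.startswith(f"tp{tb}_")]
    diffs, _ = pk.differential_peaks(counts, ga, gb, factors=factors, prior_n=prior_n)

    idx_pairs = ann.promoter_peak_pairs(master, study.genes)
    pairs = [(master[i].peak_id, gid) for i, gid in idx_pairs]
    gm = integ.gene_pls_level(pairs, levels, peak_diffs=diffs)
    expr_de = {
        "past": de_tables[transitions[t_idx - 1]] if t_idx > 0 else None,
        "current": de_tables[(ta, tb)],
        "future": de_tables[transitions[t_idx + 1]]
        if t_idx + 1 < len(transitions)
        else None,
    }
    return integ.lead_lag_concordance(
        gm, expr_de, transition=f"{ta}to{tb}", mode=mode
    )


def run_report(run_dir, out_path=None) -> str:
    """Plain-text summary of a completed run."""
    run = Path(run_dir)
    lines = ["epidyn run summary", "==================", ""]

    def _maybe(path, title, fmt):
        p = run / path
        if p.exists():
            lines.append(title)
            lines.extend(fmt(pd.read_csv(p, sep="\t")))
            lines.append("")

    _maybe(
        "expr/deg_summary.tsv",
        "Differential expression (per transition):",
        lambda df: [
            f"  {r.transition}: {r.n_up} up, {r.n_down} down" for r in df.itertuples()
        ],
    )
    _maybe(
        "integrate/concordance.tsv",
        "Lead/lag concordance (sign mode):",
        lambda df: [
            f"  {r.mark} {r.transition} {r.offset}: "
            f"{r.fraction_concordant:.3f} of {r.universe}"
            for r in df.itertuples()
            if r.mode == "sign" and isinstance(r.fraction_concordant, float)
            and np.isfinite(r.fraction_concordant)
        ],
    )
    _maybe(
        "integrate/pairwise_marks.tsv",
        "Pairwise mark-change correlation (DEGs):",
        lambda df: sorted(
            {
                f"  {r.mark_a} vs {r.mark_b}: r = {r.pearson_r:.3f}"
                for r in df.itertuples()
            }
        ),
    )
    text = "\n".join(lines)
    if out_path is not None:
        Path(out_path).write_text(text)
    return text
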