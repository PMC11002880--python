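# epidyn

Time-course integration of histone post-translational-modification (hPTM)
CUT&Tag peak profiles with RNA-seq, built around one question: do promoter
marking changes *precede* gene-expression changes?

The motivating system is macrophages recruited to ischemia-injured muscle,
profiled at 1, 2, 4 and 7 days post injury (two replicates each) for
H3K18la (histone lactylation, the focal mark), H3K4me3, H3K27ac and
H3K27me3, alongside matched RNA-seq. The package is aimed at computational
epigenomics researchers who want this style of analysis as tested,
reusable code rather than a one-off notebook — and, because the original
raw data are not publicly deposited, it ships a fully synthetic study
generator with planted ground truth so every claim is testable.

## What it computes

* **Expression**: TMM normalization and log-CPM; per-transition
  differential expression with an edgeR-style negative-binomial exact test
  (conditional-likelihood dispersion estimation with empirical-Bayes
  shrinkage, exact double-tail p, mid-p by default); DEGs at
  FDR < 0.05 and |log2FC| > 1; z-scored DEG profile clustering
  (average linkage, correlation distance, clusters numbered by peak time);
  sample PCA; hypergeometric gene-set enrichment over user GMT files.
* **Peaks**: per-mark master (union) peak lists merged >= 1 bp
  single-linkage across all samples; fragment counting over master peaks;
  differential marking (|log2FC| > 0.5, FDR < 0.05; hyper/hypo); width
  statistics; cross-timepoint detection overlap.
* **Annotation**: promoter windows (TSS +/- 2 kb), signed TSS distances,
  cCRE classes with the priority PLS > dELS > pELS > other; closest
  non-overlapping gene links for distal enhancers; top-n genes behind the
  strongest dELS peaks.
* **Integration**: expression stratified by promoter/enhancer peak-level
  quantiles (Mann-Whitney between bins, Spearman trend); **lead/lag
  concordance** — for genes with significant promoter marking change at
  transition T, the fraction whose expression change at T-1 / T / T+1
  shares its sign; pairwise mark-change correlations with quadrant
  fractions; DEG-vs-marking overlap counts.

The central statistic: with marking change m_g at transition T and
expression change e_g at offset o in {T-1, T, T+1},

    concordance(o) = #{g : sign(m_g) = sign(e_g(o))} / #universe,

where the universe is the set of genes with FDR < 0.05 and
|log2FC| > 0.5 promoter marking change at T. A mark that is instructive
for expression shows concordance(T+1) > concordance(T-1).

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic design (2000 genes, 4 timepoints x 2 replicates, 4 marks,
seed 1), writing tables under `results/run/`:

```sh
python analysis/01_simulate.py
python analysis/02_expression.py
python analysis/03_peaks.py
python analysis/04_annotate.py
python analysis/05_integrate.py
python analysis/06_report.py
```

`02_expression.py` prints the per-transition DEG counts:

```
transition 1to2: 162 up, 135 down DEGs
transition 2to4: 203 up, 132 down DEGs
transition 4to7: 146 up, 107 down DEGs
```

and `05_integrate.py` the headline lead/lag result for the focal mark at
the 2->4 transition:

```
H3K18la 2to4 past: concordant fraction 0.559 (universe 102)
H3K18la 2to4 current: concordant fraction 0.912 (universe 102)
H3K18la 2to4 future: concordant fraction 0.902 (universe 102)
```

Reading: of the 102 genes whose H3K18la promoter peak changes
significantly from day 2 to day 4, 90% change expression in the same
direction over the *next* transition (4->7), against 56% — chance level —
over the previous one (1->2). That asymmetry is exactly the planted
`lambda_future = 0.8` vs `lambda_past = 0.1` coupling being recovered
through the full pipeline. The report also shows the active marks'
promoter changes correlating pairwise (Pearson r 0.52-0.59 over DEGs)
while the repressive H3K27me3 anticorrelates (r about -0.38), and its
concordance column inverts (3% concurrent concordance), as a repressive
mark should.

The same steps are available as CLI subcommands (`epidyn simulate | expr |
peaks | annotate | integrate | report`) for use on real data in the
documented formats: SEACR-style 6-column peak files, BED3 fragment files,
BED6 gene models, cCRE BED with class labels, TSV count matrices with
`tp<d>_rep<r>` sample names, GMT gene sets. A fixed seed makes the whole
chain byte-reproducible.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full default-scale pipeline — simulation, expression and
peak differential analysis, annotation and integration — from scratch under
the given seed and writes its JSON result file. See `docs/methods.md` for
the model, parameter and convention details, and the limits of what the
synthetic study can establish.
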