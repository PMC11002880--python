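# Methods

`epidyn` analyses a time-course of macrophage histone-PTM (hPTM) CUT&Tag
profiles together with matched RNA-seq, asking whether promoter marking
changes *lead* gene-expression changes. Because the study it models deposited
no raw data, the package ships a synthetic-study generator with planted,
machine-readable ground truth; every downstream claim a test makes is a
recovery or calibration statement against that truth, a brute-force oracle,
or a closed form.

## Coordinates and interval semantics

All coordinates everywhere are 0-based half-open (BED convention). The
overlap predicate is ">= 1 shared bp"; adjacency (`end == start`) never
counts as overlap, in blacklist filtering, master-peak merging, fragment
counting and cCRE assignment alike. The master (union) peak list of a mark
merges all per-sample peak sets by single linkage (transitive, no
minimum-overlap fraction) across *all* timepoints, so every condition is
quantified against one shared reference.

## Normalization

* **TMM.** Scaling factors use the trimmed mean of M-values: 30% trim on
  M, 5% on A, precision-weighted mean of the surviving M-values, factors
  rescaled to geometric mean 1. The reference sample is the one whose
  75th-percentile count fraction is closest to the mean. Precision weights
  are computed on count *fractions* rather than raw counts; at equal depth
  this is proportional to the usual binomial delta-method weight, and it
  makes the factors exactly invariant to a pure depth change of any sample
  (an invariant the test suite asserts at 1e-9).
* **log-CPM.** `log2((y + p_k) / (L_k + 2 p_k) * 1e6)` with effective
  library size `L_k` (library size x TMM factor) and pseudo-count
  `p_k = prior * L_k / 1e6`, i.e. *prior counts per million* (default
  prior 2). A fixed pseudo-count is not stable under depth changes (a count
  of 10 shifts by ~0.13 when depth doubles); the depth-proportional prior is
  exactly stable and coincides with the usual "+2" at a 1e6 library.
  Peak-level log-CPM uses the same code path on fragment counts over master
  peaks.

## Differential testing (genes and peaks share one engine)

An edgeR-style negative-binomial exact test, written from first principles:

1. Counts are scaled to the geometric-mean effective library size
   (rounded for the integer-conditional machinery; unrounded means drive the
   fold-change estimate).
2. Dispersion phi is estimated by maximizing the *exact conditional
   likelihood* of each group's counts given its total (for per-sample size
   r = 1/phi the group total is NB with size n*r, so the conditional law is
   negative hypergeometric; conditioning profiles out the group means
   without the downward bias of plug-in MLE). Per-feature estimates maximize
   their own conditional likelihood plus `prior_n` (default 10) times the
   average curve over all features — empirical-Bayes shrinkage toward the
   common dispersion. Optimization is a grid in log-phi (1e-4 to ~6.3)
   with quadratic refinement; simulation tests recover known phi within a
   few percent.
3. The p-value is the exact double tail of one group's total conditional on
   the overall total: group sums are NB with sizes n_A/phi and n_B/phi, the
   conditional pmf is enumerated and all outcomes no more probable than the
   observed one are summed. In the Poisson limit (phi < 1e-8) this is the
   conditional binomial test, asserted against an independent oracle.
   By default the **mid-p** variant is reported (half-weight on outcomes
   exactly as probable as the observed): plain double-tail p-values from a
   discrete test are conservative and visibly non-uniform under the null at
   2000 features; mid-p restores near-uniformity while the realized
   discovery fraction at BH 0.05 stays well below nominal in the
   calibration tests.
4. log2FC = log2((mean_B + c)/(mean_A + c)) on library-equalized counts with
   pseudo-count c = 2; Benjamini-Hochberg step-up FDR over tested features;
   all-zero features are excluded and reported as filtered.

Classification is strict on both thresholds: genes need FDR < 0.05 **and**
|log2FC| > 1 (so exactly 1.0 is not significant); differentially marked
peaks use |log2FC| > 0.5 at FDR < 0.05, labelled hyper/hypo. With a single
sample per group the dispersion must be supplied.

## DEG profile clustering and PCA

Per-gene mean log-CPM per timepoint is z-scored across timepoints and
clustered by average-linkage hierarchical clustering on correlation
distance, with the tree cut at k (default 9). Clusters are renumbered by the
time of their mean-profile peak (earliest = 1, ties by peak height), making
ids deterministic. Constant profiles (undefined z-score) are assigned to the
nearest cluster mean with a warning. The choice of k is documented by a mean
silhouette across k in 4..12 on the same tree. Sample PCA is the SVD of the
gene-centered matrix with a deterministic sign convention
(largest-magnitude loading positive).

## Annotation

Promoters are TSS +/- 2000 bp, strand-independent, clipped at zero. A peak
overlapping several cCREs takes the highest-priority class:
PLS > dELS > pELS > other cCREs (CTCF-only and DNase-H3K4me3 collapse to
"other") — proximal enhancers that co-overlap a promoter are absorbed by it.
Conventions the source tooling leaves unstated are fixed as follows:

* **TSS distance**: 0 if the peak covers the TSS base, else bases between
  TSS and nearest covered base; sign + when the peak lies downstream in the
  gene's orientation. Reported in bins 0 / 0-1 kb / 1-10 kb / 10-100 kb /
  >100 kb.
* **dELS-to-gene links**: closest gene whose *body* does not overlap the
  peak, by edge-to-edge gap (adjacency = 0); ties by TSS gap, then gene id.
  The TSS-gap alternative is computed alongside for the tie-break.
* **Top enhancer genes**: dELS peaks ranked by mean log2-CPM (ties by
  coordinate), distinct linked genes collected until n (default 2000).

All interval operations are asserted equal to brute-force all-pairs scans on
1000 random instances each.

## Integration

* **Gene-level promoter marking**: a gene's PLS level per sample is the max
  over its promoter-overlapping peaks; differential statistics are inherited
  from the covering peak with the largest |log2FC| (the aggregation rule is
  a documented choice; gene-wise statements in the field are usually made
  from peak-wise tests without one). Peaks spanning two promoters pair with
  both genes and are flagged as shared.
* **Stratification**: genes split into a no-peak bin plus rank-based
  level-quantile bins (sizes within +-1); expression summarised by median
  and quartiles, consecutive bins compared by two-sided Mann-Whitney U
  (exact by enumeration when n_x*n_y <= 400 and tie-free, else normal
  approximation with tie and continuity correction), trend as Spearman rho
  of bin index vs bin median. Expression is in log-CPM, not RPKM: gene
  lengths are not modelled, and rank-based statistics are unaffected.
* **Lead/lag concordance**: universe = genes whose promoter marking at the
  focal transition T is significant (hyper or hypo). For each offset
  (past = T-1, current = T, future = T+1) a gene is concordant when the sign
  of its marking change matches the sign of its expression change
  (mode `sign`, epsilon 0: any nonzero estimate counts); mode `deg_status`
  instead requires DEG status to match direction, with `ns` counted as
  unchanged. Genes untested on the expression side count as unchanged so
  the three counts always partition the universe. Edge transitions report NA.
* **Pairwise mark correlation**: Pearson r of per-gene promoter log2FCs of
  two marks over the DEGs; quadrant fractions per DEG direction with
  exact-zero changes assigned to the positive side (arbitrary but fixed;
  the zero count is reported).

## The synthetic study

The generator emits exactly the formats the readers consume, deterministic
to the byte under a fixed seed (the test suite hashes two runs).

* **Genome**: gene loci on a regular grid (spacing = chromosome length /
  genes per chromosome, minimum 32 kb), gene bodies 2-5 kb with random
  strand; per locus one PLS centered on the TSS, one pELS 600-950 bp
  downstream, one dELS >= 10 kb from every TSS (asserted by brute force),
  CTCF-only elements in 20% of loci, a reserved background-peak strip.
  Optionally, loci host a twin gene 1.2 kb away so promoter windows overlap
  (the shared-promoter-peak case).
* **Expression**: per-gene lognormal baseline (sd 1.5 log2); a
  `deg_fraction`-scaled subset of genes is dynamic, following archetype
  sign patterns over the three transitions at planted |log2FC|
  `lfc_magnitude` (default 2). Patterns are generated in orbits closed under
  time reversal and sign negation (first two always monotone up/down):
  reversal closure makes equal lead/lag coupling imply zero expected
  concordance asymmetry, negation closure balances up/down mass per
  transition so normalization sees no composition drift. Counts are NB with
  dispersion `nb_dispersion` (default 0.05) on per-timepoint renormalized
  abundances times a uniform library size (default 1.5-2.5M reads).
  A `no_peak_fraction` (default 10%) of genes is "silent": promoter-peak-free
  for the focal mark and 4x lower baseline, giving the no-peak stratification
  bin its expected low expression.
* **Peaks/fragments**: canonical promoter peaks centered near the TSS and
  dELS peaks at enhancer elements, widths drawn per mark from the reported
  ranges (H3K18la 1000-2000, H3K4me3 1500-2500, H3K27ac 1000-3500,
  H3K27me3 2000-6000 bp); the draw range is shrunk so that replicate edge
  jitter (+-10% of width per boundary) never leaves the stated range.
  Peak height couples to expression baseline with slope
  `peak_gene_coupling` (negative half-slope for the repressive mark);
  replicates jitter boundaries, drop peaks with probability
  1 - `presence_prob` (default 0.97) and resample counts. Fragments
  (default 90-110k per sample — CUT&Tag depths are not reported anywhere,
  so this is a package choice) are multinomial over present peaks with
  gamma (NB-like) weight noise plus a 20% genome-wide background; fragment
  totals equal the drawn library size exactly.
* **Lead/lag coupling** operates on planted log2FCs: a gene with expression
  change e at transition U gains, independently with probabilities
  `lambda_future` / `lambda_current` / `lambda_past`, a promoter-marking
  change of e at U-1 / U / U+1. Defaults 0.8 / 0.6 / 0.1: the two outer
  values are the stated experimental condition for the lead/lag recovery
  check; concurrent coupling has no stated value anywhere and 0.6 reflects
  the strong concurrent marking-expression agreement active marks show.
  The repressive mark receives sign-flipped concurrent coupling only. All
  planted marking changes land in the truth table with their offset flags.

What a green test does **not** establish: the generator has no batch or
antibody-efficiency effects, no spatial autocorrelation of signal beyond
single peaks, single-TSS genes only (unless twins are requested), uniform
fragment placement within peaks, and independence between genes given the
library size — so calibration results transfer to real data only to the
extent those assumptions do.

## Numerical choices and degenerate inputs

Grid dispersion search bounds [1e-4, ~6.3]; exact-test tie tolerance 1e-10
relative; BH ties need no special rule (step-up handles them); empty
blacklist is identity; empty peak set A makes detection overlap NA with
count 0; a constant vector makes Pearson r NA; fewer genes than bins is an
error in stratification; an empty marking universe reports zero counts and
NA fractions.

## Known limitations

The concordance analysis counts sign agreement; it is not causal inference.
Enhancer-gene links are closest-gene heuristics, not measured contacts.
The NB exact test assumes equalized libraries after TMM scaling; severe
composition shifts beyond what trimming absorbs would bias fold-changes.
Printed results of the motivating study are not reproduction targets: its
data are unreleased, and all acceptance checks are property- or
recovery-based at desk scale.
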