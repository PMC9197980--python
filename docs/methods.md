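# Methods

This note records the models, defaults, and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
design decisions taken where the design was genuinely open.

## Synthetic cohorts

The generator produces a two-chromosome, 10-Mb random genome (GC 0.42) with
a small blacklist, 400 planted 500-bp peaks spaced at least 5 kb apart, and
eight cell types: white and beige adipocytes, three immune types
(macrophage, dendritic, T cell), adipocyte progenitors, and two vascular
types. The day-0 composition mirrors whole-tissue nuclei preparations
(~22% adipocytes, ~72% immune, small progenitor/stromal fractions); under
treatment the beige share follows a monotone day trajectory
{0: 1%, 1: 1.7%, 3: 3%, 7: 5%}, taken out of the white share. The default
study design is seven groups (day-0 RT; cold and CL at days 1, 3, 7) with
three replicates.

Each peak is either "shared" (accessible in all types, probability 0.5;
30% of peaks) or owned by one type (probability 0.85 there, 0.02
elsewhere). Per cell, fragment count is log-normal(μ = 8, σ = 0.6), so the
1,000-read QC floor removes a known ~3% tail. A fragment picks a peak
uniformly at random and lands inside it with the type's activity
probability, otherwise uniformly on the genome; the in-peak fraction of a
pure type therefore converges to mean(activity row) + (1 − mean) × peak
base-pair fraction, which the tests assert. Barcode collisions pool the
fragments of two random same-sample cells under one new barcode
(cross-sample collisions cannot occur in combinatorial indexing of separate
wells). Type-specific peaks carry planted 12-mer consensus motifs written
into the genome sequence, giving motif scanning and chromVAR a ground
truth. Lipid tables are base composition + condition-specific linear day
trends + Gaussian noise, renormalised to 100%.

What the generator does **not** emulate: sequencing errors, PCR duplicates,
Tn5 sequence bias in fragment placement (footprint bias correction is
tested with a uniform-insertion null and planted protection instead),
batch effects, doublet-rate variation between wells, continuous
within-type heterogeneity, and genome-scale feature counts. Passing
benchmarks therefore demonstrate correctness of the machinery under the
stated generative model, not performance on real tissue.

### Desk-scale regimes

Two scale artifacts matter and drive deliberate parameter choices in the
benchmark runs (library defaults are unchanged):

* **Window saturation.** A 10-Mb genome has only 988 10-kb windows, so
  cells at full default depth (~3,000 fragments) binarize to near-all-ones
  window rows. Pipeline-level benchmarks (two-pass clustering,
  neighbourhood abundance) simulate at log-normal(6.5–7.0, 0.6) to keep
  window sparsity informative; stages operating on peak matrices (doublet
  detection, chromVAR) run at full depth.
* **Feature selection.** Ranking features by total accessibility and
  keeping the top 50% — the standard first step before LSI — deterministically
  discards *all* peaks of rare cell types when the peak universe is only
  ~400, because totals order by type abundance and shared peaks rank
  highest. At genome scale the same rule never removes an entire cell-type
  program. The two-pass pipeline and benchmarks therefore default to
  keeping all features (`variable_fraction = 1.0`); the embedding function
  itself defaults to 0.5.

## Matrices, embedding, clustering

Fragments are BED-like 0-based half-open records. Window/peak matrices
count whole fragments (a fragment overlapping two features counts in
both); insertion-site resolution is used only by peak calling and
footprinting. Gene activity counts fragments on the gene body extended 2 kb
upstream, strand-aware and clipped at zero.

TF-IDF: TF = count / cell total over the retained features, IDF = number of
cells / feature cell-frequency, value = ln(1 + 10⁴·TF·IDF). LSI is a
truncated SVD (ARPACK, deterministic given seed). Components with
|Pearson r| > 0.75 against log depth are excluded from downstream use —
in practice component 1, generalising the usual drop-the-first rule to
synthetic regimes where more than one component may track depth.
Clustering: exact kNN (Euclidean), SNN edge weights = Jaccard overlap of
(k+1)-neighbour sets restricted to kNN pairs (zero-weight edges are
dropped so disconnected groups stay disconnected), Leiden with RB
modularity, resolution 0.8, seeded. The pipeline runs clustering twice:
windows with components 2–25, then the merged-peak matrix with components
2–15. UMAP is used only for visualisation (random init below 10 cells).

## QC and doublet detection

FRiP = fragments overlapping the merged peak set / total fragments per
barcode; retention requires reads ≥ 1,000 **and** FRiP ≥ 0.15; a
zero-fragment barcode fails. In-silico collisions are element-wise sums
(logical OR when binary) of two distinct cells sampled uniformly; the
simulated:real ratio defaults to 0.25 — enough simulated neighbours for
resolution at k = 30 without dominating the embedding. The doublet score is
the raw simulated fraction among a real cell's 30 nearest neighbours in
the joint LSI space (no ratio normalisation), cutoff 0.2.

Before the joint embedding, `detect_doublets` equalises depth by
multivariate-hypergeometric downsampling of every profile to the
25th-percentile real depth. Rationale: within-cluster geometry at desk
scale is dominated by sampling-noise radius, which shrinks with depth, so
deep singlets are otherwise exchangeable with the double-depth simulated
doublets (false-positive rates up to 35% in the top depth quartile);
equalisation makes profile *shape* the only signal. The doublet benchmark
cohort uses equal type proportions: collisions between two cells of the
same type are undetectable in principle (a same-type pool is
distributionally identical to a singlet after depth normalisation), and a
35%-macrophage composition alone caps attainable recall near 0.75. With
balanced well-separated types the same-type share is ~12.5% and the
detector achieves precision ≈ 1.0, recall ≈ 0.76–0.83.

## Peak calling

Both fragment ends are insertion sites; each is extended to a 200-bp
pseudo-read centred on it. Candidate regions are maximal runs of per-base
coverage strictly above the genome-wide mean rate; each candidate's
p-value is the Poisson upper tail of its summit height under
λ = max(genome-wide, mean of the 10-kb window centred on the candidate),
multiplied by the candidate's width (a union bound over the bases tested —
without it, long background runs yield extreme-value false positives).
BH over candidates, q ≤ 0.05. The local-λ window is fixed at 10 kb
(single window rather than a multi-scale maximum) and no duplicate
collapsing is done at this stage (deduplication happens upstream). Merging
extends summits ±250 bp, drops blacklist overlaps (peaks overlapping a
blacklist interval are dropped, not trimmed), and unions
overlapping/bookended intervals keeping the best score's summit. On the
synthetic cohort this recovers planted peaks with precision = recall = 1.0.

## Motif machinery

PWMs come from JASPAR-format files (Biopython parser) or consensus strings.
Scanning scores log-odds against the genome base composition on both
strands; the match threshold is the score whose upper-tail probability
under the background is ≤ 5×10⁻⁵, computed by convolving discretised
per-column score distributions (10,000 grid bins) with a half-column-width
margin so discretisation cannot admit the next-lower score mass.

chromVAR-style deviations: for motif j and cell i, observed
o = Σₚ MⱼₚXᵢₚ, expected e = Tᵢ·Σₚ Mⱼₚfₚ with fₚ the peak's share of all
counts; raw deviation (o − e)/e; z-scored against 50 background sets that
replace each motif peak with a random peak from the same cell of a 10×10
GC × log-mean-accessibility quantile grid. Variability is the standard
deviation of z across cells (the reference tool's adjusted variability
differs slightly; the 1.8 module threshold is kept). Modules:
average-linkage clustering on 1 − Pearson r of z rows, tree cut to k
modules. Enrichment: one-sided hypergeometric on match counts, BH over
motifs, GC-matched background expected from the caller. Footprints:
observed mean insertion profile over ±250 bp around site centres; expected
profile from a genome-wide hexamer insertion-frequency table (insertions
per hexamer occurrence) evaluated on site sequences, scaled to the
observed flank mean (|position| > 200) and subtracted.

## Co-accessibility

Metacells are sums over a seed cell's 50 nearest neighbours, seeds
accepted greedily when sharing < 10% of members with every accepted
metacell (~n/45 metacells). Counts are log1p-normalised per metacell
total. Within 500-kb windows sliding by 250 kb, the estimator minimises
tr(SΘ) − log det Θ + Σ λᵢⱼ|θᵢⱼ| by proximal gradient with positive-definite
backtracking (ridge 10⁻³·tr(S)/p; 200 iterations; tolerance 10⁻⁵), with
λᵢⱼ = 0.1 + 0.5·max(0, dᵢⱼ − 10 kb)/window — a base sparsity penalty, as in
the reference tool's graphical lasso, plus a linear distance ramp. The
score is the partial correlation −θᵢⱼ/√(θᵢᵢθⱼⱼ) clipped to [−1, 1]; pairs
in several windows get the mean. The base penalty is set so a ~100+
metacell null zeroes small-sample noise (95% of null |scores| < 0.1)
without touching strongly co-open pairs (planted pairs score ≈ 0.96).
Entrywise monotonicity in the penalty can be violated by the changing
conditioning set; shrinkage holds in aggregate. Promoters are TSS ± 1 kb;
a distal peak (not overlapping any gene body) links to a gene when a
score ≥ 0.2 link joins it directly to a promoter-overlapping peak.

## Differential abundance

Cluster level: per-replicate proportions, one-way ANOVA across the seven
groups per cluster, Bonferroni over clusters, pairwise t-tests vs day 0
Bonferroni-corrected within cluster.

Neighbourhood level: index cells are a 10% sample refined by swapping each
to its neighbourhood's most central member and de-duplicating; a
neighbourhood is the index cell's k-ball. Counts per sample are modelled
with a negative-binomial GLM (log link, log sample-total offset, condition
covariate). Dispersion is estimated per neighbourhood by maximum
likelihood (floor 10⁻⁸) and shrunk halfway to the global mean — three
replicates per group are too few for stable per-neighbourhood estimates.
The p-value is a likelihood-ratio χ²(1) test of the condition term: the
Wald statistic collapses (p → 1) under perfect separation, which is the
generic situation for a rare expanding population whose day-0 counts are
zero, while the LR statistic remains well-behaved. Spatial FDR is weighted
BH with weight 1/(kth-neighbour distance of the index cell), significance
at 10%. Neighbourhood size matters for 3-vs-3 inference: the benchmarks
use k = 40, following the reference tool's guidance that mean
neighbourhood size should exceed ~5× the number of samples; the library
default (clustering k = 20) is kept for graph construction. Measured: null
call rate ≈ 0.003 over 20 seeds; 100% of majority-beige neighbourhoods
called positive under the planted 1% → 5% expansion.

## Pseudotime

Cells in backbone cluster k are ordered by d(x, previous centroid) −
d(x, next centroid) (missing terms dropped; ties broken by barcode), and
within-cluster ranks map uniformly onto the k-th of K equal [0, 100]
spans. This reduces to decreasing-distance-to-next-centroid ordering at
the backbone ends and makes backbone reversal map t to exactly 100 − t; a
single cluster orders by distance from its own centroid. Feature dynamics:
cells binned into 100 pseudotime-quantile bins, per-bin means, centred
11-bin moving average (edge-padded), empty bins linearly interpolated,
rows ordered by smoothed argmax with constant features last. TF coupling:
Pearson r between smoothed gene and motif profiles, BH adjustment;
positive regulators need r ≥ 0.5 and adjusted p < 0.05. Smoothing inflates
autocorrelation, so the r-threshold carries the null control: the measured
null pass rate is ~3.5% at 100 bins.

## Interactions

Probability(s, r, pair) = mean normalised ligand accessibility in sender ×
receptor mean in receiver, with multi-subunit receptors aggregated by
geometric mean (a receiver missing any subunit scores ~0). Accessibility
is a proxy for expression, so the reference tool's Hill-type
response curves are deliberately omitted in favour of a monotone statistic
whose inference comes entirely from the cluster-label permutation null:
p = (1 + #{permuted ≥ observed})/(1 + n_perm), n_perm = 100, significant
at p < 0.05, clusters under 3 cells excluded.

## Lipidomics

Species parse as C:Dn-x (saturated species omit the n-x suffix). Rows
renormalise to 100 (warning beyond 1% off). Elongation and desaturation
ratios are quotients of species shares, hence invariant to the
normalisation. SFA/MUFA/PUFA partition by double-bond count (0 / 1 / ≥2);
UFA:SFA = (MUFA + PUFA)/SFA. Group statistics: one-way ANOVA per species
across the seven groups with Bonferroni over species and day-0 post-hoc
comparisons; Welch's unequal-variance t between cold and CL at matched
days; slope comparison by OLS of metric ~ day × treatment on treated days
1–7, tested on the interaction coefficient (antisymmetric in treatment
labelling by construction).

## Known limitations

* The peak caller is a deterministic re-implementation of the
  shift/extend + local-Poisson idea, not a numerical clone of MACS2
  (single 10-kb local window, union-bound candidate p, no model-based
  fragment-size estimation).
* Co-accessibility uses a penalised partial-correlation estimator rather
  than the reference tool's exact sampling procedure; scores agree in sign
  and ranking on planted structure but are not numerically comparable.
* The NB dispersion shrinkage target (global mean, weight 0.5) is cruder
  than trended empirical-Bayes shrinkage; with more replicates a trend fit
  would be preferable.
* Synthetic cells are conditionally i.i.d. within type; none of the
  benchmarks probe continuous within-type variation, batch structure, or
  depth-activity confounding beyond the log-normal depth model.
* Footprint bias correction assumes hexamer context is the only insertion
  bias and that flanks (|pos| > 200 bp) are signal-free.
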