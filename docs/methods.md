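# Methods

`modoc` implements the computational chain that links time-course
co-expression modules to transcription-factor (TF) occupancy and epigenetic
state during B-cell to plasmablast differentiation: a parsimonious
correlation network and its modules, hypergeometric signature enrichment,
peak-centre overlap clustering and promoter assignment, K-means regulatory
clusters over ±1-kb signal matrices, and the module × occupancy integration
matrix.  Every stage is exercised end-to-end against a synthetic generator
that plants known structure, so recovery can be scored exactly.

## Co-expression network and modules

Expression input is a gene × sample matrix of log2 intensities from a
differentiation series (by default 8 time points × 3 donors).  Genes are
ranked by variance across all samples and the top fraction (default 0.5) is
retained as informative; variance ranking is a simple, defensible proxy for
"informative" and is exposed as a parameter rather than claimed to be the
only possible rule.

For the retained genes, Spearman's rank correlation is computed for all
pairs.  Each gene keeps only its `retained_per_gene = 3` most correlated
partners — ranked by **signed** ρ, not |ρ| — and the union of these directed
picks is symmetrised into an undirected weighted graph.  Signed ranking
reflects that co-expression modules are positively co-regulated groups with
coherent kinetics; ranking by |ρ| is available by pre-transforming the
matrix if anti-phased modules are ever of interest.  Ties in the per-gene
ranking break on lexicographic partner id so the network is deterministic.

Modules are detected by Leiden community detection maximising Newman
modularity, run `n_iterations = 100` times with distinct sub-seeds; the
partition with the highest modularity Q is kept.  Edge weights are clipped
at zero for the modularity objective (a negative correlation, possible when
a gene lacks three positive partners, should not pull nodes together).
Per-gene **stability** is the fraction of iterations in which the gene lands
in the same community as the plurality of its final module's members — a
reproducible score in [0, 1] mirroring the per-gene stability column of the
published module tables.  Modules are relabelled by decreasing size, with
ties broken by smallest member gene id.

Module kinetics: per gene, z = (x − mean)/SD across all time-course samples;
per (module, time point) the summary profile is the median z over member
genes and donors.  A module is classed *early-off* if its profile peaks at
the first time point, *late-on* if at the last, *transient* otherwise.

## Hypergeometric signature enrichment

For universe size N (all network genes), signature size K (after
intersection with the universe), module size n and overlap k:

    E  = nK/N
    SD = sqrt(n (K/N)(1 − K/N)(N − n)/(N − 1))
    z  = (k − E)/SD

The probability is the one-sided hypergeometric tail on the observed side:
P(X ≥ k) when k ≥ E, P(X ≤ k) otherwise, so negative z marks significant
depletion.  Benjamini–Hochberg correction is applied jointly across all
(set, module) rows of a run; a per-module family is available behind the
same interface.  Degenerate cases (K = 0, K = N, n = 0, n = N) emit z = 0,
p = 1 and a `degenerate` flag rather than NaNs.

A caveat this package documents explicitly: because the reported p covers
only the observed tail, it is **not** uniformly distributed under the null —
in the continuous limit P(p ≤ α) approaches 2α, since either tail can
trigger.  For sparse signatures (K ≪ N), tail discreteness keeps the rate
near α; the null-calibration test and acceptance script therefore measure
calibration in that regime (set sizes log-uniform 10–200 against a
2,000-gene universe), which is also where curated signature collections
live in practice.

Heat-map filtering follows the published display convention: FDR < 0.05,
signature size within [5, 1000], then the 15 smallest-p signatures per
module; ties break on p, then |z| descending, then set name.

## Peak tools

All intervals are 0-based half-open; a peak's centre is floor((start+end)/2).

**Overlap clustering.**  Peaks pooled across factors are scanned per
chromosome in ascending centre order; the first unassigned peak opens a
cluster and is its *index*, and subsequent peaks are absorbed while
centre − index_centre < 250 bp.  The distance is anchored at the index peak,
not chained to the last absorbed one — chaining would allow unbounded
clusters.  Nearby peaks of a single factor can merge into one cluster, so
per-factor cluster totals may differ slightly from raw peak counts; the
discrepancy is logged.  Venn partitions count clusters by occupancy
signature, and a factor's shared fraction is shared clusters over its raw
peak count.

**Genomic location.**  Strand-aware windows on the peak centre: Promoter =
TSS − 1 kb … TSS + 100 bp, terminator (TTS) = TES − 100 bp … TES + 1 kb,
mirrored on the minus strand.  Precedence Promoter > TTS > Genic >
Intergenic makes the classes mutually exclusive (a rule is required for
short genes whose windows overlap; promoter wins).  Without exon annotation
the intragenic class is reported as `Genic`.

**Peak-to-gene assignment.**  A peak is assigned to gene g iff its centre
lies within 10 kb of g's TSS and no other TSS falls strictly between; this
reduces to the nearest TSS on each side of the centre (both genes retained
when TSSs coincide), so a peak can be assigned to at most one gene per side.
Distances are measured from the peak centre, consistent with the
centre-based clustering geometry.

## Regulatory clusters

Union regions are the consensus centres (member-centre medians) of the
overlap clusters.  Coverage input is stepwise bedGraph tracks — fragment
extension is an upstream, read-level concern; the generator emits
already-extended coverage.  Each track is rescaled to a fixed total genomic
mass (1e6 signal·bp, a counts-per-million-style normalisation, switchable
off) and averaged in 50-bp bins over ±1,000 bp around each region centre
via an exact cumulative-integral query (windows off a chromosome edge are
zero-filled with a warning).

For clustering, each track's sub-matrix is z-scaled before concatenation so
no single track dominates by dynamic range; raw means are kept for display.
K-means (default k = 6, `n_init = 10`, seeded) labels are re-ordered by
decreasing total mean raw signal so K1 is always the most active archetype
and labellings are comparable across seeds.  Per-cluster occupancy is the
percentage of a factor's union regions falling in each cluster (columns sum
to 100 per factor present).

## Integration

Occupancy gene sets — `<TF>.All` per factor and `U.K1…Kk` per regulatory
cluster (with `U.All` their union) — are built from the 10-kb assignment and
tested against the expression modules with the same hypergeometric
machinery, universe restricted to network genes.  In the displayed matrix,
z values with p > 0.05 are zeroed and values are clipped to ±5; the raw
matrix is retained.  The zeroing threshold uses the raw p by default, with
an FDR-based switch, because the display convention and the tabulated FDR
column are legitimately different families.

Differential expression between two conditions is a paired two-sided t-test
on log2 values across donors (the simplest defensible design for three
donors; pluggable), with BH FDR and a fold-change ladder at
{1.2, 1.4, 1.6, 1.8, 2.0}: a gene counts at a rung if FDR < 0.05 and
|log2FC| ≥ log2(rung) (minus a 1e−9 guard so an exactly k-fold change is not
lost to floating-point rounding).  Ladder counts are non-increasing in the
rung by construction.  The dumbbell summary runs two enrichments (up set,
down set) against the modules and ranks modules by z_up − z_down.

## Synthetic generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

* **Expression**: 2,000 genes, 8 planted modules of 100 genes, 3 donors,
  8 time points (D0, D3, then 3 h–72 h after the transition).  Each module
  draws a piecewise-linear kinetic template (early-off / transient /
  late-on, cycled) plus module-level jitter (SD 0.25) so same-class modules
  remain separable; member genes share the profile scaled by a gene-level
  amplitude (3.0 × U(0.7, 1.3) on the log2 scale), a N(7, 1) baseline, a
  per-(gene, donor) offset (SD 0.2) and i.i.d. N(0, 0.5) noise.  Background
  genes are baseline noise.  Amplitude ≫ noise mirrors array-scale dynamic
  ranges where differentiation programs swing several log2 units.
* **Signatures**: one planted set per module at a requested Jaccard
  (default 0.5) plus uniform decoys with log-uniform sizes 20–300.
* **Genome and peaks**: genes every 40 kb on 4 chromosomes, alternating
  strand, lengths 2–8 kb, so intergenic midpoints are provably > 10 kb from
  every TSS.  Each factor places 60% of its peaks inside promoter windows
  of genes sampled from its target modules (at most one peak per gene; the
  10-kb rule then recovers exactly the planted genes) and the rest at
  jittered intergenic midpoints.  Co-occupancy adds partner-factor peaks
  within ±100 bp (inside the 250-bp clustering distance) for a configured
  fraction of a factor's peaks.
* **Tracks**: each union region is assigned one of three archetypes
  (active promoter: strong bimodal H3K4me3/broad H3K27ac; CTCF-bound: sharp
  CTCF only; inactive: flat low) and every track receives the archetype's
  bin template plus truncated Gaussian noise (SD 0.3), rasterised on a
  50-bp grid with overlaps resolved by maximum.

Each artefact (expression, signatures, genome, peaks, tracks) draws from its
own RNG stream derived from the master seed, so regenerating one component
leaves the others untouched.

**What the generator does not emulate**: array normalisation artefacts,
batch effects, correlated noise between modules, realistic peak width and
fragment-length distributions, copy-number or mappability biases, and
replicate-level ChIP variability.  Passing recovery tests therefore show
the chain is implemented correctly and is sensitive at realistic
signal-to-noise, not that it would reach the same counts on any particular
real dataset.

## Numerical choices and problem sizes

* Hypergeometric tails come from `scipy.stats.hypergeom` (`sf`/`cdf`); tests
  check them against direct pmf summation with exact integer combinatorics
  to 1e−9 over randomised grids up to N = 2,000.
* Reported modularity is recomputed from the Newman definition in the test
  suite and must agree to 1e−9.
* K-means uses scikit-learn with `n_init = 10`; determinism is by seed.
* Default analysis sizes (2,000 genes, ~1,000 network genes, ~1,100 union
  regions, 100 Leiden iterations) keep a full pipeline run to a few seconds
  on one CPU while leaving module- and archetype-recovery non-trivial.

## Known limitations

* The observed-side tail convention means pooled p-values are conservative
  per tail but not uniform; see the calibration note above.
* The informative-gene rule is variance ranking; other definitions (e.g.
  expression-level filters) are not implemented.
* Exon/intron subdivision of genic peaks requires exon annotation, which the
  synthetic genome does not carry; the class is reported as `Genic`.
* A peak equidistant from two TSSs (or two genes sharing a TSS position) is
  assigned to both; this choice is deterministic but arbitrary.
* Community detection restarts share one graph; very large networks would
  want sampled-edge perturbation per iteration, which is not implemented.
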