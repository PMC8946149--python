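# Methods

This note documents the models, conventions and parameter choices behind
`ocstrat`, what the synthetic cohort generator does and does not emulate,
and the numerical decisions a maintainer would want written down.

## Coordinates and variant handling

All coordinates are 1-based inclusive (VCF convention); BED-style inputs
must be converted at the reader boundary. Only PASS VCF records are
consumed; multiallelic records are split into one variant per ALT, and
exact duplicates are dropped with a warning. Variant classes derive from
allele lengths after shared-prefix/suffix trimming: equal length 1 = SNV,
equal length ≥ 2 = MNV, otherwise insertion or deletion. MNVs longer
than 2 bp count toward mutation totals (TMB) but are excluded from
doublet (DBS-78) classification, which is defined only for dinucleotides;
length-2 MNVs count once toward TMB and once in the DBS spectrum. The
purity filter keeps samples with tumor purity strictly above the
threshold (default 0.20). Whether subclonal variants should be excluded
is left to the caller; all PASS somatic records are used.

## Mutation-context schemes

**SBS-96.** Substitution class (C>A … T>G) × 5′ × 3′ flank, pyrimidine-
centred: purine-reference SNVs are reverse-complemented including flanks.
SNVs whose flank is N or off-contig stay in totals but leave the SBS-96
vector (with a warning).

**DBS-78.** Ten canonical reference doublets (AC, AT, CC, CG, CT, GC,
TA, TC, TG, TT); a non-canonical reference doublet is reverse-
complemented together with its ALT, and for palindromic references (AT,
CG, GC, TA) the lexicographically smaller of ALT/revcomp(ALT) is the
representative. The unit tests enumerate all 144 doublet substitutions
and confirm they canonicalize onto exactly 78 keys.

**ID-83.** The indel scheme follows the COSMIC ID-83 structure —
1 bp events by homopolymer length, longer events by tandem-repeat copy
number, deletions additionally by flanking-microhomology length — with
SigProfiler-like text labels (`1:Del:T:5`, `3:Del:M:2`, `2:Ins:R:1`).
Conventions: homopolymer length for a 1 bp deletion includes the deleted
base (bins 1–6+); insertion homopolymer length is the adjacent run (0–5+);
repeat copies for deletions include the deleted copy (so `R:1` means a
unique, non-repeat, non-MH deletion); microhomology is the longer of the
common prefix with the following sequence and the common suffix with the
preceding sequence, capped at size − 1 and at the COSMIC bin edges.
Deletions are assigned repeat > microhomology > unique, in that priority.
Indels at contig edges where flanks are unavailable fall into the
non-repeat bins. Catalogs supplied in other ID label dialects must be
mapped to these labels; the packaged catalog already uses them.

**SV categories.** DEL/DUP/INV/INS split at 10 kb span (`< 10000` short,
`≥ 10000` long); interchromosomal breakends are translocations by
definition and form a single TRA bucket (span undefined), giving nine SV
features. Insertions are split at 10 kb like the other types even though
long insertions are rare; this keeps the category grid regular.

## Ploidy, WGD, TMB

Ploidy fractions are segment-length weighted with the diploid band the
closed interval [1.5, 2.5]; below is haploid, above polyploid (the band
edges themselves count as diploid). WGD is called when the
length-weighted mean major-allele ploidy exceeds 1.5 in more than 10
autosomes; length-weighting is the natural per-autosome summary for
PURPLE-like segment input (the summary statistic is otherwise
unspecified, so it is fixed here and documented). TMB divides total
SNV + MNV + indel counts by the mappable GRCh37 length
2,858,674,662 bp / 10⁶; the constant is a reporting convention retained
even for the 22-Mb toy genome so that TMB values are comparable across
runs.

## Signature refitting

The refit minimizes the least-squares reconstruction error of the count
vector over non-negative signature contributions. The optimiser is
cyclic coordinate descent; each coordinate is solved by golden-section
line search on [0, Σcounts] (the coordinate objective is unimodal), with
a line tolerance of 10⁻¹⁰ × max(Σcounts, 1) and a sweep-level stop when
the objective improves by less than `tol` (default 10⁻⁶) relative to
max(1, objective). Because the problem is convex, the optimum coincides
with non-negative least squares; the tests verify agreement with scipy's
NNLS within 10⁻⁴ relative objective on random 20-signature × 96-context
instances. Contributions are absolute mutation counts; reconstruction
quality is reported as the cosine between observed and reconstructed
vectors (defined 0 for an all-zero input). Refitting is scale-
equivariant and its objective non-increasing across sweeps.

Cohort-level selection refits all samples with the full catalog, ranks
signatures by summed contribution, re-runs with shrinking top-k subsets
(about `max_iters` = 8 runs), and keeps signatures contributing at least
`min_contrib_frac` = 0.05 of a sample's mutations in at least
`min_sample_frac` = 0.10 of samples in every run where they appear. The
thresholds quantify "consistent contribution in a high number of
samples" and are configurable; an empty selection raises with advice to
loosen them.

## HRD proxy

Two feature fractions: microhomology deletions / all indels (f_mhdel)
and 1–100 kb duplications / all SVs (f_shortdup), both 0 when their
denominator is 0. Deficient iff f_mhdel ≥ 0.10 or f_shortdup ≥ 0.25;
the short-duplication phenotype maps to BRCA1-type, otherwise
BRCA2-type. The thresholds are invented, chosen to sit well above the
background of HR-proficient genomes and well below HRD genomes under the
generator defaults; the BRCA1/BRCA2 direction follows the association of
tandem-duplication phenotypes with BRCA1 loss. This proxy deliberately
trades the accuracy of a trained classifier for transparency; it is not
CHORD and its calls on real cohorts are not comparable.

## Feature matrix and clustering

24 features per sample: 6 SNV substitution-class counts, total DBS
count, 5 collapsed indel families (repeat-context insertions/deletions,
microhomology deletions, other insertions/deletions — 1 bp homopolymer
events count as repeat context), 9 SV categories, 3 ploidy fractions.
Absolute counts are used (with the ploidy fractions as-is); a DBS-by-
class variant would be a one-line change in `feature_columns`. Dependent
blocks (SNV6, indel families, SV categories) are centred and scaled by
the pooled mean/SD of the whole block so that, e.g., a uniformly 10×
larger C>T column stays larger after normalization; singletons are
z-scored; zero-variance columns/blocks map to zeros.

Distance is 1 − Pearson correlation between normalized rows (range
[0, 2]; not a metric — the triangle inequality is not asserted).
Agglomeration implements the classic **ward.D** convention: the Ward
Lance–Williams update applied to the distances as given, *without*
squaring — as distinct from ward.D2. Ties merge the lowest-index pair.
On non-Euclidean dissimilarities ward.D can produce height inversions,
so trees are cut by merge order (apply the first n − k merges), which is
exactly R `cutree` semantics and independent of heights. The tests
cross-check the implementation against scipy: scipy's `ward` applies the
recursion to squared inputs and reports square roots, so running it on
√d reproduces ward.D heights on d after squaring.

Bootstrap stability resamples features (columns) with replacement B
times (B ≥ 100, default 200), reclusters, and reports per original
cluster the fraction of replicates containing a cluster with Jaccard
≥ 0.75 to it. This is an ordinary bootstrap probability — a deliberate
simplification of pvclust's multiscale "approximately unbiased"
p-values; at these cohort sizes the 0.95 stability screen used to pick k
behaves the same under either. Replicates whose resampled columns leave
a row with zero variance fall back to a guarded correlation (r = 0 for
flat rows). k is always a user decision; `suggest_k` reports stability
and PCA cumulative-variance curves but never chooses.

## Clinical derivations

CR/PR = favorable, SD/PD = poor, NA = missing; clinical progression
without imaging should be coded PD upstream. PFI is the time from the
last platinum stop date to the first subsequent recurrence, binned at
183 days for the six-month boundary; missing platinum or recurrence
gives NA, and a recurrence strictly before the platinum stop is a data
inconsistency that raises. One-year survival excludes patients censored
alive before day 365 from numerator and denominator so that reported
x/y count pairs are exact; the Kaplan–Meier estimator (lifelines) is the
principled alternative and is also provided. Percentages round to the
nearest integer, half away from zero. Group comparisons use the
Wilcoxon rank-sum test with Bonferroni correction by the stated family
size. The drug → class mapping (chemo/targeted/hormonal/immuno, plus a
platinum flag) ships as an editable TSV.

## Actionability

Evidence levels: A = validated association, B = clinical evidence; each
entry is on- or off-label. Hotspot events satisfy both hotspot-specific
and any-mutation entries; plain mutations satisfy only any-mutation;
copy-number and fusion classes match exactly. Entries flagged standard
of care never match. The per-sample best tier uses the total order
A-on > A-off > B-on > B-off; adding evidence can only improve it.
Multi-drug matches count as unique (gene, drug, level, label) entries.
The packaged table is a small synthetic fixture covering KRAS, NF1,
PIK3CA and negatives; fuller database exports can be dropped in.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not real genomes. The reference is 22 uniform-random 1-Mb autosomes
(GC ≈ 0.5); the reference has its own seed (default 0) because the
genome is a fixed quantity across cohorts, and the built k-mer indexes
are cached. Per archetype: mutation loads are negative binomial
(overdispersed; dispersion ~10–40), SNV contexts are drawn from the
archetype's signature mixture and placed at genomic positions whose
trinucleotide matches (half on each strand, exercising pyrimidine
normalization); indels are constructed to literally realize their
category family and verified with the production classifier (rejection
sampling, 1000-try cap); SV spans are log-normal around per-type modes
(the duplicator archetype's DUP mode is 231 kb); copy-number segments
are drawn so the WGD flag is decided by construction (per-autosome major
ploidy clipped to ≥ 1.7 for WGD archetypes, ≤ 1.45 otherwise); gene
events are Bernoulli with optional mutual-exclusivity pairs (KRAS/TP53
in the repeat archetype); survival is exponential (rates 4×10⁻⁴ to
2.2×10⁻³ per day by archetype) with uniform censoring on [200, 1500]
days.

Default cohort: 120 samples across HRD-diploid (17), HRD-WGD (25),
genome-stable (20), long-duplicator (11), mixed (15), aging (14),
repeat/C>T (18) — cluster sizes chosen to mirror the subgroup sizes the
method is meant to resolve. Mean SNV loads run from ~550
(genome-stable) to ~9000 (HRD-WGD); these desk-scale loads keep the
qualitative contrasts (HRD clusters mutation- and SV-rich, stable
cluster quiet) without claiming any real cohort's absolute numbers.

What the generator does **not** emulate: chromatin- or replication-
timing-dependent mutation rates, kataegis, subclonal structure, purity
effects on variant detection, germline variation, realistic karyotypes,
or inter-feature correlations beyond the archetype means. Passing tests
therefore demonstrate that the pipeline recovers planted structure of
the kind described, not that it would resolve any particular real
cohort.

## Problem sizes and tolerances in the test suite

The acceptance-style tests run at: 10 cohorts × 120 samples for
archetype recovery (mean adjusted Rand index ≥ 0.90 over 10 seeds); 100
random 20 × 96 instances for refit/NNLS agreement (10⁻⁴ relative); 50
samples × 10,000 SNVs for signature closure (cosine ≥ 0.95 per sample);
60 + 60 samples for HRD sensitivity/specificity (≥ 0.95 each); n = 500
for the Kaplan–Meier versus analytic exponential check (truth inside the
Greenwood 95% CI); spectrum convergence at 20,000 SNVs (total-variation
distance < 0.05). These sizes were chosen as the smallest at which the
corresponding statistics are stable.

## Known limitations

* The HRD proxy is a two-threshold rule, not a trained classifier.
* ward.D on 1 − r dissimilarities is a convention, not a guarantee of
  monotone trees; merge-order cutting sidesteps but does not remove
  height inversions.
* Bootstrap probabilities are plain BP values, biased relative to
  multiscale AU p-values for small, tight clusters.
* The one-year-survival exclusion convention differs from the KM curve
  when early censoring is heavy; both are reported.
* Signature selection assumes the catalog is well conditioned; highly
  collinear catalogs (e.g., several flat signatures) will trade
  contributions between near-duplicates.
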