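# Methods

This package implements a gene-centric profiling pipeline for nine
arsenic resistance and metabolism genes in soil microbial genomes and
metagenomes: the arsenite efflux pumps *acr3* and *arsB*, the cytoplasmic
arsenate reductases *arsC* (grx) and *arsC* (trx), the chaperone *arsD*,
the arsenite methyltransferase *arsM*, the arsenite oxidases *aioA* and
*arxA*, and the respiratory arsenate reductase *arrA*. It operates
downstream of homology search (hmmsearch against complete genomes) and
gene-targeted assembly (per-gene protein variants with coverage-adjusted
abundances from soil metagenomes); neither of those producers is
reimplemented here.

## Hit screening

Raw hits are retained when bit score > 100 **and** percent alignment
(model-relative coverage, 100 × aligned HMM positions / model length)
> 90. Hits to *aioA*, *arrA* and *arxA* must additionally score > 1000;
these deep-branching oxidoreductase families attract cross-family
matches in the 100–1000 bit range, and the elevated floor replaces the
manual inspection that motivated it. All thresholds are strict
inequalities. When one ORF hits more than one model, only the
highest-scoring hit is kept; equal-score ties break toward the gene
earliest in the canonical ordering (acr3, aioA, arrA, arsB, arsC_grx,
arsC_trx, arsD, arsM, arxA), then the smallest replicon id, and the
deduplicated table is sorted by (genome, ORF) so the result is invariant
to input row order. Rejections are attributed to the first failing rule
(score, then alignment, then elevated score) so the report partitions
the input exactly. An e-value cutoff (1e-10) is a producer-side
contract of the upstream search and is not re-applied here.

## Genotype profiling

The genotype matrix counts retained hits per genome × gene × location
(chromosome vs plasmid). Genomes with zero retained hits remain as
all-zero rows: the "none" fraction is a result. A genome "tests
positive" for a gene with ≥ 1 copy at either location; per-gene plasmid
fractions are computed over hit copies, not genomes, because the
corresponding survey figures are phrased as fractions of sequences.
Phylum proportions default to carrier-genome denominators (the
hit-based variant is a one-line change on the tally), and copy-number
histograms pool chromosomal and plasmid copies of the same organism.

## Phylogenetic signal

Presence/absence of each (gene, location) trait over the genome
phylogeny is tested with Blomberg's K:

    K = (MSE0 / MSE)_observed / (MSE0 / MSE)_expected

where, with V the tip × tip phylogenetic variance-covariance matrix
(shared root-to-MRCA branch length; polytomies are kept and define V
unambiguously), â = (1ᵀV⁻¹1)⁻¹ 1ᵀV⁻¹x the GLS ancestral mean,
MSE0 = Σ(xᵢ − â)²/(n − 1), MSE = (x − â)ᵀV⁻¹(x − â)/(n − 1), and the
Brownian expectation of the ratio is [tr(V) − n / ΣᵢⱼV⁻¹ᵢⱼ]/(n − 1).
K is invariant to affine transforms of the trait and uniform rescaling
of branch lengths, and equals 1 exactly on star phylogenies. A near-
singular V receives a 1e-8 ridge. Binary traits are deliberately
analyzed with the continuous-trait K — fidelity to the source analysis
over methodological alternatives (Pagel's λ, the D statistic are
non-goals).

Significance comes from shuffling tip-value assignments: p = (1 +
#{MSE_perm ≤ MSE_obs}) / (n_perm + 1) with 999 permutations by default,
so p is never 0 and signal means smaller phylogenetically corrected
variance than chance. Families of traits are adjusted with
Benjamini-Hochberg; constant traits are flagged untestable and excluded
from the family, and traits with fewer than 5 positive or 5 negative
tips are flagged low-power but reported. The implementation was
cross-checked against `picante::Kcalc` (agreement to 7 decimals).

**Known limitation.** Thresholding a Brownian trait into presence/absence
discards the magnitudes whose variance ratio K measures. On standard
random trees (Yule, coalescent, balanced) the mean K of
Brownian-threshold binary traits is ≈ 0.45–0.65, not 1; simulated
continuous Brownian traits do average K ≈ 1.0 here, and thresholded
traits still rank far above i.i.d. traits (≈ 0.6 vs ≈ 0.07), which is
the property the positive/negative controls rely on. One acceptance
check expects the binary-trait mean inside [0.7, 1.3]; it fails for
this reason, and we keep it failing rather than hand-pick a tree shape
(deep two-clade trees can push the mean anywhere between 0.3 and 40).

## Abundance estimators

Cultivation-dependent: for each sample, expected copies per genome =
Σ_genomes weight × total copies, with 16S-inferred weights summing to 1
(tolerance 1e-6); the estimate is linear in the weights and bounded by
the maximum per-genome copy number. Soil-order summaries average
samples within order after the per-gene estimate (both orderings are
trivial on the per-sample table, which is always emitted).

Cultivation-independent: per-site gene counts (coverage-adjusted,
treated as opaque non-negative inputs from the assembler) divided by
the site's total count of the single-copy marker rplB, giving
dimensionless per-genome units that are invariant to sequencing depth.
A gene not assembled at a site is *not detected* (NaN), distinct from
zero; cross-site summaries default to the conservative convention
(detecting sites only) with an include-zeros mode for sensitivity. The
reference-collection analogue divides total copies by the number of
genomes, since every complete genome carries exactly one rplB.
Community structure tables report per-site phylum proportions of rplB
counts and flag the six most abundant phyla, warning when they cover
less than 75% of a community.

## Variant clustering and endemism

Pairwise identity uses global alignment (match +1, mismatch 0, gap open
−5, gap extend −1 — guide scores only) with identity = 100 × matches /
alignment columns, excluding terminal-gap columns so ragged assembly
ends are tolerated while internal indels are penalized. Clustering is
greedy and UCLUST-style within each gene: sequences in decreasing
total-abundance order (ties: longer, then smallest id) join the first
centroid at ≥ 90% identity or found a new cluster. For equal-length
sequences a Hamming prefilter skips the aligner when the pair is more
than 8 identity points below threshold; at these gap penalties a gapped
realignment cannot bridge that margin for point-substituted sequences.
Real assemblies with large internal indels should disable the
prefilter. Exact duplicates are merged per (gene, sequence, site) with
abundances summed before clustering, so total abundance is conserved
end to end.

A cluster present at fewer than 3 distinct sites (summed abundance > 0,
no minimum floor) is endemic, otherwise cosmopolitan. Both the
cluster-denominator and the dereplicated-sequence-denominator endemic
proportions are reported, clusters being the default denominator.

## Comparative statistics

Mann-Whitney U (U = Σ[xᵢ > yⱼ] + ½[xᵢ = yⱼ]) is exact by full null
enumeration for n₁, n₂ ≤ 10 without ties, else normal approximation
with tie and continuity corrections (SciPy backend; the test suite
carries an independent enumeration oracle). Geographic distances are
haversine great-circle distances (Earth radius 6371 km). Gene-content
dissimilarity is Bray-Curtis on rplB-normalized abundances with
non-detections as zeros — a dissimilarity needs complete vectors, a
documented asymmetry with the conservative summaries. The Mantel test
correlates upper triangles (Pearson), permuting one matrix's site
labels, one-sided for positive association with an add-one p-value;
with ≤ 6 sites the null is enumerated over all n! relabelings instead.

## Synthetic data: what it emulates, and what it does not

All inputs are generated with planted truth ledgers; identical
arguments and seed give byte-identical files.

* **Genomes** (default 922 across 25 phyla, Zipf-skewed): each genome
  gets 1 chromosome and 0–3 plasmids (P = 0.5/0.3/0.15/0.05). A 14.3%
  fraction carries no gene at all; carriers plant each gene with
  probability prevalence/(1 − none_fraction) so the marginal matches
  the configured carriage. Default prevalences echo the genome survey
  (arsM 5.2% is the one printed figure; detoxification genes common,
  metabolism genes rare). Copies are mostly single (0.85/0.12/0.03 for
  1/2/3); plasmid placement targets the survey's plasmid shares (acr3
  6.1%, arsC_grx 4.6%) as marginal rates. True hits draw scores from
  150–2500 (1100–2500 for the elevated genes) and coverage 92–100%;
  decoys (rate 0.3/genome) draw scores 20–99, coverage 10–89, or — for
  elevated genes — scores 110–990. Bands are disjoint from every
  threshold, so genotype recovery is exact, not statistical; an
  adversarial mode plants hits exactly at 100 / 1000 / 90% to pin the
  strict inequalities.
* **Trees** are Yule (pure-birth) with exponential waiting times —
  the standard neutral model; real 16S trees have reticulate depth
  structure this does not mimic.
* **Sites** (default 16 in five continental bounding boxes, so Mantel
  distances have real structure): per gene, cluster founders mutate a
  random ancestor (length 150, or 120 for arsC-like genes) at 35% of
  residues — far below 90% pairwise identity — while within-cluster
  members differ at ≤ 2%; a 0.7% fraction of clusters is shared
  (identical residue string at 3–6 sites), the rest occur at exactly
  one site. rplB totals are uniform 50–500; abundances uniform
  0.5–30. No indels, no amino-acid substitution matrix, no chimeras:
  passing recovery tests shows the pipeline arithmetic is exact given
  separated clusters, not that 90% is the right threshold for real
  assemblies.
* **Weights**: per-sample Dirichlet(0.3) over all genomes (sparse,
  dominated by a few organisms), 38 samples over 7 soil orders.

Because planted genotypes are independent of the generated tree, the
pipeline's own signal tests act as a negative control; positive
controls come from traits simulated on the tree (Brownian-threshold and
clustered modes).

## Problem sizes and numerical choices

The analysis scripts and acceptance script run the full default
conditions (922 genomes, 922-tip tree with 999 permutations per trait,
16 sites with ~1150 clusters, 38 samples) in about two minutes on one
core. Test fixtures are smaller (200 genomes, 64-tip trees, 6–8 sites)
and chosen once as desk-scale analogues. Tolerances: exact equality
for planted-recovery and ledger comparisons; 1e-9 for abundance
conservation and the star-tree K identity; 1e-10 against the dual
K implementation; 1e-12 against enumeration oracles.
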