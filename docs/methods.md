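# Methods

This note documents the statistical machinery implemented in `palmspec`,
the assumptions behind the synthetic-data generator, and the numerical
conventions used. It states no empirical result beyond what the test suite
and `scripts/acceptance.py` themselves compute.

## Duplicate removal (`palmspec.dedup`)

Paired-end mates are concatenated (sequence and quality strings alike) and
compared position-wise. Two concatenations of equal length are duplicates
when the number of mismatching positions at which **both** bases have
Phred quality ≥ `qual_floor` (default 7) is at most
`max(1, floor(L · mismatch_rate))` with `mismatch_rate = 1/200`. The floor
with a minimum of one generalizes the one-mismatch-per-200-bp rule
conservatively to read lengths other than 2×100 bp. Mismatches involving an
N are ignored: an uncalled base carries no evidence of difference. Reads of
unequal length are never duplicates.

Duplicate pairs are clustered by **single linkage** (pairwise duplicate
identification alone does not define retention; transitive closure does).
One read pair per cluster is retained: the one with the highest mean
quality over both mates, ties broken by read id ascending bytewise so the
result is deterministic.

Candidate search is all-pairs within equal-length groups. This is exact and
entirely adequate at the scales the package targets. A fast approximate
mode (`bucket=True` / `--bucket`) additionally partitions each length group
by the first 16 bases of the concatenation; it can split a true family when
an allowed mismatch falls inside that prefix, which is why it is not the
default. A prefix restricted to *high-quality* positions was considered and
rejected: which positions qualify depends on each read's own quality
string, so family members need not agree on the key.

## Population genetics (`palmspec.popgen`)

Genotypes are biallelic-site × diploid-individual dosage matrices with
species labels. Filtering mirrors a VCFtools pass: genotypes with GQ < 20
or DP < 3 are set missing; sites with QUAL < 20 (when present), pooled
minor-allele frequency < 0.1 (computed over non-missing alleles of both
species together, matching one filtering pass over a joint call set), or
call rate < 0.7 are dropped.

Diploid genotypes are expanded to 2n allele samples for the sequence
statistics:

* π per site: Σ<sub>sites</sub> 2p̂q̂·n/(n−1) divided by gene length
  (the unbiased pairwise-difference form; verified against explicit
  enumeration of allele pairs in the tests).
* Tajima's *D* with the standard a₁…e₂ constants.
* Fu & Li's *D*\* and *F*\* in the **outgroup-free (starred)** form, using
  within-sample singleton counts (sites whose rarer allele occurs in
  exactly one sampled allele). No outgroup sequence exists in this design,
  so the starred variants are the defensible choice. The variance constants
  follow the corrected formulation in general use in popgen libraries (the
  original publication's constant sheet contains known typos); the tests
  cross-check them against an independently coded sheet.
* *F*<sub>ST</sub>: Weir–Cockerham θ as a ratio of sums of the a, b, c
  variance components across sites, skipping sites monomorphic in the
  pooled sample. Slightly negative estimates are reported as-is, not
  clamped. θ = 1 exactly when every usable site is a fixed difference with
  no within-species variation.
* *D*<sub>xy</sub> per site: (1/L) Σ [p_A(1−p_B) + p_B(1−p_A)].
* SNP classification: *fixed* (disjoint monomorphic allele sets), *shared*
  (both species polymorphic), *private* (exactly one polymorphic);
  sites uncalled in one species are labelled `uncallable` and excluded
  from class counts.
* Species consensus: the within-species major allele is substituted at each
  SNP site; 50/50 ties keep the reference allele.

Statistics are undefined (rather than zero) when their preconditions fail —
Tajima's *D* at S = 0, *F*<sub>ST</sub> with no usable site, ω at
d<sub>S</sub> = 0 — and are reported as missing.

## Selection statistics (`palmspec.selection`)

Site and difference counting uses the **equal-weight counting scheme**
(Nei–Gojobori style): each codon position contributes (number of synonymous
single-base changes)/3 synonymous sites, changes to stop codons counting as
nonsynonymous; site totals are averaged over the two sequences of a pair.
Codons differing at several positions are resolved by averaging the
synonymous/nonsynonymous step counts over all minimal substitution
pathways with equal weights, excluding pathways through stop codons unless
none is stop-free. Proportions p<sub>N</sub> = N<sub>d</sub>/N and
p<sub>S</sub> = S<sub>d</sub>/S receive the Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3), undefined at p ≥ 3/4. ω = d<sub>N</sub>/d<sub>S</sub>
when d<sub>S</sub> > 0. The module is structured so a
transition/transversion- and codon-frequency-weighted engine could be added
behind the same interface; the equal-weight scheme is the default because
its inputs and outputs are plain counts, reproducible and checkable against
exhaustive enumeration (which the test suite does on random two-codon
alignments).

MK tallies take D<sub>N</sub>, D<sub>S</sub> from pathway counting between
the two species consensus sequences and P<sub>N</sub>, P<sub>S</sub> from
classifying each polymorphic site in its consensus codon context.
Polymorphisms creating a premature stop are counted nonsynonymous and
flagged (the MK framework has no stop category). Codons carrying multiple
fixed differences are decomposed by the same pathway averaging, with a
warning listing them.

**α = 1 − (D_S·P_N)/(D_N·P_S)** on pooled counts; undefined when
D<sub>N</sub> = 0 or P<sub>S</sub> = 0. The class contrast
Δα = α(class A) − α(class B) is tested by permuting gene-class labels
(default 10 000 permutations), with the **one-sided**
p = (1 + #{Δα<sub>perm</sub> ≥ Δα<sub>obs</sub>})/(n<sub>perm</sub> + 1);
the hypothesis of interest is directional (the ω > 1 class should have the
higher α) and the add-one form avoids p = 0. Permutations whose pooled
counts leave α undefined are redrawn and their number reported. The
permutation engine is vectorized (label matrices × count matrix), so the
calibration test in the suite (200 replicate null datasets × 500
permutations × 200 genes) runs in seconds.

*f*<sub>N</sub> = d<sub>N</sub>/(d<sub>N</sub> + d<sub>S</sub>) is formed
**average-then-ratio**: d<sub>N</sub> and d<sub>S</sub> are first averaged
over the relevant pair set, then combined. The within-species pair set
pools both species' intraspecific pairs before averaging — the alternative
(per-species averages, then a mean of two f<sub>N</sub> values) differs
only at second order and the pooled form keeps genes with an invariant
sample in one species usable. DiS = f<sub>N-between</sub> −
f<sub>N-within</sub>; the regression of f<sub>N-between</sub> on
f<sub>N-within</sub> is ordinary least squares.

## Expression and NODE (`palmspec.expression`)

rpm[g, s] = counts[g, s] · 10⁶ / mapped-reads[s]. A gene enters a tissue's
analysis only if rpm ≥ 1 in **every** sample of that tissue (the
per-sample reading; filtering is per tissue, so a gene can be testable in
one tissue and not another).

The built-in DE engine fits, per gene, an ordinary linear model to
log2(rpm + 0.5) with an intercept, a species indicator and collection-trip
(batch) factors, and tests the species coefficient with a t statistic. The
0.5 pseudo-count keeps zeros finite; trip effects are additive on the log
scale. When species and trip are perfectly confounded the trip factor is
dropped with a warning. This engine deliberately is **not** a reimplementation
of negative-binomial GLM machinery: DE calling is a pluggable contract
(`de_from_table` accepts any caller's gene/logFC/p table), and the
package's own contribution is the layer on top. Benjamini–Hochberg FDR is
applied within each tissue; significance means FDR < 0.05.

**NODE**: a significant gene is NODE when min(rpm over all samples of one
species) > max(rpm over all samples of the other), strictly — equal
extremes do not qualify. The direction (which species is up) is recorded;
the definition is antisymmetric by construction.

Soil contrasts rerun the same engine on relabelled sample subsets (the
two-soil species' soil-1 vs soil-2 samples, and each soil group vs the
other species) and partition the significant genes of the two
between-species contrasts into unique/shared sets.

## GO screening (`palmspec.screen`)

Over-representation uses the hypergeometric upper tail P(X ≥ k) with the
background as population, restricted to terms annotating between 10 and 100
background genes (excluding overly general and weakly supported terms),
with BH FDR across tested terms. The default background is the annotated
subset of the reference gene set (the conventional ORA universe); a flag
widens it to all genes. No GO-graph propagation is performed — a gene has
exactly the terms in its map, since propagation would change term sizes.

The pleiotropy screens require at least one ecological-stress focal term
(response to stress GO:0006950, osmotic stress GO:0006970, water
deprivation GO:0009414, metal ion GO:0010038) **and** at least one
reproductive focal term (reproduction GO:0000003, regulation of flower
development GO:0009909), on genes with ω > 1 (selection route) or NODE
(expression route). The expression route also reports a secondary list:
NODE genes with ≥ 2 ecological terms and no reproductive term. The
two-proportion z test (pooled variance, two-sided normal p) supports
comparisons such as "are high-F<sub>ST</sub> genes differentially expressed
more often than expected".

## Synthetic data (`palmspec.synthetic_data`)

The generator produces the study's data structures with recorded truth.
Design choices:

* **Coding sequences.** Ancestral ORFs are uniform random sense codons
  (ATG first, no internal stops). Fixed differences are applied to the
  species-B consensus by biased acceptance: given a gene's target ω, the
  nonsynonymous share of fixations is ω·N/(ω·N + S) for the gene's site
  totals, so counting methods can recover ω from realized counts. At most
  one variant site is placed per codon, keeping counting-truth recovery
  exact and the no-stop invariant simple to enforce.
* **Polymorphism.** Per species, segregating sites arise at rate
  `theta_within` per site; derived-allele frequencies follow a 1/i
  spectrum and diploid genotypes are drawn at Hardy–Weinberg proportions
  (no within-species structure is modelled), redrawn until the sample is
  actually polymorphic. A `frac_shared` share of sites is polymorphic in
  both species, the rest private. Alignments carry the two consensus
  sequences plus two haplotypes per individual, so every SNP exists in
  both the alignment and the genotype-matrix representation.
* **Counts.** Negative binomial with var = μ + φμ² (φ = `nb_dispersion`,
  Poisson at φ→0), gene means lognormal on the rpm scale, library sizes
  uniform in `lib_size_range`, trip effects additive on log2 means. DE
  genes get ±`lfc_de`/2 per species in one designated tissue; the
  `frac_node` share of them is forced, by redrawing that gene's counts in
  that tissue, to strict rpm range separation with all samples at rpm ≥ 1
  — that is what "planted NODE" means here. Non-DE genes have identical
  species means.
* **GO maps.** Every gene draws a Poisson number of terms uniformly from a
  vocabulary of the six focal ids plus `n_background_go_terms` generic
  ids; a `go_enrichment_frac` share of selected genes is additionally
  given one ecological and one reproductive focal term.
* **Reads.** Duplicate families of categorical size derive from one random
  fragment each; copies get independent quality strings (a
  `low_quality_frac` share of bases at Q < 7) and sequencing errors planted
  **only** at those low-quality positions, so by the dedup rule the
  families are exactly recoverable.

Default rates (θ = 0.003/site, divergence 0.002/site, 30% shared
polymorphism, 10% selected genes at ω = 2 vs background ω = 0.2, 10% DE
genes at |log2FC| = 2, dispersion 0.05, 1–5 M reads per library) are chosen
as plausible for recently diverged congeners profiled by RNA-seq; they are
free parameters of the generator, not calibrated claims about any
particular system, and are deliberately denser than real transcriptome SNP
rates so that per-gene statistics are exercised at desk scale.

What the generator does **not** emulate: genealogical correlation along
sequences (no coalescent; sites are independent), linkage disequilibrium,
splice isoforms, mapping ambiguity, GC or length biases in counts, and
read-position error profiles. Passing tests therefore demonstrate
correctness of the statistics and screens under their stated models, not
robustness to those real-data complications.

A master seed fixes every output byte-identically; each generator stage and
each pipeline stage draws from an independent stream derived from it.

## Scale of the shipped checks

The test suite runs the pipeline end to end at a few hundred genes and
checks the statistics' closed forms, oracle agreements (10⁴ random
two-codon alignments against exhaustive pathway enumeration), a 200-replicate
permutation-null calibration (200 genes, 500 permutations) and a
2000-gene NODE/screen truth-recovery run with 8 samples per species per
tissue — sizes chosen so the whole suite completes in about a minute on one
CPU while still giving the stochastic checks useful resolution.

## Known limitations

* The equal-weight counting scheme ignores transition/transversion bias
  and codon-frequency weighting; ω from it is biased for strongly skewed
  mutation processes.
* The Jukes–Cantor correction saturates at p = 3/4; such pairs are flagged
  rather than corrected.
* The built-in DE engine's normal-theory p-values are approximate for
  low counts; for real analyses, import an external caller's table.
* Fu & Li's starred statistics treat the folded singleton class; with an
  outgroup the unfolded variants would be more powerful.
* The bucketed dedup mode is approximate by design (see above).
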