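# Methods

`metasig` reconstructs **metagenomic signature pairs** — a catalog enzyme
gene attributed to the taxon whose contig carried it — from shotgun gut
metagenomes, and tests them between a depressed (PwD) and a healthy-control
(HC) cohort. This note documents the models, the parameters that matter,
what the synthetic cohorts do and do not emulate, and the numerical choices
made where the design was open.

## Pipeline model

The analysis follows the standard whole-metagenome two-branch layout:

1. **Taxonomic branch.** Reads are classified with a k-mer LCA classifier
   (below) at confidence 0.5, supra-species mass is redistributed to species
   in proportion to each sample's direct species counts, and profiles are
   aggregated to genus and phylum. Alpha diversity is Shannon's H (nats),
   beta diversity is Bray-Curtis with a permutation PERMANOVA
   (999 permutations, add-one p estimator, so min p = 0.001).
2. **Functional branch.** ORFs are called on contigs (six frames,
   ATG-to-stop, longest ORF per in-frame stop, default floor 150 nt) and
   annotated against the enzyme catalog by Smith-Waterman local alignment
   (BLOSUM62, affine gaps 11/1 in the BLAST cost convention) with the
   admission thresholds **identity >= 60%** and **relative alignment length
   >= 90%** of the reference protein. Read counts per ORF come from a
   seeded exact k-mer mapper (k = 15; a read is assigned when more than half
   its k-mers agree on one ORF, ties to the lowest ORF id) and are
   normalized between samples with TMM.
3. **Signature branch.** Contigs that carry annotated ORFs are classified at
   confidence 0.01; unclassified contigs are discarded; contigs without a
   species-level call get a nucleotide-alignment fallback against the
   reference genomes, accepted only at identity **strictly** > 90%. The
   surviving (taxon, enzyme) combinations form signature pairs at genus and
   species level; a pair's abundance is the sum of its ORFs' normalized
   abundances.
4. **Inference.** Two-sided Mann-Whitney U with Benjamini-Hochberg FDR,
   corrected separately per family (taxa per rank, genes, pairs per level,
   severity correlations), after excluding features detected in fewer than
   half of the samples. Severity association uses Spearman correlation of
   species-level pairs with CES-D, GAD-7 and HAMD-17.

## Classifier

The index maps every canonical k-mer (lexicographic min of k-mer and
reverse complement) of the reference genomes to the LCA of the species
carrying it. Classification tallies a sequence's k-mer hits over the
taxonomy, takes the candidate with the highest root-to-node accumulated
weight (ties resolve to the LCA of the tied candidates), and raises the call
toward the root until the clade holds at least the confidence threshold's
share of **all queried k-mers** (misses count against the confidence). If
even the root fails the threshold the sequence is unclassified. Defaults:
k = 31 for reads, k = 21 for contigs — longer sequences tolerate the smaller
k, which helps sensitivity at the permissive 0.01 contig threshold. The
species redistribution step is a deliberately simple proportional rule (with
a uniform fallback for clades without direct species counts); no Bayesian
re-estimation is attempted.

## TMM normalization

Factors follow the published trimmed-mean-of-M-values estimator: reference =
sample whose upper-quartile/library-size ratio is closest to the mean such
ratio; per sample, over features nonzero in both sample and reference, log2
ratios M are double-trimmed (30% each end, and 5% each end on average log
abundance A) and averaged with **inverse** delta-method-variance weights;
factors are rescaled to geometric mean 1. Samples sharing fewer than 5
surviving features fall back to factor 1 with a warning. The implementation
reproduces edgeR's `calcNormFactors(method="TMM")` to ~1e-10 (cross-checked
in the test suite via Rscript). Note that the inverse-variance weights
depend weakly on absolute library size, so TMM factors — and hence
normalized abundances — are only approximately invariant to scaling one
library (exactly invariant at fixed factors).

Normalized abundance is counts per million of the effective library
(library size x factor). ORF-level abundances are summed to enzyme level
after annotation; signature pairs keep ORF provenance.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, at
desk scale:

- **Reference genomes** are i.i.d. random backbones (default 12 kb) with
  catalog genes inserted as ATG...stop loci. Each planted locus translates
  to its catalog protein at an identity drawn from a configurable band
  (default 80-100%), realized by an exact count of residue substitutions
  with protected 3-residue flanks so a local alignment measures the planted
  identity exactly; codons are randomized per locus so the same protein
  diverges at the nucleotide level across species.
- **Compositions** are log-normal per species (default sd 0.6 on the log
  scale, a realistic inter-subject spread), normalized to sum to 1; planted
  species effects shift the case-group log mean by log(fold-change). Because
  compositions are renormalized, the realized relative-abundance ratio of a
  planted effect is attenuated for dominant species; planted effects are
  therefore best placed on minority species.
- **Contigs** are verbatim substrings of one genome (assembly is out of
  scope and assumed error-free); counts per genome are multinomial in the
  composition; planted *gene* effects act on the sampling weight of contigs
  overlapping the locus, so gene-level and taxon-level effects are
  decoupled (a gene fold-change is copy-number-like, conditional on its
  host species).
- **Reads** are fixed-length substrings of the contigs with i.i.d.
  substitution errors (default 0.5%, constant Phred quality; no indels,
  no quality decay, no host contamination). Read and contig names carry
  their source genome, position and strand, so classifier recall and
  planted-gene recovery can be scored exactly.
- **Clinical scores.** A latent severity is drawn per subject from a Beta
  distribution; CES-D, GAD-7 and HAMD-17 are deterministic monotone maps of
  that latent onto each instrument's eligibility window (PwD: HAMD-17 >= 14,
  CES-D >= 27, GAD-7 < 10; HC: CES-D < 18, GAD-7 < 5). Putting all
  randomness in the latent keeps the componentwise-monotonicity guarantee
  that the score simulator promises.
- **Severity-linked pairs.** Where a rank correlation between a pair's
  abundance and HAMD-17 is planted, the Iman-Conover method is used: exact
  normal scores are rotated through the Cholesky factors of their empirical
  and the target correlation matrices, so the **sample** Spearman
  correlation sits at the target (up to ~0.02 attenuation from integer
  score ties) rather than fluctuating with the O(1/sqrt(n)) noise of a
  population-level copula plant. This is the standard way to induce a
  target rank dependence in simulation studies.

Passing tests on these cohorts demonstrate that the pipeline's bookkeeping,
thresholds, and inference are correct under the generative model; they do
not certify behavior under real-data phenomena the generator omits
(assembly chimerism, indels, strain mixtures, uneven coverage, host reads).

## Problem sizes and numerical choices

Simulation-based checks run at sizes chosen to make their statistical
targets sharp while staying desk-scale: null calibration uses 500 cohorts of
20+20 samples with 200 features (Mann-Whitney) and 1000 replicates at 999
permutations (PERMANOVA); planted-pair recovery uses 20 cohorts of 20+20
samples, 10 species across 5 genera, 300 contigs and ~3500 reads per
sample, with the 4-fold decrease planted on a species at baseline log-mean
+0.7 so its gene stays above the prevalence filter in both groups.

Other numerical conventions: identity = matches / alignment columns
(gaps included) and coverage = aligned reference span / reference length,
both in percent; ties in Mann-Whitney use midranks with the tie-corrected
normal approximation (exact enumeration when min(n) <= 8 and tie-free);
Spearman p is exact by permutation enumeration for n <= 7; all-tied group
comparisons report p = 1; degenerate PERMANOVA (zero within-group sum of
squares) reports the floor p with a flag; byte-identical ORF sequences are
collapsed to their lowest-id representative before read mapping (the
tie-break makes this exact, not an approximation).

## Known limitations

- Strain-level signatures are out of scope; the species rank is the finest
  reported.
- The prevalence filter and BH families follow the fixed 50% / per-family
  conventions; no covariate adjustment (age, sex, BMI are carried as
  metadata only) and no multivariable association step.
- The exact k-mer read mapper scores no mismatches; with substitution-only
  errors at <=1% and k = 15 its sensitivity is adequate, but it would
  undercount reads at higher divergence between reads and ORFs.
- The catalog shipped by the generator is synthetic (random proteins with
  realistic enzyme/metabolite metadata); real analyses should load a curated
  protein catalog via `metasig.catalog.load_catalog`.
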