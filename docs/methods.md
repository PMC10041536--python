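# Methods

## The breeding-line model

`tempsweep.sim` simulates a closed meat-duck line under mass selection on
breast muscle weight (BMW). Each generation holds `pop_size` diploid birds
(default 3,300) with 1:1 sexes. Within each sex, birds are ranked by phenotype
and the top `female_retention` (0.375) of females and `male_retention` (0.075)
of males become parents — about 619 dams and 124 sires, "roughly 750" parents
per generation. Each offspring draws a dam and a sire uniformly with
replacement (no selfing is possible across sexes; pedigree-based
inbreeding-avoidance is not modelled). The variance effective size of this
scheme is Ne = 4·N_m·N_f/(N_m+N_f) ≈ 413.

**Trait.** BMW (grams) is additive: genetic value = Σ dosage·effect over
`n_causal` loci, phenotype = baseline (80 g) + centred genetic value +
N(0, σ_e²). σ_e is calibrated once, at the founders, so the founder
narrow-sense heritability equals `h2` (default 0.3 — an assumption; the line's
BMW heritability is not published). Calibrating once keeps h² interpretable as
a founder property; under selection the realised h² declines as genetic
variance erodes (Bulmer effect plus frequency change), as in a real programme.
With `h2 = 0` the phenotype is pure noise, so selection is random with respect
to genotype — the breeder's-equation limit R = h²S = 0. Component measurements
(BB, KL, BMT) are back-filled from BMW via BMV = (BMW − 17.042)/0.6228 with BB
and KL fixed at reference values, purely for I/O realism.

**Causal architecture.** Causal loci are drawn from standing variants whose
favored (effect-carrying) allele segregates at founder frequency 0.1–0.5
(`causal_maf_range`). A trait never previously selected upward has its favored
alleles away from fixation, and this matches the observed behaviour of
selected loci in such experiments: frequencies rise gradually across the ten
generations rather than jumping to fixation. Effects default to equal
(`effect_sizes = 3.0` g/allele); only relative effects matter once h² is
fixed, since σ_e is scaled to the genetic variance.

**Founders and recombination.** Founder haplotypes come from an msprime
coalescent (Ne = 200, a small conserved line) so they carry realistic LD
blocks — without which haplotype statistics (EHH, XP-EHH) are uninformative.
Independent-locus founder laws (`uniform`, `fixed`) are available for
calibration work. Meiosis is a crossover Poisson process with no interference
(rate `recomb_rate`/bp); transmission at SNPs is realised by per-interval
switch indicators with the Haldane probability (1 − e^{−2rd})/2, which is
distribution-identical at the marker positions because only the parity of
crossover counts between adjacent markers matters. Mutation is off: ten
generations of response come from standing variation (soft sweeps).

**Scaling rule.** Desk-scale chromosomes conserve *map* length, not physical
length: the default 1 Mb chromosome at 1e-6 crossovers/bp/meiosis spans ~1
Morgan, like a real macrochromosome. This matters: at the physical avian rate
a 0.5-Mb toy chromosome is a single ~1-cM linkage block, every sweep drags the
whole chromosome, and "neutral" loci show draft far above the Wright–Fisher
expectation. With map length conserved, simulated backgrounds (top-1% window
F_ST, maximum ΔAF) sit in the same regime as the genome-scale experiment the
simulator emulates.

**Sampling.** The default schedule draws 15 males + 15 females at generations
1, 4, 7 and 10, dropping one generation-4 female (119 records), uniformly
without replacement within sex.

**CNV loci.** `simulate_cnv_matrix` treats each CNVR as a diallelic locus
(normal vs variant allele, deletion- or duplication-type at ±0.5 copy per
variant allele, measurement noise SD 0.05). Neutral CNVRs drift as binomial
Wright–Fisher steps at Ne = 413; "selected" CNVRs follow a forced linear
frequency trajectory (default 0.1 → 0.7), emulating a CNV responding to
selection without modelling its phenotypic mechanism.

**What the generator does not emulate.** Sequencing depth and genotyping
error (depth filters become no-ops on simulated VCFs), overlapping
generations, pedigree structure in mate choice, dominance/epistasis,
genotype-by-environment effects, sex chromosomes, and mutation. Passing tests
therefore validate the statistical machinery and its calibration under an
idealised version of the design, not robustness to real-data artefacts.

## Statistics

**Variant filters.** Two retention profiles mirror resequencing practice:
`discovery` (3× < mean depth < 30×, MAF > 0.05, major-allele frequency < 0.99,
missing rate < 0.1, biallelic) and `afd` (mean depth in [5, 30], MAF > 0.01,
missing rate ≤ 0.1). Boundaries are strict exactly as printed; allele
frequencies use non-missing alleles only. Rejection counts are reported per
criterion, so a site failing several criteria appears under each (under
biallelic coding, failing the major-allele-frequency bound implies failing the
MAF bound, so first-failure counting would be order-dependent).

**ΔAF and enrichment.** ΔAF differences reference-allele frequencies (folding
optional). Bins are [0, 0.05), …, [0.95, 1.00] (last bin closed), 1-based.
Enrichment cells use χ² without continuity correction, replaced by Fisher's
exact test when any expected count is below 5; sites fixed for the same allele
in both cohorts are excluded from enrichment denominators. No multiple-testing
correction is applied across bins × categories by default.

**F_ST.** Weir–Cockerham (1984) two-population components with observed
heterozygosity; windowed values use ratio-of-sums Σa/Σ(a+b+c) (mean-of-sites
available). Identical finite cohorts give slightly *negative* a — the
estimator is unbiased, not positive — and monomorphic sites are flagged
uninformative with components (0, 0). Windows are [start, start+10 kb) every
5 kb, clipped at chromosome ends; windows without informative sites are
omitted.

**EHH / XP-EHH.** EHH(x) = Σ_g C(e_g,2)/C(n,2) over groups of identical
extended haplotypes from the core to x; the core column itself is excluded so
EHH(core) = 1. The decay walk stops below 0.05 (no max-gap pruning by
default). iHH integrates the pooled-haplotype (combined-allele) curve by
trapezoid over physical distance, both sides, truncated at the last point at
or above the cutoff; unstandardised XP-EHH = ln(iHH_query/iHH_ref) with the
earlier cohort as reference, standardised by the genome-wide mean and SD of
scored sites. Per-site values are assigned to windows as the value of the
maximum-|z| site (the aggregation is a package decision; tools differ).
Unphased input is refused rather than pseudo-phased.

**Thresholds and regions.** Empirical tails use linear-interpolation (type-7)
quantiles; XP-EHH is thresholded two-sided. Candidate regions are the merged
genomic intersection of above-threshold F_ST windows with above-threshold
|XP-EHH| windows.

**Mixed model.** Kinship is ZZᵀ/m on per-site-centred dosages rescaled to
mean diagonal 1 (IBS alternative available); missing dosages are mean-imputed.
REML maximises the restricted likelihood over δ = σ_e²/σ_g² via the
eigendecomposition of K, a 61-point log-grid on [1e-5, 1e5] and bounded scalar
refinement. Per-SNP tests hold the null-model variance components fixed
(the EMMAX approximation), whiten by (Λ+δ)^{-1/2} in the rotated basis, and
use t statistics with n − rank([X, snp]) degrees of freedom; with K = I the
scan reduces exactly to OLS. Fixed effects are intercept, sex, and the top-3
Patterson-normalised genotype PCs. The Bonferroni cutoff is −log10(α/N) with
N the number of SNPs actually tested.

**LD.** Default r² is the squared Pearson correlation of dosage vectors
(composite), appropriate for unphased data; `haplotype_em` computes
D²/(p_Ap_B(1−p_A)(1−p_B)) from directly counted (phased) or EM-estimated
(unphased) haplotype frequencies. Refinement keeps the [min, max] envelope of
region SNPs with r² > 0.4 to the lead SNP (ties at the lead go to the smaller
coordinate); with no qualifying neighbour the region degenerates to the lead
position and is flagged. "Noncoding" means every annotation category except
`exon`; UTRs count as noncoding.

**CNV screen.** Copy numbers round to the nearest half-integer (midpoints
half-up); values above 2.25 collapse into the multicopy class, coded 2.5 for
numeric work. The silhouette is computed on the 1-D values with classes as
clusters; the minor-state frequency is 1 − (modal class frequency). The
default RFD is the pooled-SE two-proportion z statistic
(f_B − f_A)/√(f̄(1−f̄)(1/n_A+1/n_B)) on carrier frequency (class ≠ 1), whose
magnitude is unbounded — consistent with screens whose printed cutoffs exceed
any frequency-difference bound; the bounded `relative` form 2(f_B−f_A)/(f_B+f_A)
is selectable. The screen keeps CNVRs at or above the (1 − 0.05) quantile of
|RFD|, ties included. Variance explained regresses phenotype on the numeric
class (ANOVA coding optional); pooled across generations this estimate
includes any cohort-level confounding between CNV frequency and phenotype
trend, which is why the calibration experiment (below) uses a single
unstructured cohort.

## Coordinates and conventions

Internal coordinates are 0-based half-open; VCF (1-based) and BED (0-based)
are converted only at I/O. Dosage counts ALT alleles; missing is −1, never
zero. A 1-based site p lies in interval [start, end) iff start ≤ p−1 < end.
All randomness flows from a single integer seed; identical seeds give
bit-identical outputs end to end, including the pipeline's JSON report.

## Calibration experiments and problem sizes

The replicated self-checks (`tempsweep.experiments`) run at deliberately small
problem sizes chosen as the package's demonstration scale: 1,000–2,000 SNPs on
4 × 0.5-Mb (1-Morgan) chromosomes, default population and schedule, 10–20
replicates.

- *Drift calibration*: 100 unlinked neutral loci through the default scheme;
  pooled Var(Δp)/(p(1−p)) is compared with 1/(2Ne). The theory band is
  [0.8, 1.3] because the closed form ignores the without-replacement
  (hypergeometric) correction in parent sampling and the finite-offspring
  term, which together put the true ratio a few percent above 1 at default
  sizes, plus Monte-Carlo error at ~900 transitions.
- *Joint-scan recovery*: windows are ranked by the smaller of their F_ST and
  |XP-EHH| percentile ranks; a causal locus's rank is its best containing
  window. The overlap-stage event — a Bonferroni-significant SNP inside a
  top-1%∩top-1% candidate region near a causal locus — is a triple
  coincidence that is rare at 119 samples (the corresponding genome-scale
  analysis yielded 2 regions from 187 candidates and 22 significant SNPs),
  and the package reports its empirical rate rather than guaranteeing it.
- *CNV power*: a 0.1 → 0.7 shifted CNVR among ~80 neutral ones is screened at
  the top-5% tail; a CNV effect simulated at 2% of phenotypic variance
  (n = 500, single cohort) is recovered by the class-regression R².

## Known limitations

Single-trait mass selection only (no BLUP/index selection, which the real
programme may have approached); EMMAX approximation rather than exact per-SNP
REML; no indels or multi-allelic sites; XP-EHH requires phased input; the CNV
module consumes a normalized copy-number matrix and does not call CNVs from
read depth; desk-scale genomes make quantile thresholds noisy (a warning fires
below 100/tail values).
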