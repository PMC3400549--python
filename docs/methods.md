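# Methods

This note documents the models, numerical choices and known limitations of
`autozyg`. Parameter defaults are stated with units and rationale; nothing
here asserts an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Genotype handling and QC

Calls are alternate-allele dosages in {0, 1, 2, missing}, where the
alternate allele is fixed at read time as the rarer observed allele
(lexicographic tie-break), so dosage coding is reproducible across the three
supported layouts (PED/MAP, BED/BIM/FAM SNP-major v1.00, TSV matrix).
Strand is taken as given; only autosomes 1–22 are kept; SNP-map coordinates
are 1-based inclusive and interval tables half-open. Monomorphic SNPs do not
round-trip through allele-labelled formats (the rarer-allele rule cannot
recover which homozygote was coded 0); QC removes them before anything
downstream cares.

QC applies, in a fixed documented order: sample missingness > 5%, SNP
missingness > 10%, Hardy–Weinberg exact test p < 1e-4, MAF < 1%. The HWE
test is the exact conditional (enumeration) test, two-sided without mid-p:
deterministic and correct at the low genotype counts where the chi-square
approximation fails. Because all four filters are per-sample or per-SNP
marginal rules, the surviving set is invariant to the SNP-stage order; the
order matters only for the per-stage accounting in the QC report, and is
asserted by tests through those counts. QC is idempotent on typical data;
exact idempotence is not guaranteed in pathological cases where removing
SNPs pushes a borderline sample over the missingness threshold.

## ROH calling

The caller follows the classic array-genotype sliding-window design. Windows
target 50 consecutive SNPs capped at a 5000 kb span; truncated windows at
chromosome ends (or under the span cap) are still formed. A window passes
when it contains at most 1 heterozygous and 5 missing calls — the allowance
exists because a single genotyping error would otherwise split a long run. A
SNP's hit rate is the fraction of passing windows among windows covering it;
maximal runs with hit rate ≥ 0.05 (the cited tool's documented default,
exposed as a parameter) become candidates, which are trimmed so reported
coordinates start and end on homozygous non-missing calls, split at
adjacent-SNP gaps above the allowance (splitting rather than rejecting
preserves long runs broken by one sparse region), and filtered on SNP count,
length and density (`length_kb / n_snps`) computed on the final segment.

Two presets: `froh_dense` (≥ 25 SNPs, ≥ 1500 kb, ≤ 100 kb gap, ≤ 20 kb/SNP)
for the full panel and `frohld_pruned` (≥ 12 SNPs, ≥ 1000 kb, ≤ 250 kb gap,
≤ 100 kb/SNP) for the LD-pruned panel. The implementation is vectorised with
prefix sums; the test suite holds it equal to a literal loop-based
enumeration of the rules on hundreds of random instances.

## LD pruning

Pairwise-r² pruning in 50-SNP windows advancing by 5 SNPs (the window size
and r² = 0.1 ceiling are the analysis constants; the step is the common
companion default, recorded in output config). r² is the squared Pearson
correlation of dosages over pairwise-complete samples — composite LD, since
array genotypes are unphased. Determinism is pinned down explicitly: within
a window the currently largest-r² pair is eliminated first (ties by SNP
index), and the removed member is the lower-MAF SNP (MAF tie: larger
position). A SNP removed in any window stays removed. After pruning, no
retained pair within any original window position exceeds the ceiling.

## Homozygosity measures

`typed_genome_length` is the summed first-to-last-SNP span per autosome
minus its overlap with a centromere interval table (build-specific, an
input; the simulator's fictional genome has none). Each panel (dense,
pruned) uses its own typed length, computed per cohort since panels differ
after QC. F_hom is computed on the QC'd dense panel — its definition covers
all genotyped SNPs, not the pruned subset.

## Genomic kinship and the polygenic model

K uses half-dosages x ∈ {0, 0.5, 1} and per-cohort alternate-allele
frequencies p from non-missing calls: off-diagonals are the pairwise-complete
mean of (x_i − p)(x_j − p)/(p(1 − p)); the diagonal is 0.5·(1 + f_i) with
f_i the individual's excess homozygosity (observed homozygous fraction minus
its allele-frequency expectation). Using in-sample frequencies centres the
matrix, leaving an O(1/n) negative bias on the off-diagonal mean — asserted,
not hidden, in the tests. Downstream the genetic covariance is 2K; if 2K has
a negative eigenvalue it is bent by adding |λ_min| + 1e-6 to the diagonal,
logged.

The mixed model is fitted by maximum likelihood (the option `reml=True`
switches the criterion): one eigendecomposition of bent 2K, then profile
likelihood in λ = σ²_g/σ²_e. The profile in log λ can be multimodal, so the
optimiser first scans a 61-point grid over λ ∈ [1e-6, 1e6] and then refines
the bracketing interval with a bounded scalar search (tolerance 1e-8,
≤ 200 iterations). λ outside [1e-5, 1e5] is flagged as a boundary fit —
reported, warned about, and treated by the pipeline as a convergence
failure, i.e. excluded from the affected meta-analysis with a logged reason.
Fixed-effect SEs use the degrees-of-freedom-corrected residual variance
(σ̂² = RSS_w/(n − p)), so that with no relatedness information (2K ∝ I) the
mixed fit reproduces OLS estimates and SEs exactly; the reported −2 log L is
the uncorrected ML value and is verified against a dense variance-component
grid. Mixed-model p-values use the normal reference, OLS p-values the t
distribution. Sex enters as a single indicator, age linearly, ordinal
socio-economic covariates linearly (factor coding was considered and left
out: with the small level counts simulated here the linear coding is the
conservative default and matches how such covariates are usually entered).

## Meta-analysis and the cousin scale

Fixed-effect inverse-variance pooling only — a random-effects estimator
would silently change the method being reproduced, so it is an explicit
non-goal. Pooled p from a two-sided normal test; heterogeneity by Cochran's
Q on k − 1 df. Diagnostics correlate cohort mean homozygosity with β_i
(expected ≈ 0 if the signal is not purely recent consanguinity) and with
SE_i (expected negative: more homozygosity variance, more precision).

The cm conversion multiplies |β| (z per 1% homozygosity) by ΔF (percentage
points between first-cousin offspring and outbred offspring, estimated
empirically per population from pedigree-classified individuals — more
realistic than the theoretical 6.25 because background homozygosity raises
both groups; the theoretical value is the logged fallback) and by the
sample-size-weighted height SD. With several ΔF sources the report lists
each cm figure and the min–max range. Pedigree F is Wright's path-counting
coefficient, computed by the recursive kinship algorithm and cross-checked
against an allelic gene-drop Monte Carlo.

## The synthetic-data generator

The generator emulates the features the analysis relies on, at desk scale by
default: 4 chromosomes × 12 Mb with 5000 SNPs (≈ 10 kb spacing, matching the
~9 kb density of a 300K array on the real genome; a 22-chromosome preset
scales up), uniform 1 cM/Mb map, per-cohort founder pools, pedigrees with
first-cousin (F = 1/16) and second-cousin (F = 1/64) matings plus optional
full-sib pairs, Poisson-recombination gene drop with exact tract ground
truth on the SNP grid, 0.1% genotype error and 0.2% missingness.

Founder haplotypes are mosaics of an ancestral pool: between adjacent SNPs
the copying process re-picks a pool member with probability
1 − exp(−ρ·d_bp), ρ = recombination rate × mixing depth. Pool size sets LD
strength (two loci are copied from the same member with probability
1/P + (1 − 1/P)·e^(−ρd), so r² decays analytically — tested). The mixing
depth default (300 generations) puts ancient shared segments at ~0.3 Mb,
below both ROH length thresholds: this matches the empirical premise that
ancient/common ROH are short and only recent parental relatedness produces
multi-Mb runs. (A shallower depth was tried first and produced multi-Mb
ancient segments — a regime the length-threshold design explicitly assumes
away, and which showed up as attenuation of the recovery experiment; the
default was corrected to the realistic regime.)

Height is built as 162 cm + 13 cm (male) − 0.05 cm/yr beyond age 50
+ additive polygenic value (SD 2.5 cm, 200 loci) + directional-dominance
load + N(0, 5.5 cm). The mechanistic load is −2.5 cm per rare homozygote at
500 recessive loci with allele frequency 2–8%: in expectation
Σ d·p(1−p) ≈ −59 cm per unit inbreeding coefficient, i.e. ≈ −0.61 cm
(≈ −0.065 z at SD 9.4) per percentage point of autozygosity — the design
load. The variance bookkeeping (42.25 + 6.25 + 30.25 + load ≈ 88 cm²) puts
the height SD near the 9.4 cm target in a panmictic cohort; consanguineous
cohorts legitimately exceed it because the load adds variance. The
reduced-form mode replaces the recessive loci with b_ID (−0.61 cm per 1%)
times the true autozygosity fraction, and an ordinal EA/OS covariate can be
generated with a configurable correlation to autozygosity for confounding
experiments. The consortium schedule interpolates mating mix (0 → 30%
first-cousin, 0 → 20% second-cousin) and pool size (400 → 40) across
cohorts, producing a better-than-tenfold spread in mean pruned-panel ROH
coverage.

What the generator does not emulate: real LD block structure and allele
frequency spectra (the pool model is exchangeable and analytically
tractable, not coalescent), selection, assortative mating, admixture, the X
chromosome, genotyping batch effects, or age–homozygosity cohort trends.
Passing tests therefore demonstrate correctness of the measurement and
inference chain under the stated generative model, not robustness to every
property of real cohort data.

## Validation experiment design

The end-to-end recovery experiment uses six cohorts of 500 samples
(n = 3000) at 5000 SNPs under the reduced-form load, repeated over three
independent consortium replicates and pooled jointly (18 cohort fits,
n = 9000): pooling replicates shrinks the Monte-Carlo SE, so the 2-SE
agreement check is a sharper test of unbiasedness than a single draw.
Because heights are z-scored within cohort, cohort i's true coefficient is
b_ID/sd_i; the pooled fixed-effect estimand is therefore the
inverse-variance-weighted mean of b_ID/sd_i over the pooled cohorts, which
is what the experiment compares against (≈ −0.065 by design). The null
calibration re-draws heritable phenotypes (polygenic additive part from the
cohort's own genotypes, h² ≈ 0.2) with zero load, 400 replicates, and checks
the pooled two-sided rejection rate at α = 0.05. Problem sizes throughout
(desk-scale genome, 300–500-sample test cohorts, 100 oracle instances) were
chosen so the whole suite completes in minutes while keeping every
statistical band at ≥ 3 Monte-Carlo SEs.

## Known limitations

- The ROH window contract (SNP-count windows with a kb cap, truncated
  windows formed at chromosome ends) is one consistent reading of the
  routine it mirrors; other tools resolve the window-definition ambiguity
  differently, which can shift segment boundaries by a few SNPs.
- ML variance components on small related cohorts can land on the λ
  boundary (σ²_g → 0 or σ²_e → 0); such fits are excluded from pooling,
  which slightly prunes the meta-analysis rather than biasing it.
- ΔF estimation requires pedigree-identified cousin offspring with measured
  genotypes; with none, the theoretical 6.25 understates background
  homozygosity differences.
- No hemizygous-deletion masking: large deletions can masquerade as ROH;
  on array data their impact on total ROH length is known to be small.
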