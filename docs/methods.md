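# Methods

This note documents the statistical procedures, the defaults and the
numerical choices in `skypurge`, and what the synthetic cohorts can and
cannot demonstrate about real data.

## Genotype input and filtering

Genotypes enter as a sites × samples dosage matrix (0/1/2 copies of the
first alternate allele, −1 for missing), read from VCF 4.x with cyvcf2.
Multiallelic records are kept and flagged by the reader; the biallelic
filter removes them, so no information is silently discarded at parse
time. Site filters follow VCFtools semantics and run in a fixed order —
genotype-level GQ masking first, then biallelic-SNP, QUAL, mean depth,
call rate, and minor-allele frequency — with each removed site attributed
to the first rule it fails and the per-rule counts logged. Defaults: mean
depth ≥ 3, GQ ≥ 10, QUAL ≥ 30, MAF ≥ 0.05, call rate ≥ 0.8. MAF uses
called alleles only, so sites monomorphic after GQ masking fall to the
MAF rule. When a VCF lacks DP or GQ FORMAT fields the corresponding rules
are skipped with a warning (permissive mode, the default) or raise
(strict mode).

LD pruning mirrors PLINK `--indep-pairwise w s r²` on the dosage
(composite) correlation: inside each window of `w` SNPs advanced by `s`,
any retained pair with r² above the threshold loses its later-positioned
member. The keep-earlier tie rule is deterministic; the postcondition (no
surviving pair within any window above threshold) is verified by brute
force in the tests. Genotypes are treated as unphased throughout; no
haplotype-based LD statistic is computed.

## Diversity and differentiation

Per-site diversity is the unbiased estimator (n/(n−1))·2p(1−p) over
called alleles; window values divide the summed site diversity by the
window's bp span (terminal windows by their true span). Windows are
anchored at position 1 per chromosome, 100 kb sliding by 10 kb for all
windowed statistics. Tajima's D uses the 1989 constants; because
missingness makes the per-site allele count vary, the constants are
evaluated at the harmonic mean of called-allele counts over the window's
segregating sites, with the a₁/a₂ sums analytically continued through the
digamma/trigamma functions (exact at integers). D is undefined (NaN)
without segregating sites. F<sub>ST</sub> is the Weir–Cockerham (1984) θ
with window and genome-wide values formed as ratios of summed variance
components; the per-site mean-of-ratios is also reported but the ratio of
sums is primary. Negative θ is reported as estimated, not clamped.

Private alleles count either allele (reference or alternate) observed in
exactly one population. LD decay averages pairwise r² in physical-
distance bins up to 300 kb and reports where the 3-bin-smoothed curve
first falls below a query level. Mantel tests correlate the upper
triangles of two labelled distance matrices with a one-sided (greater)
permutation p-value, (1 + #{r\* ≥ r})/(n\_perm + 1), permuting one
matrix's label order under an explicit seed; the isolation-by-distance
convention is great-circle km against Rousset-linearized F<sub>ST</sub>/(1
− F<sub>ST</sub>), and isolation-by-environment uses Euclidean distance on
z-scored variables.

## Inbreeding

F<sub>IS</sub> is the method-of-moments estimator (O<sub>hom</sub> −
E<sub>hom</sub>)/(N − E<sub>hom</sub>) with expected homozygosity 1 −
2p(1−p) from sample-wide allele frequencies; no small-sample correction
is applied (the difference from the frequency-corrected estimator is
O(1/2n) and immaterial at cohort sizes of ~140 haplotype pairs). ROH are
maximal stretches free of heterozygous calls, kept when they span
strictly more than 1 kb and contain at least 50 homozygous SNPs; missing
calls neither break a run nor count toward the minimum, and segment
coordinates run from the first to the last homozygous SNP. These
thresholds imply a high SNP density at the minimal length; both knobs are
arguments. ROH are classed short (1–100 kb, boundary inclusive) or long
(> 100 kb). F<sub>ROH</sub> divides the summed ROH length by the genome
length, default 786,920,000 bp, and runs on the full filtered SNP set,
not the LD-pruned one.

## Genetic load

Polarization uses the majority-homozygote rule: an allele is ancestral
when more than half (configurable) of individuals are homozygous for it,
counted over called genotypes by default (an all-individuals denominator
is available). Ties are excluded, and by default so are sites whose
inferred ancestral allele differs from the reference — the same
reference-bias guard as masking reference errors. Polarization is an
involution: a second application changes nothing.

Effects come from translating reference vs alternate codons in annotated
CDS (reverse-complemented on minus-strand genes, phase-trimmed): same
amino acid → SYN; stop gained/lost or start lost → LoF; SNPs in the 2-bp
intron edges → LoF (splice); otherwise MIS. Genes whose spliced CDS is
not a multiple of three are skipped with a warning. Missense sites split
at an externally supplied deleteriousness score: < 0.5 DEL, ≥ 0.5 TOL,
NA or low-confidence excluded. The package consumes these scores from a
TSV rather than computing them — substitution-deleteriousness scoring
needs a protein database and is outside this package's scope; the
synthetic generator fabricates scores with known truth.

Load ratios are zygosity-matched by default (het DEL / het SYN, hom DEL /
hom SYN) because heterozygous and homozygous load tracts answer different
questions about masked vs expressed load; a total-SYN denominator is a
flag. Population values are means over members. π₀/π₄ averages per-site
diversity over all annotated 0-fold and 4-fold degenerate positions —
monomorphic positions contribute zero but stay in the denominators — and
2-/3-fold sites are annotated but unused.

## Selective sweeps

The scan contrasts a focal with a contrast population: windows in the
upper 5 % of both the F<sub>ST</sub> distribution and ln(π_contrast /
π_focal) (upper tail = diversity loss in the focal population) are
candidates; thresholds are empirical quantiles over windows where both
statistics are defined, ties included, and adjacent candidates merge into
regions. Genes overlapping a region by ≥ 1 bp are reported once with
their region list. Orientation is fixed by argument order, so the
opposite contrast is obtained by swapping populations.

## Genotype–environment association

Environmental variables are z-scored and pre-selected greedily by
descending importance under a |r| < 0.8 Pearson filter. The association
model is a deterministic latent-factor formulation: K factors are the
leading left singular vectors of the genotype matrix after removing the
least-squares projection onto the environmental variables, so the factors
are exactly orthogonal to the tested variables and absorb the residual
population structure; each SNP is then regressed on intercept + variable
+ factors, t-statistics become χ² p-values, and a genomic inflation
factor λ = median(χ²)/0.456 recalibrates them. This trades the Bayesian
MCMC machinery of the original latent-factor mixed models for exact
reproducibility; with K = 0 it reduces to per-SNP OLS (verified to 1e−8).
K defaults to the number of populations (7 here). Significance is the
fixed p ≤ 1e−5 threshold with no further multiple-testing correction.
The GEA SNP subset keeps sites with call rate ≥ 0.99 and mean-imputes
the remainder.

Environment–structure confounding deserves a caveat: when the tested
variable varies only between populations, drift along the environmental
axis is statistically indistinguishable from selection at any single
locus. The λ calibration absorbs this into the null scale, which
controls the error rate but means only loci whose clines rise well above
the drift scale remain detectable — the relevant power regime for "core
adaptive" loci.

RDA regresses the centered (unscaled) dosage matrix on the standardized
variables and takes the SVD of the fitted values; SNP loadings are the
right singular vectors scaled by their singular values, and outliers
deviate from an axis mean by more than 3.5 SD on at least one axis.
Unscaled dosages are the standard landscape-genomics protocol and let
strongly clinal loci stand out through both correlation and variance; a
correlation-based variant (unit-variance SNPs) is available by flag.
Individual-level genotypes are the default unit; population allele
frequencies can be substituted upstream. The core adaptive set is the
intersection of LFMM-significant and RDA-outlier SNPs with merged
provenance.

## Genomic offset

A random-forest regression is fitted per SNP on population allele
frequencies (the GEA core SNPs by default) against the bioclimatic
predictors; every split's impurity reduction is attributed to its
predictor at its threshold, normalized within each SNP's forest, weighted
by the SNP's out-of-bag R² truncated below at zero, binned (200 bins)
along the predictor's observed range, and accumulated into nondecreasing
cumulative-importance step functions. Defaults: 500 trees per SNP, all
predictors tried at every split — greedy split choice keeps importance on
the true driver rather than crediting randomly forced predictors, which
matters with the handful of units a population-level fit provides. The
forest is fully seeded and bit-for-bit reproducible. Climate vectors map
through the step functions (below the first split → 0, above the last →
the function maximum); a cell's offset is the Euclidean distance between
its transformed current and future climates, computed per climate model
and scenario and then averaged across models within a scenario. Offsets
are a metric on the transformed space: zero iff the transforms agree,
symmetric, triangle inequality.

## Synthetic cohorts

The generator emulates the seven-population, three-lineage design:
ancestral allele frequencies Uniform(0.05, 0.95), lineage and population
frequencies drawn Balding–Nichols (lineage F = 0.08; population F 0.06–
0.15, highest in the selfing population), Hardy–Weinberg genotypes within
populations, ~0.2 % missing calls. Defaults: 20 diploids per population,
20,000 SNPs on four 2.5-Mb chromosomes. Autozygosity is implemented as
literal haplotype-copy tracts (exponential lengths, mean 200 kb, placed
until the target genome fraction is covered — realized coverage
overshoots the target by roughly the mean residual tract length, ~2 % of
the genome), so ROH detection has positional ground truth. Defaults give
the selfing population a 0.30 target and the rest 0.05.

Coding SNPs (15 % SYN, 5 % DEL, 5 % TOL, 2 % LoF) are packed into toy
single-exon genes whose codons are constructed so the effect classifier
recovers every configured class exactly: SYN at 4-fold third positions,
missense at 0-fold first positions, LoF as stop-gains, with every fifth
gene on the minus strand. Derived frequencies of DEL and LoF sites are
suppressed (× 0.5 and × 0.3) to mimic purifying selection; populations
with a purging deficit δ convert that fraction of their homozygous-DEL
genotypes to heterozygous (default δ = 0.3 in the selfing population),
modelling purging phenomenologically as the statistic of interest rather
than through forward simulation. Fabricated deleteriousness scores are
< 0.5 for DEL, ≥ 0.5 for TOL, with ~3 % NA/low-confidence.

Environment-associated loci are exact logit clines along a
precipitation-like gradient (bio18, declining smoothly toward the
north-west so population scores spread evenly), slope ±4 per standard
deviation from an intermediate midpoint frequency — strong selection
overwhelming drift at these loci, which realizes the dosage–environment
correlations (≈ 0.8–0.95) at which clinal detection is meaningful; loci
whose clines were left subject to drift would sit inside the
drift-confounded regime discussed above. One genomic region (200 kb) in
the selfing population is pushed most of the way to fixation as a planted
sweep. Current climate grids evaluate the same smooth surfaces on a 6×6
lon/lat raster; future grids add per-variable displacements scaled by
scenario (0.5/1.0/1.5/2.0 for the four emission pathways) and by climate
model (0.9/1.0/1.1 across three model labels), so offsets are monotone in
scenario by construction and the truth table records every displacement.

What passing tests do *not* show about real data: the generator has no
linkage (sites are exchangeable within windows), no recombination map, no
gene conversion, no mutation-rate heterogeneity, no genotyping-error
model beyond uniform missingness, pop-level (not individual) environment,
and purging as a direct genotype deficit rather than selection dynamics.
Estimator correctness is instead established against independent
textbook oracles; the cohort-level tests establish that planted signals
of realistic magnitude propagate through the full pipeline.

## Problem sizes used by the test suite

The validation suite runs the estimator-oracle comparisons on one hundred
20 × 200 panels; ROH against brute force on fifty random chromosomes;
purging recovery on one hundred full-size cohorts (140 diploids, 20k
SNPs); autozygosity recovery on twenty 6k-SNP cohorts per target level;
GEA null calibration on ~10⁵ tests and power on one hundred 8k-SNP
cohorts; RDA null calibration on 10⁴ pure-noise SNPs; and one end-to-end
run of the command-line pipeline on a full-size fixture bundle validated
against its truth tables. These sizes were chosen so the full suite
completes in a few minutes on a single CPU while keeping every assertion
at the stated statistical strength.
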