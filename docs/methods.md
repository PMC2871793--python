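# Methods

`castebias` implements a dual-omics analysis of developmental caste bias
in *Polistes* paper-wasp larvae: candidate-gene qRT-PCR differential
expression and label-free spectral-count proteomics, compared between
foundress-reared (FR, putative worker-destined) and worker-reared (WR,
putative gyne-destined) fifth-instar larvae, with haplodiploid
microsatellite sexing upstream of both. This note documents the models,
the numerical conventions, the synthetic study conditions the test
suite runs under, and the known limitations.

## Sexing by microsatellite ploidy

Hymenoptera are haplodiploid: females develop from fertilized diploid
eggs, males from unfertilized haploid eggs. A specimen heterozygous at
any microsatellite locus is therefore provably diploid and female; one
with a single allele at every amplified locus is *potentially* male
(a diploid homozygous everywhere is indistinguishable); three alleles
at a locus indicate triploidy; a specimen with no amplified locus is
unscorable. The minimum number of heterozygous loci needed to call a
female is configurable (`min_het_loci`): the default is 1, because one
heterozygous locus already proves diploidy; a stricter 2-locus variant
is exposed, as both conventions appear in the field's literature.
Failed loci are excluded from counting, and only a specimen with no
amplified loci at all is eliminated.

The false-male rate of this rule is the probability a diploid is
homozygous at all L amplified loci, `prod_l sum_a f_la^2` for allele
frequencies `f_la` — about 1e-4 per specimen under the default
simulated frequencies (six loci, five moderately uneven alleles each).
The simulator allocates truth classes deterministically (rounded
fractions, shuffled order), so the default 29-specimen worker-reared
cohort contains exactly 18 haploid males and 1 triploid, matching the
observed sex ratio of that cohort; the sexing stage must recover them.

## qPCR quantification and normalization

Quantities come from a genomic-DNA standard curve, the least-squares
line of Cq on log10 quantity; amplification efficiency is
`10^(-1/slope) - 1` (1.0 at slope -3.3219). Technical triplicates are
aggregated as the mean of quantities (not of Cq values), with an
advisory flag when the replicate CV exceeds `cv_warn` (default 0.3, a
conventional triplicate-QC bound). Duplicate runs of the same gene and
distinct contigs of one gene are merged by the per-sample mean; the
Pearson correlation of the merged pair is recorded and a low value
(below 0.9) flags but does not abort the merge, because merging is
justified by identity of the underlying gene, with the correlation as
a consistency check.

Normalization divides each gene's quantity by the endogenous control
gene (RSP8) of the same individual and then takes log2:
`value(g,i) = log2(q(g,i) / q(ctrl,i))`. Ratio-then-log is the standard
relative-quantification convention; it makes the control row exactly
zero and cancels any multiplicative per-sample technical factor
exactly (the end-to-end test verifies identity to 1e-12 with and
without simulated scale factors). The log base is configurable; rank
statistics are base-invariant and the F statistic is invariant up to a
positive scalar. Missing cells are imputed with the same-group median
of the gene before the rank test only; the ANOVA instead drops missing
cells, so imputation cannot manufacture ANOVA degrees of freedom.

## Per-feature tests

The Mann-Whitney U statistic is `#{x_i > y_j} + ties/2`. Its exact
two-sided p-value is the permutation probability, over all
`C(n1+n2, n1)` label assignments of the pooled data, that U deviates
from `n1*n2/2` by at least the observed amount, conditional on the
observed tie pattern (midranks). The null distribution is computed by
dynamic programming over the rank-sum generating function —
mathematically identical to full enumeration (the tests verify
agreement to 1e-12 against a brute-force enumerator) but cheap enough
to recompute inside resampling loops. `auto` mode uses the exact
distribution whenever the assignment count is at most 50,000, which
covers the 10-vs-7 design (19,448 assignments) exactly, and otherwise a
tie-corrected normal approximation with continuity correction.

Exact small-sample p-values are discrete and conservative: at (10, 7)
the attainable level just below 0.05 is 0.0431, and the smallest
attainable two-sided p is 2/19448 = 1.03e-4. Calibration tests
therefore assert the exactly attainable level, and the uniformity
property is checked after a randomized probability integral transform,
which is exactly U(0,1) for a correctly calibrated discrete test.

The ANOVA is a fixed-effects one-way F test with df (1, n-2), equal to
the squared pooled-variance t statistic. The original analysis used a
mixed-model routine, but FR and WR larvae come from disjoint nests
collected in disjoint periods, leaving no estimable shared grouping
factor; a nest random intercept remains a documented hook rather than a
default. Zero pooled within-group variance yields F = inf, p = 0 when
means differ (flagged as infinite-F) and F = 0, p = 1 when they
coincide.

## Familywise correction

Both feature families (genes, peptide hits) use a min-p resampling
correction: group labels are resampled under the null, all per-feature
p-values recomputed, the per-iteration minimum recorded, and the
corrected cutoff set to the empirical alpha-quantile of that null
min-p distribution — the k-th smallest with
`k = max(1, floor(alpha * n_iterations))`, 1000 iterations by default.
Features are resampled jointly, so dependence reduces the effective
multiplicity: ten identical features give a cutoff near alpha, 38
independent features approach the Sidak value `1 - 0.95^(1/38) =
0.00135`. Label permutation is the default resampling scheme (exact
under exchangeability); a group bootstrap (resampling individuals with
replacement, preserving group sizes) is exposed as the named
alternative, with ties introduced by duplicated samples handled by the
tie-aware exact test. A significance flag requires `p <= cutoff`
(boundary inclusive); for the gene family the default is the
concordance rule — both the Mann-Whitney and the ANOVA p must pass.

Two discreteness effects matter. First, the cutoff lands on the
attainable-p grid, so the realized familywise error rate sits at the
grid point nearest the nominal alpha (about 0.046-0.072 around 0.05 at
the 38-gene, 10-vs-7 design; the 500-study calibration test bounds it
within the binomial band around 0.05). Second, at 5 vs 5 the smallest
attainable two-sided p is 2/252 = 0.0079; when that floor has more than
alpha family probability, the empirical quantile *is* the floor, and no
cutoff below ~0.008 is meaningful. Rejections at 5 vs 5 therefore
require complete separation of the two groups, and the familywise
false-flag probability cannot be pushed below roughly
`m * 0.004-0.006` for m tested null features — a structural property of
exact rank tests at this sample size, not of this implementation.

## Discriminant classification

Two-class LDA with pooled within-class covariance:
`w = S^-1 (mu_WR - mu_FR)`, optional ridge
`S + lambda (trace(S)/p) I`, and the decision boundary at the
prior-adjusted midpoint of the projected class means. Priors default to
the empirical class frequencies (10/17, 7/17), matching common solver
defaults; an equal-prior option exists. Ridge defaults to 0 with loud
singularity diagnosis (16 features vs 17 samples *is* singular-adjacent
and must fail rather than silently pseudo-invert).

Because strongly correlated gene pairs (insulin-pathway genes,
lipoprotein genes, the Hex70b contigs) make the pooled covariance
ill-conditioned, features are pruned first: either a manual override
list (the reproducible stand-in for the published manual curation that
removed PmPi3K, PmILP2, PmRfaBp and PmeELF1a before the 12-gene
discriminant), or a greedy rule — repeatedly drop the feature with the
most above-threshold (|r| > 0.9) partners, breaking ties by larger mean
|r|, then by lexicographically later id — which terminates in at most
p steps and never removes both members of an isolated pair.

Leave-one-out cross-validation refits the discriminant on each n-1
subset and predicts the held-out sample. The feature set is pruned once
on the full data and held fixed across folds, mirroring the published
sequence (prune, then LDA, then LOOCV); this is mildly optimistic and a
per-fold pruning option is provided. Null calibration: with 12 noise
features at n = 10 vs 7, mean LOOCV accuracy is 0.5 (the acceptance
test bounds it within 3 SE over 200 simulations).

## Spectral-count proteomics

Raw counts are filtered on presence — count >= 3 in at least 3 of 5
replicates, evaluated within either group by default (a hit confidently
present in only one group is the most interesting biological case); a
pooled variant is exposed. Normalization is dialect-specific. In-gel:
counts are divided by the spike-in standard count of their (sample,
band) — each band piece carries its own beta-lactoglobulin spike — and
then by the lane total over all hits and bands; per-lane-aggregate
spike normalization is an option. In-liquid: division by the per-sample
total only. Either way each sample's normalized values sum to 1. The
total-count denominator is all target hits, excluding spike-in and
decoy entries. Decoy-database hits give the target-decoy FDR of the
accepted list, `#accepted decoys / max(1, #accepted targets)`, capped
at 1. Redundant hits mapping to one protein are tested and reported
individually with their protein group attached, not collapsed.

Differential abundance uses the same Mann-Whitney + min-p machinery as
the gene family, at the peptide family's own alpha; the corrected
cutoff emerges from its own resampling run.

## Synthetic study conditions

The original raw tables were never deposited, so the generators define
the study conditions the pipeline is tested under.

**Expression** (defaults): 10 FR vs 7 WR samples; 38 genes plus the
control; 16 genes up-regulated in WR by 2.5 within-group SD on the log2
scale; three correlated blocks (sizes 3, 3, 2) at pairwise r = 0.93,
realized by one shared latent factor per block with loading sqrt(r);
log-normal biological noise (log2 SD 1.0) — the analysis log-transform
presumes approximate log-normality; a removable per-sample technical
scale factor (log2 SD 0.25) applied to every gene including the
control; technical triplicates at CV 0.1; missingness completely at
random at rate 0.003 (matching the reported 2 missing cells in ~650),
never on the control gene. The control gene carries no biological noise
of its own: it is the uniformly expressed reference. The paper gives no
quantitative effect sizes, only direction; 2.5 SD is the package's
documented free parameter. At that effect the exact-test power per gene
under the familywise cutoff is ~0.77, so a single run typically flags
12-14 of the 16 true genes, all in the up direction — the qualitative
pattern, not a guaranteed 16/16.

**Spectral counts** (defaults): 5 vs 5 samples; 24 database hits (21
targets, 3 decoys at near-background intensity 1.0, which keeps the
simulated accepted-list FDR in the <=1% regime); Poisson counts with
per-lane log-normal loading (sd 0.2), five gel bands with a fixed
per-hit Dirichlet band profile, spike-in mean 30 per band. Nine hits
are differential at 8-fold: four low-abundance hits up in WR and five
high-abundance hits down, with base intensities (6 and 38.4) chosen so
the differential spectral mass gained equals the mass lost. This
balance is deliberate: total-count normalization is compositional, and
an unbalanced differential mass shifts every null hit's normalized
value between groups, generating spurious calls — a known limitation of
total-count normalization that the real study cannot escape either.
Poisson (not negative binomial) is the default count model because
spectral counts are small and the pipeline's arithmetic, not biological
dispersion, is under test; a gamma overdispersion option exists.

**Genotypes** (defaults): 29 specimens, 6 loci, five alleles per locus
at frequencies (0.35, 0.25, 0.20, 0.12, 0.08), male fraction 18/29,
triploid fraction 1/29, 3% per-locus amplification failure.

What the generators deliberately do not emulate: raw spectra and
chromatograms, amplification curves and Cq calling, nest structure and
seasonal covariates, peptide-to-protein inference beyond a grouping
column, and any systematic (non-random) missingness. Passing tests
therefore demonstrate the statistical machinery under the stated
conditions, not robustness to those unmodelled features of real data.

## Numerical conventions and degenerate inputs

Quartiles use linear interpolation (the common "type 7" convention);
box-summary outliers use the 1.5*IQR rule. Z-scores use the sample
(n-1) SD; a constant feature z-scores to zeros with a flag rather than
an error. Heatmap output orders samples FR block then WR block and
features by ascending Mann-Whitney p — the package's own convention.
All randomness flows from explicit integer seeds (never the clock), and
repeated runs at equal configuration produce byte-identical artifacts,
verified by content hash. Merges need >= 3 jointly observed samples;
curves need >= 2 distinct quantities; correlations need >= 3 pairs and
non-constant input; imputation refuses a gene with no observed value in
a group; LDA refuses singular covariance at ridge 0 and each LOOCV fold
must keep both classes non-empty.

## Problem sizes in the test suite

The calibration experiments run at sizes chosen to keep Monte-Carlo
error well inside the asserted bands: 500 null studies for the
familywise error rate, 1000 resampling iterations per correction, 200
null simulations for classifier calibration, 100 datasets for the
reference-solver comparison, 10 seeds for the pattern-recovery run, and
10^4-scale draws for generator-convergence checks.
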