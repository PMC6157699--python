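# Methods

`fursealpop` implements the population-genomic analysis chain used to study
the New Zealand fur seal (*Arctocephalus forsteri*), a pinniped that was
hunted to near-extinction by Polynesian and then European sealers and has
since recolonized most of its former range from a small number of refugium
colonies. The package covers SNP quality control, diversity and structure
statistics, coalescent ABC inference of the two-bottleneck demographic
history, an FST-outlier scan, leave-one-out population assignment, and a
synthetic eight-colony study generator that stands in for the original
GBS dataset.

## Genotype model and quality control

Genotypes are biallelic SNP dosages (copies of the alternate allele as
written in the source file; 0/1/2 with a missing sentinel). Minor-allele
orientation is computed per dataset for frequency filters only — calls are
never recoded. The QC chain applies, in order: individual missingness
(> 90% removed), locus missingness (> 20%), minor allele frequency (< 5%,
recomputed on the post-missingness matrix), a per-population Hardy–Weinberg
exact test (two-sided enumeration of heterozygote counts conditional on the
allele counts; default alpha 0.01), and windowed LD pruning (squared Pearson
correlation of dosages over pairwise-complete individuals, window of 50
loci, r² > 0.8, keeping the higher-call-rate member of a pair). HWE and LD
removals require flagging in at least 6 of 8 populations, following the
study design. All thresholds sit in a single `QCConfig`.

Two choices the upstream tooling leaves open: the LD filter is windowed
(pairwise within a sliding window) and the MAF filter is global rather than
per-population; both are configurable.

## Diversity and structure statistics

* Expected heterozygosity is the unbiased gene diversity
  (2n/(2n−1))·2p(1−p) per locus, averaged over loci; FIS = 1 − Ho/He on
  multilocus means, tested by re-pairing gametes within the group.
* FST is Weir & Cockerham's (1984) variance-component θ, combined across
  loci as a ratio of sums; negative estimates are not clamped. Slatkin's
  linearization θ/(1−θ) is applied for isolation-by-distance work.
* The Mantel test correlates upper-triangle entries and permutes row/column
  labels jointly; all permutation p-values in the package use
  (k+1)/(n+1) smoothing, so p is never zero and never below 1/(n+1).
* Isolation by distance uses great-circle distances between colony
  coordinates; a user-supplied distance matrix can replace them (the real
  seals disperse along a coastline, which great circles only approximate).
* AMOVA partitions squared dosage differences (summed over loci,
  missing dosages mean-imputed) into among-group, among-colony-within-group
  and within-colony components via the standard nested sums-of-squares with
  unequal-size coefficients; Φ-statistics are tested by permuting
  individuals (Φ_ST) and whole colonies among groups (Φ_CT). A haplotypic
  AMOVA is not possible for unphased SNPs.
* PCA mean-imputes missing dosages, centres by twice the allele frequency
  and eigendecomposes the individual covariance; it is deliberately plain
  (no read-depth-aware relationship matrix).

## Coalescent simulator

Unlinked SNP loci are simulated one genealogy at a time under a
piecewise-constant multi-deme coalescent (pair-coalescence rate 1/(2N) per
generation, continuous-time approximation; optional symmetric island
migration; backward-time merge and resize events). A single mutation is
placed uniformly on the total branch length, and the locus is redrawn —
tree and mutation together — until the pooled minor-allele frequency
reaches the ascertainment threshold (default 0.05, capped at 10,000
redraws). Times are generations; the 7-year generation time only annotates
reports. Diploids are formed by pairing gene copies within a deme
(consecutive pairing of exchangeable copies, which is a random pairing in
distribution).

The two demographic scenarios compared are:

* **two-decline** — backward in time, the NZ-North and NZ-South demes
  (sizes Ne_N, Ne_S) merge at the post-sealing time t_post_seal into a
  refugium of size Ne_refugium; at the European-sealing time t_Europeans
  the size becomes Ne_historical; at the Polynesian time t_Polynesian it
  becomes Ne_pre_historical. No migration after divergence.
* **null** — the same divergence, but a single constant ancestral size.

The event loop is numba-compiled with an inline xorshift64* random stream
(the loop is RNG-bound; the inline generator roughly halves tree cost). The
simulator is cross-validated against msprime (total-branch-length
distribution, Kolmogorov–Smirnov), against the 2N expectation for pairwise
coalescence times, and against the finite-island closed form
FST = 1/(1 + 4Nm(d/(d−1))²).

## ABC inference

The summary layer is the DIYABC-style 8-vector for two samples: per-sample
mean gene diversity across polymorphic and across all loci; mean pairwise
Weir–Cockerham FST and mean Nei (1972) standard distance, each as a
"nonnull" (defined and nonzero) and an all-loci mean with undefined values
contributing zero (flagged). Priors are independent uniforms with the
ordering conditions t_Europeans > t_post_seal, t_Polynesian > t_Europeans,
Ne_pre_historical > Ne_N and > Ne_S (rejection sampling); the null
scenario's constant size takes Uniform[10³, 5·10⁶], mirroring the
ancestral-size prior.

Rejection standardizes each statistic by its reference-table standard
deviation and retains the closest fraction (default 1%) by Euclidean
distance. Scenario choice reports both the direct (retained-frequency) and
the multinomial-logistic estimate (fit on the retained rows with
Epanechnikov distance weights, evaluated at the observed vector, clipped
and renormalized). Parameter posteriors use the local-linear
regression adjustment: sizes on log scale, times on a prior-bounded logit
scale, Epanechnikov weights, minimum-norm weighted least squares (the
ascertained statistics are partly collinear — e.g. the polymorphic-loci and
all-loci diversities coincide on simulated data — and the minimum-norm
solution predicts correctly through that); a regression with no usable
signal falls back to the unadjusted sample with a warning. Posterior modes
come from a weighted Gaussian KDE (Silverman bandwidth) on the natural
scale; intervals are weighted 5%/95% quantiles.

Reliability of the scenario choice is quantified with pseudo-observed
datasets (PODs): type I is the fraction of focal-scenario PODs not assigned
(argmax) to the focal scenario, type II the fraction of alternative PODs
assigned to it. POD parameters can be drawn from a prior or fixed; the
shipped reliability check generates focal PODs at the published
posterior-mode parameters (the closest available stand-in for draws from
the fitted posterior) and null PODs from the null prior.

Two properties of this comparison are worth knowing before reading error
rates. First, the two-decline prior nests effectively null histories (a
2,500-breeder "refugium" held for five generations leaves no trace), so
data simulated from the null prior carry almost no information about the
scenario — the true scenario posterior for typical null pseudo-observations
sits near 0.5 and argmax classification of them is close to a coin flip at
any simulation budget. The measured type II error (~0.4 at desk scale)
reflects that overlap, not estimator noise. Second, a dataset generated at
the posterior-mode parameters (strong bottleneck) is decisively assigned to
the two-decline scenario (logistic probability ≈ 1), matching the published
behaviour.

Desk-scale defaults used by the shipped checks: 5,000 simulations per
scenario, 1,000 ascertained loci, samples of 101 and 66 diploids, tolerance
1%, 500 PODs per scenario; parameter recovery uses 20,000 two-decline
simulations. These sizes were chosen as the smallest that keep the
bottleneck identifiable (with fewer than ~500 loci the refugium size is
unresolved and the posterior stays prior-like). Note that the generating
values of the recovery check sit near prior boundaries (Ne_refugium = 110
is the 0.4th percentile of its prior, t_Europeans = 49.2 the 96.8th), so
90% interval coverage of t_Europeans is intrinsically marginal — the
published posterior itself prints a mode (49.2) above its own 95% quantile
(49).

## Outlier scan

The FDIST-style scan estimates per-locus multi-population θ, calibrates a
finite-island null (deme size 1,000 by default; migration rate solved so the
closed-form island FST matches the 5%-trimmed mean of the observed θ),
simulates single-SNP island loci with matched sample sizes and the same
pooled-MAF ascertainment as the filtered data, bins simulated (He, θ) pairs
by pooled heterozygosity (width 0.02, empty bins merged with the nearest
occupied bin), and assigns each observed locus a two-sided rank p-value
within its bin. p-values become Benjamini–Hochberg q-values; loci at or
below the FDR threshold are outliers, split into diversifying and balancing
tails. The scan also reports the CI envelope (default 0.99) per bin and
flags loci outside it — the classical FDIST criterion.

A limitation worth stating: the per-locus θ of a neutral island locus has a
heavy genealogical tail (its 0.995 quantile is ~4–5 times the mean with 8
demes), so a *single* moderately diverged locus essentially never reaches
q ≤ 0.05 — the envelope criterion is the sensitive detector for single
loci, while q-values control the FDR of panel-scale scans. This mirrors the
original study, where the FDIST run found no outliers.

## Assignment

Each individual is scored against every candidate population by the log10
likelihood of its genotype under Hardy–Weinberg proportions at the
population's allele frequencies, with the individual's own alleles removed
from its home population's estimate (leave-one-out). Frequencies of exactly
0 or 1 are replaced by 0.005/0.995 without renormalization. Missing calls
are imputed once per analysis by drawing allele pairs from the global
pool (seeded). The best population is the likelihood argmax; the home
p-value positions the observed home likelihood among genotypes simulated
from the home LOO frequencies (10,000 by default, (k+1)/(n+1) smoothing)
and is reported separately from the accuracy (argmax-only, with optional
exclusion masks for admixed colonies in the average). Cluster-level
assignment pools individuals by cluster and recomputes frequencies.

Small-sample caveat: because the home frequencies are estimated from n−1
individuals while other candidates use n, home likelihoods carry a slight
downward bias; with few individuals and many loci the home p-values skew
low, and panmictic colony-level accuracy sits slightly below 1/k. The
bias vanishes as samples grow (verified in the tests at n = 200).

## Synthetic study generator

The generator emulates the survey design: eight colonies with the published
sample sizes (28, 23, 21, 14, 15, 22, 22, 22; 167 pups), a North-West and a
South cluster plus an admixed North-East pair (CP at weight 0.6 toward the
North-West pool, OP at 0.5). Ancestral minor-allele frequencies are uniform
on [0.05, 0.28] (giving mean He ≈ 0.26 after binomial sampling); cluster
pools diverge from the ancestor by a Balding–Nichols F of 0.014 and
colonies from their pools by 0.004–0.008, which lands pairwise θ in the
published 0.003–0.022 range with a weak isolation-by-distance gradient; 2%
of calls are masked as missing. Colony coordinates are synthetic stand-ins
(the study prints none) chosen to give a sensible coastal gradient. What
this fixture does *not* emulate: GBS read-depth structure, allelic dropout,
genotyping error, linkage, and real geographic sampling noise — so passing
tests demonstrate correct statistical machinery, not field realism.

## Reproducibility

Every stochastic routine takes an explicit seed; dataset-level seeds are
derived from user seeds via `numpy.random.SeedSequence`. The pipeline runs
from a single YAML configuration with one seed per stage, and two runs with
the same configuration produce byte-identical outputs.
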