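# Methods

This note documents the statistical conventions, models and numerical
choices behind `genld`, and what the validation experiments do and do not
demonstrate.

## Set-level LD statistics

For a locus set L of m polymorphic sites with derived-allele dosage vectors
X_i ∈ {0,1,2}ⁿ over n diploid individuals:

* **LDcor(L)** — the mean over all admissible pairs i < j of the Pearson
  correlation cor(X_i, X_j). Range [−1, 1].
* **LDcorabs(L)** — the mean of |cor(X_i, X_j)|. Range [0, 1]; zero iff all
  pairs are uncorrelated. LDcor ≤ LDcorabs always.
* **NetLD(L)** — the mean of cov(X_i, X_j) on the raw dosage scale.
* **nLDcor / nLDcorabs** — the target-set value minus the value of a null
  set computed under the identical pair filter (range [−2, 2]); the package
  follows the convention of using synonymous variants as the near-neutral
  null in empirical data.

**Averaging prefactor.** All set-level means divide by the number of locus
pairs m(m−1)/2. An alternative reading of the prefactor (dividing by a
pair count formed from the number of *individuals*) would not keep LDcor
inside [−1, 1], which is the property that makes the statistic comparable
across sets and species, so the loci-pair convention is used throughout and
recorded here deliberately.

**Moment convention.** Sample moments use the n−1 denominator everywhere.
Correlations are denominator-invariant; NetLD and V_A are not, so the
convention is recorded in every result (`moment_denominator` field).

**V/V_A.** Two quantities are reported because they differ on the
covariance term: the compact form (m(m−1)/2 · NetLD + V_A)/V_A, in which the
pairwise covariance sum enters once, and the direct data ratio
Var(Σ_j X_j)/Σ_j Var(X_j), in which it enters twice
(Var(Σ) = V_A + 2Σ_{i<j} cov). Users comparing against either convention
can pick the matching number; the package takes no side.

**Fast paths.** When the pair filter admits every pair, the pair sums
collapse through the variance identity
Var(Σ_j Z_j) = m + 2Σ_{i<j} cor(X_i, X_j) on unit-standardized columns
(and its raw-dosage analogue for NetLD), at cost O(nm) instead of O(nm²).
The absolute-value statistic has no such identity; beyond 5×10⁶ admissible
pairs LDcorabs switches to seeded uniform pair subsampling without
replacement, and the result records the path taken. Fast and explicit paths
agree to 1e−10 (tested).

**Pair filters.** Distance filters operate on |pos_i − pos_j| in bp
(1-based coordinates kept from the VCF). Cross-chromosome pairs count as
infinitely distant: admitted by any minimum-distance filter, excluded by any
finite maximum, excluded entirely under `same_chrom_only`.

**Classical statistics.** D = p_AB − p_A p_B on derived-allele haplotypes;
r² = D²/(p_A p_a p_B p_b); D′ normalizes D by max(−p_A p_B, −p_a p_b) for
D < 0 and min(p_A p_b, p_a p_B) for D > 0 (D = 0 ↦ 0). The signed √r²
carries the sign of D computed on the derived–derived haplotype, and for a
single pair equals the Pearson correlation of the two haplotype indicator
columns — which is why genotype-based LDcor tracks it without phasing
(random union of gametes halves neither the sign nor, in expectation, the
standardized covariance).

## VCF ingestion and quality control

Only biallelic SNPs with complete genotypes are kept. Default filters:
QUAL ≥ 20, INFO/MQ ≥ 40, every sample's FORMAT/DP ≥ 3, site mean depth at
most 2.5× the dataset-wide mean (sites lacking a field pass that filter; the
dataset mean is taken over the sites that reach the depth stage), and an
exact Hardy–Weinberg test p ≥ 1e−6. All thresholds are configurable;
species-specific caller expressions are out of scope — the generic filter
set is the supported surface.

The HWE test is exact and conditional on the allele counts: it enumerates
every heterozygote count compatible with the observed counts,
P(n_het = b) ∝ n!/(a! b! c!)·2^b, and sums the probabilities of all
configurations no more likely than the observed one (ties included — a
two-sided convention that agrees with full multinomial enumeration to
1e−12 on all totals tested).

Polarization uses an ancestral-allele map (TSV or the VCF `AA` tag):
ancestral = REF keeps the ALT dosage, ancestral = ALT flips it to
2 − dosage, anything else (including "N" or absence) drops the locus, as do
sites monomorphic after polarization. Functional categories come from a TSV
or a VEP-style `CSQ` field; with multiple transcript annotations the most
severe recognized category wins (LoF > missense > synonymous), where LoF is
the union of stop-gained, stop-lost, splice-acceptor and splice-donor
consequences.

Locus sets default to dac ≥ 2 (doubletons and up): singletons carry no
pairwise information at matched frequency and are the class most exposed to
sequencing and calling error.

## Exact two-locus null

For two unlinked loci with derived counts dac1, dac2 among 2N gametes, the
observed D has a discrete exact distribution: conditional on the margins,
the derived–derived haplotype count n_AB is the only free entry of the 2×2
table, each table weighted by its multinomial coefficient
(2N)!/(n_AB! n_Ab! n_aB! n_ab!) — equivalently n_AB is hypergeometric.
Probabilities sum to 1 and E[D] = 0 to 1e−12; enumeration is guarded at
2N ≤ 60 (beyond which the finite-sample question stops being interesting
and a normal approximation serves). The per-table diploid-class likelihood
∏ y_ij^{N_ij} with combination number (2N)!/∏ N_ij! is exposed separately
for user-supplied frequency vectors; the enumeration itself works at the
haplotype level, which is the distribution random union of gametes actually
induces.

## Resampling inference

Null replicate sets are drawn from a pool (e.g. synonymous loci) to match
the target set's derived-allele-count histogram *exactly*, stratum by
stratum, without replacement within a stratum, independently across
replicates (default 100). A binned variant (`match_on="daf_bin"`) exists
for pools too small for exact matching. Permutation p-values use the
add-one rule p = (1 + #hits)/(R + 1), which cannot return 0; lower, upper
and two-sided (2·min, capped at 1) values are always all reported because
the interesting tail depends on whether one expects repulsion or coupling.

## Forward Wright–Fisher simulator

Discrete generations, panmictic demes, fitness-proportional parent sampling
(selfing not excluded), one recombinant gamete per parent draw with
Poisson(r·L) crossovers at uniform positions, Poisson(2N·μ·L) new
infinite-sites mutations per generation on a continuous coordinate line,
each new mutation deleterious (coefficient s ≤ 0) with probability
1 − `neutral_fraction`. Multi-epoch demography changes deme sizes by
fitness-proportional resampling at the new size (the bottleneck mechanism);
per-pair migration fractions give the probability that an offspring's parent
is drawn from another deme. Burn-in defaults to 10·N₀ generations.

**Fitness.** w = Π_j w_j · (1 − ε)^{k(k−1)/2} with w_j = 1 + s (derived
homozygote), 1 + h·s (heterozygote), and k the individual's total count of
deleterious derived allele copies (`epistasis_mode="loci"` counts mutated
loci instead). ε > 0 is synergistic epistasis — the standard
pairwise-interaction penalty making log-fitness concave in the burden —
and the functional form is a package design choice: direction-of-effect
claims, not numerical equality to any particular epistasis implementation,
are what the validation tests assert. Fitness is floored at 0.

**Rescaling.** `scaling_factor` Q divides population sizes and epoch
durations and multiplies μ, r, s and ε, preserving N·μ, N·r, N·s, N·ε.
Fixed deleterious sites are pruned eagerly whenever epistasis is active
(they would otherwise leak into k); lost and inert fixed sites are pruned
lazily for speed. Site columns are kept in insertion order internally and
sorted by position at sampling time.

**Calibration oracles.** Neutral runs reproduce Watterson's
E[S] = θ·Σ_{i=1}^{2n−1} 1/i within 3 s.e. over 50 replicates
(N = 200, θ = 4NμL), allele-frequency trajectories are martingales, and a
new neutral mutant fixes with probability ≈ 1/(2N) within binomial error —
the three classical closed forms a forward simulator must hit.

## Desk-scale validation experiments

The directional experiments (LDcor vs selection strength, epistasis level,
bottleneck severity/duration) run at desk scale: N = 500 diploids, 50 kb,
30 replicates per grid cell, with rates rescaled so the population-scaled
compound parameters match the reference setup of a 10,000-diploid, 1 Mb,
μ = 1.5e−8 simulation: μ_desk = 3e−7 (20-fold), and r_desk = 4e−6 — the
20-fold selection/mutation rescaling times a further 20-fold compensation
for the shorter sequence, so the *total map length* 4N·r·L (≈ 400) matches
the reference. Preserving map length matters: if desk-scale pairs are much
more tightly linked than reference-scale pairs, neutral doubletons acquire
a genealogical coupling bias (two rare mutations of matched frequency tend
to sit on the same recent lineage when tightly linked) that has nothing to
do with selection and swamps the directional signal. Most of the population
(400 of 500 individuals) is sampled so that doubletons are appropriately
rare (frequency 0.25%, near the reference setup's 0.1%). LD is computed on
doubletons (dac = 2), separately within each selection-coefficient class,
so pairs never mix classes.

Grid values: selection coefficients {0, −1e−3, −1e−2, −1e−1} are applied as
desk-level values (population-scaled strengths N·s of 0, −0.5, −5, −50);
epistasis levels are population-scaled to the reference grid, ε_desk ∈
{0, 0.02, 0.2} giving N·ε of 0, 10 and 100. The selection contrast is
evaluated on doubletons; the epistasis contrast on the maximum-MDAC set
(every site with dac ≥ 2, still within-class pairs) — the epistatic pair
penalty acts on the whole mutation burden, so its LD signal spans the
frequency range, and under strong epistasis too few deleterious doubletons
segregate per desk-scale replicate for a doubleton-only mean to be stable.
Both conditionings are computed from the same simulations and reported. Directional cells use a 5N
burn-in — the contrasts compare cells with identical burn-in, and
calibration experiments (which measure absolute levels) keep the 10N
default. The no-selection zero check is evaluated at the high-recombination
end of the grid (r_desk = 2e−5, map length ≈ 2000), where the
pairwise-independence expectation applies; at the tightly linked end the
genealogical coupling bias of rare-variant pairs keeps neutral doubleton
LDcor slightly positive (~+0.01 at these sizes) regardless of
implementation, and the directional tests are contrasts against that
common baseline.

What passing these tests shows: the implementation's statistics respond to
selection, synergistic epistasis and drift in the directions population
genetics predicts, at compound parameters honestly rescaled from the
reference conditions. What they do not show: numerical agreement with any
full-scale simulation study or with empirical species data — desk-scale
effect sizes are larger and noisier, and real genomes add gene structure,
variable recombination and mutation-rate heterogeneity that the uniform
infinite-sites model deliberately omits.

## Synthetic genotype generator

The fixture generator builds 2n latent haplotypes from a shared Gaussian
template: locus j assigns its derived alleles to the top-dac_j scores of
√a·u + √(1−a)·e_j. The loading a is calibrated against the bivariate-normal
quadrant probability so the expected pairwise indicator correlation equals
the requested ρ, and the top-k rule enforces the dac spectrum exactly;
haplotypes are then paired at random into diploids (making the dosage
correlation ≈ the haplotype indicator correlation). Negative ρ is feasible
only for two loci (mean pairwise correlation of m variables is bounded
below by −1/(m−1), and the shared-template construction needs a nonnegative
loading beyond pairs); infeasible requests raise. The generator emulates
frequency spectra and exchangeable pairwise LD — not genealogical
structure, distance decay, or selection.

## Known limitations

* The Gravel et al. (2011) human-demography presets are piecewise-constant
  approximations (growth rendered as two constant stages) with externally
  sourced parameter values; they are editable configs, not calibrated fits.
* The simulator records no genealogies; statistics needing tree topology
  are out of reach.
* LDcorabs on very large sets is estimated by pair subsampling; the
  subsample size and seed are recorded in the result.
* The exact two-locus enumeration treats loci as unlinked; linked exact
  distributions and composite-D estimators are not implemented.
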