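# Methods

This document records the model behind `mutascan`, the statistical choices
each module makes, and the derivations used to validate the simulator.
Default parameter values appear in `mutascan.theory.MutatorModel`.

## 1. Model

A **mutator allele** at a focal locus multiplies the germline mutation rate
of its carriers by φ ≥ 1. Parameters:

| symbol | default | meaning |
|---|---|---|
| μ | 1.2×10⁻⁸ | wild-type mutation rate, per bp per generation |
| ρ | 1.26×10⁻⁸ | recombination rate, per bp per generation |
| φ | 5 | carrier mutation-rate multiplier |
| g | 20,000 | generations since the allele arose |
| s | −2×10⁻⁴ | selection on the mutator homozygote |
| h | 0.5 | dominance (heterozygote fitness 1 + h·s) |
| p₀ | 0.2 | allele frequency at origin of the analysis window |
| N | 10,000 | diploid effective population size |

### Closed forms (`theory`)

- **Excess per site** on a carrier haplotype carried for g generations:
  g·μ·(φ−1) (= 9.6×10⁻⁴ at defaults).
- **Mean unrecombined segment** around the focal locus after g generations:
  each flank survives recombination with mean length 1/(g·ρ), so the
  two-sided mean is 2/(g·ρ) (= 7936.5 bp).
- **Excess on the mean segment**: 2·μ·(φ−1)/ρ (= 7.619), independent of g —
  older alleles have more excess per bp on a proportionally shorter segment.
- **Selection against a mutator** through the extra deleterious load: a
  carrier transmits an extra (φ−1)·U deleterious mutations per generation
  (U = genomic deleterious rate); with codominant constituent mutations of
  mean heterozygous effect s_d this gives s = −2·s_d·(φ−1)·U. An optional
  dominance argument rescales by h_mut/0.5.
- **Background expectation**: heterozygosity × length derived alleles on a
  non-carrier haplotype (≈ 7.9 over the mean segment at π = 10⁻³), the yard
  stick against which the carrier excess is judged.

### Allele-frequency dynamics

`deterministic_trajectory` iterates the standard single-locus recursion
p′ = p(p·w_AA + q·w_Aa)/w̄. `wf_extinction_time` simulates discrete
Wright–Fisher reproduction (deterministic selection on the expected
frequency, then binomial sampling of 2N copies), vectorized over replicates;
replicates that fix are excluded from the loss-time mean and reported
separately. `diffusion_extinction_time` evaluates the mean absorption time
by quadrature of the standard sojourn-density Green's function with scale
density exp(−2Nsx) (codominant selection only, h = 0.5); with
`conditional_on_loss=True` the density is reweighted by the loss
probability. The neutral limit is −4N(p ln p + q ln q). At defaults:
unconditional 12,859.8, conditional on loss 12,476.7, Wright–Fisher loss
mean 12,830.8 ± 521.8 over 500 replicates — an allele that raises load only
weakly persists on the order of 13,000 generations.

## 2. Simulator (`simulate`)

`simulate_mutator_region` builds a structured coalescent sample:

1. An `msprime` ancestry simulation over the region (discrete genome,
   optionally with a piecewise genetic map read from a HapMap-style file).
2. The deterministic frequency trajectory f(t) of the mutator allele
   classifies, backward in time, whether the lineage carrying the focal
   locus is a carrier.
3. **Mutation-rate convention** (the novel part): material linked to the
   focal-carrier lineage mutates at φμ; all other material mutates at the
   population-average rate μ(1 + f(t)(φ−1)) — the expected-rate form of
   assigning each unlinked lineage carrier status with probability f(t).
   Material recombined away from the focal lineage joins the carrier
   background with probability f(t).
4. If the deterministic trajectory hits 0 before the present,
   `AlleleLostError` is raised rather than returning a sample with no signal.

`simulate_null` is the neutral control, single population or a symmetric
split. **Ploidy convention**: haplotypes are simulated as ploidy-1 samples,
and in `msprime` the coalescent timescale with ploidy 1 is
`population_size` generations (not 2·`population_size`), so a diploid Ne is
passed as `population_size = 2·Ne` to recover diversity θ = 4Neμ.

`add_multinucleotide_mutations` converts a fraction of mutation events into
two-site clusters (same haplotype column, second site within a fixed
distance), modelling multinucleotide mutations that inflate local derived
counts without a mutator.

### Semi-analytic carrier excess (simulator validation)

Let x be distance from the focal locus and τ backward time. A site at
distance x remains attached to the focal lineage back to τ with probability
exp(−ρxτ). While attached, the carrier-conditioned lineage mutates at φμ
against the non-carrier expectation μ(1 + f(τ)(φ−1)): a differential of
μ(φ−1)(1−f(τ)). After detachment, material from carrier- and
non-carrier-conditioned haplotypes enters the *same* background process, so
by a coupling argument its expected contribution cancels from the
carrier-minus-non-carrier difference. Hence

  E[excess] = 2 ∫₀^W dx Σ_{τ=0}^{g} μ(φ−1)(1−f(τ)) e^{−ρxτ},

implemented in `theory.expected_carrier_excess` (trapezoid over x, exact sum
over τ). As W → ∞ with f → 0 this recovers 2μ(φ−1)/ρ. Validation at the
default model (400 coalescent replicates): window ±4 kb simulated
5.467 ± 0.165 vs 5.566 predicted; ±20 kb simulated 15.329 ± 0.391 vs 15.483.
An independent forward-in-time Wright–Fisher oracle with explicit mosaic
recombination (in `tests/_forward_wf.py`) agrees with the coalescent
simulator to within 0.2 combined standard errors at a small-parameter
configuration.

## 3. Genome scan (`scan`)

Per haplotype and sliding window (default 10 kb, step 1 kb, half-open,
anchored at 0), count derived alleles. Per window:

- **IQM**: interquartile mean of the per-haplotype counts (drop ⌊n/4⌋ from
  each end after sorting) — a robust estimate of the background that is
  insensitive to up to a quarter of haplotypes being highly derived.
- **max**: the largest per-haplotype count.
- **fitted**: an OLS fit of max on IQM across *all* windows predicts how
  large the maximum should be given local diversity.
- **M = max − fitted**: the scan statistic; windows where a few haplotypes
  carry far more derived alleles than local diversity explains score high.

Artifact filters, applied to reporting but not to the M ranking:

- **Hardy–Weinberg**: per SNP per population, a 1-df χ² test on observed
  genotype counts (no continuity correction); windows with a failing-SNP
  fraction strictly greater than 5% are flagged (genotyping artifacts and
  unmodelled structure both violate HWE; a true haplotype-borne excess does
  not, provided carriers are unrelated).
- **High diversity**: windows with IQM above the 75th percentile are flagged
  — the max-vs-IQM regression is least reliable in its upper tail.

`rank_candidates` reports windows with M ≥ 18 (roughly the closed-form
doubling signal at default parameters, 7.6 excess + background ≈ 8, with
headroom) that pass both filters, merging overlapping windows within one
window length. In split-population samples the scan runs per population and
combined ("all"); demographic structure moves IQM and fitted together, so M
is insensitive to it (verified in the acceptance suite: the 99th percentile
of null M agrees within a factor of 2 between panmictic and 5-deme samples).

## 4. Trio validation (`trios`)

Carriers are identified among parents by counting derived alleles in the
candidate window on each phased haplotype (`classify_phased`): haplotypes
above a data-driven threshold — the largest gap in the sorted counts above
the median — are "highly derived", giving 0/1/2 copies per parent. For
unphased parents a genotype-count analogue is provided.

The test regresses the offspring de novo count on parental copies with a
robust linear model (Huber loss, t = 1.345, MAD scale), optionally adjusting
for parental age; the one-sided p_t comes from the t distribution of the
coefficient. Because de novo counts are overdispersed and cohorts small, the
primary p-value is a one-sided permutation test of the coefficient
(label-permutation of copies; plain proportion reported alongside the
(b+1)/(n+1) form). Cohorts with fewer than 5 carriers raise
`TestNotApplicableError` and are reported as not-performed. The battery
routine runs loci × cohorts × parent sex and Bonferroni-corrects by the
number of *performed* tests.

## 5. Repair-gene enrichment (`enrichment`)

Observed statistic: the number of distinct flagged (repair) genes with any
part within radius r of a candidate point (gene [gs, ge) is near point p iff
gs − r ≤ p < ge + r). Null: candidate points are redrawn uniformly from the
callable space (length-weighted across BED intervals), preserving the number
of points. P-values are the plain exceedance proportion and the (b+1)/(n+1)
form; seeded and reproducible.

## 6. Numerical and design choices

- All random processes take explicit seeds; identical seeds give identical
  output across runs.
- `wf_extinction_time` caps at 400·N generations (far beyond the neutral
  mean −4N(p ln p + q ln q)); hitting the cap leaves replicates unabsorbed
  rather than biasing the mean.
- The diffusion quadrature uses `scipy.integrate.quad` with a breakpoint at
  p₀, relative tolerance 10⁻⁸.
- `expected_carrier_excess` uses 400 trapezoid nodes in x by default;
  the τ sum is exact.
- VCF output encodes haplotypes as phased diploid pairs (2i, 2i+1) with
  ancestral allele annotation (AA); reading flips derived status when AA
  equals ALT, and skips (with a report) multiallelic sites, indels and sites
  whose AA matches neither allele. Unphased genotypes in the scan path raise
  `PhasingRequiredError`.

### Limitations

- The simulator conditions on the deterministic frequency trajectory; it
  does not model stochastic trajectory fluctuations of the mutator allele
  itself, which widen the distribution (but not the mean structure) of the
  carrier excess.
- The expected-rate mutation convention matches all first moments (it is
  validated against the forward oracle on means) but is not exact for higher
  moments of per-haplotype counts on unlinked material.
- The diffusion routines cover codominant selection only; other dominance
  regimes are available through the Wright–Fisher simulator.
- The scan's OLS max-vs-IQM fit assumes enough windows (a full region) to
  estimate the relationship; single-window inputs raise `SingularFitError`.
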