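# mutascan

Detection of germline **mutator loci** — genetic variants that raise the
germline mutation rate of their carriers — from phased haplotype data.

A mutator allele multiplies its carriers' mutation rate by a factor φ. While
it segregates, the chromosomal segment linked to it accumulates derived
alleles faster than the population background, leaving a *highly derived
haplotype* signature that persists even after the allele itself is lost.
`mutascan` provides, end to end:

- **`mutascan.theory`** — closed-form expectations for the signature (excess
  mutations per site, mean unrecombined segment length, segment mutation
  excess, the selection coefficient induced by extra deleterious load) plus
  single-locus allele-frequency dynamics: a deterministic recursion, a
  vectorized Wright–Fisher simulator of extinction times, and the matching
  diffusion quadrature.
- **`mutascan.simulate`** — coalescent simulation of haplotype samples with
  and without a mutator allele (built on `msprime`), including a structured
  carrier/non-carrier mutation process, multinucleotide-mutation spiking,
  single- and split-population demographies, and VCF / sample-panel /
  genetic-map I/O.
- **`mutascan.scan`** — the genome scan: in sliding windows, compare the
  *maximum* per-haplotype derived-allele count against the value predicted
  from the interquartile mean (IQM) by a robust linear fit; the scan
  statistic **M = max − fitted(IQM)** flags windows where a few haplotypes
  are far more derived than the bulk. Artifact filters (Hardy–Weinberg
  failure fraction, high-diversity exclusion) and candidate merging included.
- **`mutascan.trios`** — validation in parent–offspring trios: a robust
  (Huber) regression of de novo mutation counts on the parent's number of
  highly derived haplotype copies, with one-sided permutation p-values and a
  Bonferroni-booked battery over loci × cohorts × parent sex.
- **`mutascan.enrichment`** — permutation test for enrichment of DNA-repair
  genes near candidate loci, length-weighted over a callable-space BED.
- **`mutascan.synthetic`** — seeded generators for every input shape (trio
  cohorts, spiked haplotype samples, gene annotations), so the whole pipeline
  is testable offline.

## Worked example

Closed-form expectations at the default parameters (μ = 1.2×10⁻⁸,
ρ = 1.26×10⁻⁸ per bp per generation, φ = 5, allele age g = 20,000
generations):

```text
$ mutascan theory table
quantity        value
extra_mutations_per_site        0.00096
mean_segment_length_bp  7936.51
extra_mutations_in_mean_segment 7.61905
mutator_selection_coefficient   -8e-05
expected_background_derived     7.93651
```

So the mean unbroken segment around the focal locus is ≈ 7.9 kb and carries
≈ 7.6 excess derived alleles — comparable to the ≈ 7.9 expected on the
background, i.e. roughly a doubling of the local derived count.

Simulate a neutral 100 kb sample, spike a mutator-like signature onto 5
haplotypes, and scan:

```text
$ mutascan simulate null --sample-size 50 --length 100000 --locus 50000 \
    --seed 12 --out-vcf null.vcf --out-panel null.panel
$ mutascan synth spike --vcf null.vcf --k 5 --extra 30 \
    --window-start 45000 --window-end 55000 --seed 1 --out-vcf spiked.vcf
wrote 435 sites for 50 haplotypes
$ mutascan scan --vcf spiked.vcf --out scan.tsv
100 windows, 1 candidate loci (M >= 18.0)
$ cat scan.tsv.candidates.tsv
chrom  start  end    group  iqm   max   n_snps  fitted  m      hwe_fail_fraction  excluded_reason
1      45000  55000  all    7.88  41.0  97      14.87   26.13  0.0                none
```

The spiked window is recovered exactly, with M ≈ 26 against the M ≥ 18
reporting threshold.

Validate a locus in trios (synthetic cohort with a true effect of +12
de novo mutations per highly derived haplotype copy):

```text
$ mutascan synth trios --n-trios 100 --delta 12 --carrier-freq 0.3 \
    --seed 4 --out trios.tsv
$ mutascan trio-test --records trios.tsv --n-perm 2000 --seed 0 --out res.tsv
1 tests performed (Bonferroni factor 1)
```

`res.tsv` reports coef ≈ 13.0 extra de novo mutations per copy,
p_perm = 0 (< 1/2001), significant after Bonferroni.

Persistence of the mutator allele itself (N = 10,000 diploids, p₀ = 0.2,
codominant s = −2×10⁻⁴):

```text
$ mutascan theory extinction --reps 500 --seed 7
quantity        value
mean_loss_time  13038.0
se      584.8
n_lost  490
n_fixed 10
mean_absorption_time    13444.9
diffusion_absorption_time       12859.8
```

A weakly deleterious mutator persists ≈ 13,000 generations on average before
loss, consistent with the diffusion approximation.

## Reproduction

`scripts/acceptance.py` reproduces the headline extinction-time benchmark:

```bash
python scripts/acceptance.py --seed 42 --out result.json
# t7 = 12384.9 generations (se 258.6, n_lost 1946, n_fixed 54, 10.1s)
```

which writes `{"t7": {"value": ..., "n": ...}}`.

See `docs/methods.md` for the model assumptions, the derivation of the
semi-analytic carrier-excess prediction used to validate the simulator, and
the numerical choices behind each statistic.
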