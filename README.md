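# nucleovar

Rare-variant discovery and intraorganismal diversity estimation across
populations of haploid nuclei.

## The problem

Some organisms — most prominently arbuscular mycorrhizal (AM) fungi — are
coenocytic: a single mycelium carries hundreds to thousands of haploid nuclei
that divide asexually and mix in a shared cytoplasm. Genetic variation in
such an organism is variation *between nuclei*, and most variant alleles are
rare, often private to a single nucleus. Two sequencing designs probe this
variation, each with its own blind spots:

* **pooled whole-organism sequencing** (spores + mycelium, ~86× mean depth),
  where a site's alternate-read fraction estimates the fraction of nuclei
  carrying the allele, but alleles below ~5 % frequency drown in the error
  floor; and
* **single-nucleus sequencing** after multiple displacement amplification
  (MDA), which sees private alleles directly but covers only ~30–60 % of the
  genome per nucleus, with uneven depth and amplification noise.

`nucleovar` implements the analysis pipeline for comparing these designs:
haploid genotype scoring per nucleus, nucleus- and population-level hard
filtering, alternate allele frequency (AAF) spectra under both designs,
cross-design concordance with uncalled-site classification and a random-site
chi-square null, and intraorganismal diversity estimation (SNP densities,
allele accumulation curves, Chao2 asymptotic richness). A seeded simulator
of nucleus populations under both designs stands in for raw sequencing data
and provides ground truth for validation.

## The core rules and statistics

**Haploid genotype scoring.** A nucleus with `r` reference and `a` alternate
reads at a site is scored

```
MISSING   if r + a < 5
ALT       if a/(r+a) ≥ 0.9
REF       if a/(r+a) ≤ 0.1
MISSING   otherwise        (intermediate fractions are MDA/sequencing noise
                            in a haploid)
```

**Population-level filter.** A site is kept if it has genotype data in at
least 67 % of the analysed nuclei (`⌈0.67·N⌉`, e.g. 9 of 13) and is
polymorphic across nuclei (≥1 ALT and ≥1 REF call).

**AAF, two ways.** Read-based AAF = alt reads / total reads (pooled design);
nucleus-based AAF = ALT nuclei / nuclei with data (single-nucleus design).
Frequencies bin into low (AAF ≤ 0.1667), intermediate (0.1668–0.3333) and
high (> 0.3333).

**Richness.** Treating nuclei as incidence sampling units with per-site
incidence counts `Y_i`, uniques `Q1` and duplicates `Q2`, the accumulation
curve is sample-based rarefaction
`S(t) = S_obs − Σ_i C(T−Y_i, t)/C(T, t)`, extended by the standard
incidence-based extrapolation, with asymptote

```
S_Chao2 = S_obs + ((T−1)/T) · Q1² / (2·Q2)          (Q2 > 0)
        = S_obs + ((T−1)/T) · Q1·(Q1−1) / 2         (Q2 = 0)
```

## Worked example

```python
>>> from nucleovar import (score_nucleus_genotype, summarize_spectrum,
...                        population_support_threshold, build_incidence,
...                        chao2_estimate)
>>> [int(score_nucleus_genotype(r, a)) for r, a in [(1, 9), (9, 1), (3, 3), (4, 0)]]
[1, 0, -1, -1]
```

The four count pairs score ALT (fraction exactly 0.9 is inclusive), REF
(fraction exactly 0.1), MISSING (intermediate fraction 0.5) and MISSING
(depth 4 < 5).

```python
>>> s = summarize_spectrum(counts=(649, 542, 389))
>>> s.total, s.percentages
(1580, (41.1, 34.3, 24.6))
```

Of 1,580 pooled-design SNPs binned 649/542/389, 41.1 % are low-frequency,
34.3 % intermediate and 24.6 % high.

```python
>>> population_support_threshold(13, 0.67)
9
>>> inc = build_incidence({"n1": ["s1", "s2"], "n2": ["s2", "s3"], "n3": ["s4"]})
>>> est = chao2_estimate(inc, with_curve=False)
>>> est.s_obs, est.q1, est.q2, round(est.estimate, 2)
(4, 3, 1, 7.0)
```

Three nuclei observed 4 distinct alternate-allele sites (3 uniques, 1
duplicate); Chao2 estimates at least 7 sites in the whole population.

The full pipeline runs from the command line:

```
nucleovar run-all --seed 1 --out results/
nucleovar simulate --seed 1 --out fixtures/     # VCFs, BEDs, pileups, truth
```

`run-all` writes the spectra, concordance, chi-square, density and richness
tables plus `report.json` and figures.

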