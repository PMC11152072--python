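# Methods

## Model and procedure

The organism is modelled as a population of `N` asexually reproducing
haploid nuclei. Each variant site is a biallelic SNP carried by a fixed
subset of nuclei (its *carrier set*); the site's true alternate allele
frequency is the carrier fraction `k/N`. The pipeline ingests two derived
observations of this population and runs, in order:

1. **I/O** — VCF v4.2 call sets with per-sample RO/AO read counts, labelled
   BED region files (CDS / nonrepetitive / repetitive), per-nucleus ≥5×
   coverage BEDs, and a tidy pileup TSV for naive count lookup at arbitrary
   positions.
2. **Quality/biallelic subsetting** — keep biallelic SNPs with QUAL
   strictly above 30. Strictness is configurable (`qual_strict`) because
   "at least 30" is the other defensible reading of the filter; the
   expression form `QUAL > 30` is taken as authoritative.
3. **Design-specific filters** — pooled: ≥5 reads supporting the alternate
   allele. Single-nucleus: haploid scoring (min depth 5; alternate fraction
   ≥0.9 → ALT, ≤0.1 → REF, else MISSING; both boundaries inclusive),
   then the population filter (data in ≥ `⌈0.67·N⌉` nuclei and ≥1 ALT plus
   ≥1 REF among non-missing calls).
4. **Spectra** — read-based and nucleus-based AAFs, binned low /
   intermediate / high.
5. **Concordance** — exact-key intersection of the two call sets within the
   CDS; classification of each design-exclusive site in the *other*
   design's raw counts (pooled: potential SNP / other variants / invariant /
   no coverage; nuclei: potential SNP / invariant / missing data);
   provenance annotation from the filter audit (initially called but failed
   the nucleus-level or population-level filter vs never called); and a
   random-site null — the same number of uniformly drawn CDS positions,
   ten replicates, one Pearson 2×2 chi-square test per replicate on
   (potential vs other) × (uncalled vs random).
6. **Diversity** — SNP density per genome fraction (whole organism) and per
   nucleus on the fraction∩mask intersection; the alternate-allele
   incidence matrix across nuclei; sample-based rarefaction/extrapolation;
   and the Chao2 asymptote with the `(T−1)/T` small-sample factor.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `min_qual` / `qual_strict` | 30 / strict | phred | marginal-call floor |
| `min_depth_nucleus` | 5 | reads | haploid call needs real depth |
| `alt_fraction_alt_call` / `alt_fraction_ref_call` | 0.9 / 0.1 | fraction | a haploid nucleus is one allele; intermediates are MDA/sequencing artifacts |
| `min_alt_reads_pooled` | 5 | reads | at 86× this bounds detectable AAF at roughly 5 % |
| `population_support_fraction` | 0.67 | fraction | enough nuclei with data to call a frequency |
| `require_ref_allele` | True | — | see design choices |
| bin bounds | 0.1667 / 0.3333 | AAF | thirds of the unit interval at 4-decimal precision |

## What the simulator emulates — and what it does not

`SimulationConfig` defaults encode the study conditions: a 2×10 Mbp genome
carrying 7,400 variant sites (0.37 SNPs/kb, the asymptotic density scale),
200 nuclei of which 13 are sequenced, pooled depth Poisson(86) with a
0.002 per-read error channel, per-nucleus ≥5× coverage drawn uniformly from
30–60 % of the genome as a merged union of exponentially sized (mean 5 kb)
intervals, overdispersed within-mask depth `5 + NegBin(mean 15,
dispersion 3)`, and a 1 % read-level cross-contamination rate between the
carried and non-carried allele at variant sites.

The carrier-count distribution is a mixture: probability 0.76 of exactly one
carrier, otherwise `2 + Geometric(p)` truncated at `N`. The tail parameter
was set to `p = 0.065` by calibrating one observable — the fraction of
detected alternate-allele sites seen in exactly one nucleus — to the
study-reported 76 %; it makes no claim of biological realism beyond that.

Counts at each genomic position come from a position-keyed random substream,
so querying additional positions (the random-site nulls) never perturbs
counts simulated elsewhere, and every output is byte-reproducible from the
seed.

Not emulated: read-level artifacts (chimeric MDA products, mapping error),
indels and MNPs beyond a per-site non-SNP flag, linkage between sites,
coverage below 5× inside the mask (the mask *is* the ≥5× region, so the
simulated 1× and 5× fractions coincide), and real base-composition effects.
Passing tests therefore demonstrate the correctness of the filtering and
estimation logic under the stated stochastic model — not that the model
captures every failure mode of real MDA data.

## Numerical choices

* Percentages and the shared-SNP percentage are rounded half-up to one
  decimal (printed-table convention); AAFs are rounded half-up to four
  decimals before binning, matching bin bounds that leave no gap at four
  decimals. An exact-fraction binning mode (bounds 1/6 and 1/3) is
  available.
* The population support threshold is `ceil(fraction × N)` with the product
  pre-rounded at 9 decimals so binary float noise cannot inflate the
  threshold (e.g. `0.67 × 100 = 67.00000000000001`).
* Rarefaction uses the product form of `C(T−Y,t)/C(T,t)`, exact to within
  float rounding (validated at 1e-9 against exhaustive subset averages).
* Chao2 falls back to the bias-corrected form `Q1(Q1−1)/2` when `Q2 = 0`;
  the extrapolation horizon defaults to `3T`, the conventional reliability
  bound for incidence-based extrapolation.
* A 2×2 table with a zero margin is scored χ²=0, p=1 (no information about
  a difference in proportions); otherwise the Pearson statistic without
  continuity correction (expected counts are large in this design), with
  Yates' correction and a matched-pair McNemar variant available as options.
* Interval arithmetic is 0-based half-open throughout; VCF/pileup positions
  are 1-based, and position `p` maps to interval coordinate `p−1`.
  Density denominators are computed on merged interval unions, never raw
  interval sums.

## Design choices where the design was open

* **"Polymorphic across nuclei"** requires at least one REF call in
  addition to an ALT call by default: a site uniformly ALT in every sampled
  nucleus is reference-divergent but shows no within-organism polymorphism.
  `require_ref_allele=False` restores the laxer reading.
* **The random-site comparison** is interpreted as one independent Pearson
  test per random replicate (ten tests, all reported, the maximum p
  highlighted) rather than McNemar: random sites are not matched one-to-one
  with uncalled sites. The paired variant is provided for callers that do
  construct matched pairs.
* **Random sites are drawn uniformly over region coordinates**, not
  coverage-weighted; positions without reads score as the no-coverage /
  missing-data categories, which the classification keeps separate.
* **Caller emulation**: the simulator converts counts to call sets by
  emitting every truth site with ≥1 alternate read, with QUAL proportional
  to the alternate evidence (10 per read). This reproduces the qualitative
  behaviour that marginal sites fail QUAL filtering without re-implementing
  a Bayesian caller, which is out of scope.

## Problem sizes

The default simulated organism (2×10 Mbp, 7,400 sites, 13/200 nuclei) runs
the full pipeline in ~15 s; the test suite uses a 0.5 Mbp / 250-site
configuration for end-to-end checks and exhaustive oracles only up to
`T = 8` sampling units, where subset enumeration is exact.

## Known limitations

* Chao2 is a lower-bound-style estimator: with 13 sampling units and a
  strongly singleton-skewed incidence distribution it recovers the order of
  magnitude of the true site count, not the count itself.
* Nucleus-based AAFs are quantised by the number of nuclei with data
  (multiples of ~1/13 − 1/9), so spectrum bin shares move in discrete jumps.
* The per-nucleus density denominator trusts the ≥5× mask; real MDA data
  require an external depth profile to build it.
* Multiallelic simulation (`multiallelic_fraction`) is deliberately minimal:
  a second alternate allele with a disjoint carrier subset, sufficient to
  exercise the exclusion paths downstream.
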