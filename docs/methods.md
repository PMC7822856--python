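# Methods

## Model and assumptions

`rohmap` treats ROH detection as a filter-then-segment problem over the
variant sites of a single sample. The underlying assumptions are:

* Autozygous segments are long (≳1 Mb) stretches in which essentially every
  *true* genotype at a variant site is homozygous.
* WES genotype calls are noisy in a characteristic way: false heterozygous
  calls arise from mis-mapping and capture artifacts, and their alt-read
  fraction is skewed away from the 0.5 expected of true hets; true hets at
  adequate depth are binomially balanced.
* Repeat regions produce unreliable calls regardless of genotype and are
  excluded wholesale.
* Variant sites are sparse and clustered (exons), so the segmentation must
  tolerate large variant-free stretches up to a limit (`maxgap`), beyond
  which a single ROH call is no longer supported by data.

Evidence is assessed per call, never per window: a call is removed only for
its own depth/balance/location, so a segment's support degrades gracefully
with noise instead of collapsing.

## Parameters

Variant filter (defaults):

| parameter | default | units | meaning |
|---|---|---|---|
| `min_depth` (`--DP`) | 8 | reads | minimum total depth, inclusive |
| `min_alt_fraction` (`--minpercalt`) | 0.25 | fraction | lower allele-balance bound for hets, inclusive |
| `max_alt_fraction` (`--maxpercalt`) | 0.75 | fraction | upper bound, inclusive |
| `binomial_p` (`--binomial`) | 1e-6 | probability | remove hets with two-sided binomial p below this |
| `min_surviving_variants` | 10,000 | calls | hard stop below this (strict `<`) |

Detection:

| parameter | default | units | meaning |
|---|---|---|---|
| `window` | 7 | variants | sliding-window size |
| `windowthres` | 5 | variants | min homozygous calls per passing window (inclusive) |
| `extend` | 1 | Mb | max outward boundary extension per side |
| `maxgap` | 10 | Mb | split ROHs at longer variant-free stretches (strict `>`) |
| `minsize` | 1 | Mb | final size threshold (inclusive) |
| `minvar` | 25 | variants | final variant-count threshold (inclusive) |
| `minperc` | 88 | % | final homozygous-percentage threshold (inclusive) |
| `include_chrX` | false | — | scan chrX (hemizygous counts as homozygous) |

Evaluation: `min_size_mb` ∈ {1, 5} with a strict "larger than" reading (a
`strict=False` switch covers the inclusive alternative).

## Numerical and design choices

* **Binomial test.** The two-sided p-value is the exact "sum of all
  outcomes no more probable than observed" definition, computed by
  `scipy.stats.binomtest`; results are cached per (alt, depth) pair. The
  test suite pins the definition against an independent integer-arithmetic
  pmf-summation oracle, exhaustively for all n ≤ 200 (agreement ≤ 1e-12).
  A one-sided option exists (`binomial_alternative`) since either reading
  of "a binomial test" is defensible; two-sided is the default.
* **Boundary strictness.** All min/max thresholds are inclusive (a call at
  exactly depth 8 or balance 0.25 survives; an ROH at exactly 88.0 %
  homozygosity is reported). The evaluation size filter is strict, reading
  "larger than" literally. The minimum-variant stop is strict `<` 10,000.
* **Filter order.** Repeats → depth → allele balance → binomial. Each
  criterion is per-call, so the surviving set is order-independent (tested);
  only the per-reason counts in the report depend on the order.
* **Candidate boundaries.** Before trimming, candidates span the first to
  the last *covered* variant (covered = member of ≥ 1 passing window), not
  window midpoints; trimming then anchors both ends on homozygous calls.
* **Extension obstruction.** Extension stops just inside the nearest
  surviving heterozygous call outside the ROH (and at the chromosome end).
  Without this rule, extension would re-admit exactly the het evidence
  trimming removed. A consequence used by the percentage accounting: no
  extension or post-extension merge can bring a het call into an ROH.
* **Post-processing order.** trim → extend → split → final filter. ROHs
  that overlap or abut after extension are merged before splitting; counts
  are recomputed from the filtered table after every boundary change.
* **Gap measurement.** `maxgap` distances are between consecutive
  *surviving* variant positions, not raw VCF records — the filters define
  what counts as data.
* **Homozygosity percentage.** Denominator = all surviving post-filter
  variants inside [start, end]; hemizygous calls count as homozygous.
* **Sex handling.** Hemizygosity is read from GT ploidy, so the male-X rule
  (hemizygous → homozygous) and the female-X rule (ordinary autosome
  treatment) both fall out of the genotypes without a behavioural switch;
  the `--sex` flag and the `infer_sex` heuristic (X het rate < 5 % → male)
  are informational and logged. chrY and the mitochondrial contig are never
  scanned.
* **Multiallelic records** are decomposed per alt allele; zygosity follows
  the GT (1/2 → het for both alts). Half-missing genotypes (./1) count as
  missing and are dropped with a counter. Homozygous-reference records are
  dropped: the algorithm is defined over variant sites.
* **Coordinates.** Internal interval arithmetic is 0-based half-open with a
  single conversion point per direction; all user-facing coordinates are
  1-based inclusive. Gap subtraction precedes the evaluation size filter: a
  gap-spanning ROH's usable extent is what the size should measure.
* **Repeat/gap tracks are inputs** (BED), typically exported from a genome
  browser's repeat and gap tables for the relevant assembly; any BED works,
  and which repeat track to use is the user's choice.

## The synthetic-data generator

The generator emulates the data features detection behaviour depends on:
exon-clustered sites (dense 20 kb blocks alternating with empty 30 kb
blocks; Poisson site counts giving 20 variants/Mb overall, ≈60k sites on a
3 Gb genome — a typical single-sample WES VCF), planted autozygous
segments, background heterozygosity at 0.66 of sites (the het excess of
polymorphic exome sites), gamma-Poisson depth (mean 50, shape 10), binomial
read sampling consistent with the AD fields, a central 3 Mb centromere-like
gap with no sites, and periodic 20 kb repeat intervals whose calls are
deliberately noisy. False heterozygous in-segment calls are emitted at a
configurable rate (default 0.10, within the few-percent-to-30 % band
reported for exome genotyping noise) with alt-read fractions from a Beta
mixture peaked at 0.1 and 0.9 (weights 0.3/0.7, concentration 20) — the
allele-skewed regime of real artifacts, and the regime the balance/binomial
filters target. All randomness flows from one seeded generator; identical
configs produce byte-identical files.

What the generator does **not** model: linkage disequilibrium and
population haplotype structure, reference bias, indel realignment
artifacts, caller-specific QUAL/FILTER behaviour, capture-kit boundary
effects, and balanced (0.5) false hets. Passing the planted-recovery tests
therefore demonstrates the pipeline's mechanics — noise removal, no
fragmentation, correct boundary handling — not clinical performance on any
particular cohort.

## Problem sizes used in tests

Unit tests run on hand-built tables (tens of calls) and 2–6 chromosome
simulations (~13k sites). The acceptance suite uses 22-chromosome,
120 Mb/chromosome genomes (~50k sites, eight planted segments of 2–20 Mb)
— full single-exome scale — and exhaustive/randomised oracle comparisons
(binomial: all n ≤ 200; window seeding: 1,000 random tables of ≤ 500
variants; interval overlap: per-base masks over 100 kb spans). These sizes
exercise every code path at realistic density while keeping the whole suite
under a minute of compute.

## Known limitations

* Uniparental disomy and large hemizygous deletions surface as ROHs but are
  not distinguished from autozygosity.
* The minimum-variant stop (10,000) is calibrated for exomes; sparse gene
  panels will refuse to run unless the threshold is lowered.
* Reference ROH sets are consumed as BED; producing them (e.g. from array
  genotypes) is upstream of this package.
* gVCF blocks and structural-variant records are out of scope (symbolic
  alleles are skipped with a warning count).
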