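# rohmap

Homozygosity mapping directly from WES/WGS variant calls.

## The problem

In patients with recessive conditions — especially from consanguineous
families — the causal mutation almost always lies inside a *run of
homozygosity* (ROH): a long stretch of consecutive homozygous genotypes
co-inherited from a common ancestor. Locating ROHs ("homozygosity mapping")
is how candidate regions are prioritised in medical genetics. ROH callers
built for SNP-array genotypes perform poorly on whole-exome sequencing
(WES) data, whose variant sites are sparse, clustered in exons, and carry a
substantial rate of false heterozygous calls. A single surviving false het
inside a true autozygous segment fragments it, or hides it altogether.

`rohmap` detects ROHs straight from a standard VCF (GATK, samtools/bcftools,
Strelka, ...) by removing unreliable calls *before* segmentation, then
applying a sliding-window scan:

1. **Variant filtering** — drop calls in repeat regions; calls with depth
   `DP < 8`; heterozygous calls with alt-read fraction outside
   `[0.25, 0.75]`; heterozygous calls failing an exact two-sided binomial
   test of alt vs. ref read counts (p < 1e-6 against p=0.5). Stop if fewer
   than 10,000 calls survive.
2. **Segmentation** — a window of 7 consecutive variants passes with ≥ 5
   homozygous calls; maximal runs of covered variants become candidates.
3. **Refinement** — trim ends to homozygous variants; extend each boundary
   by up to 1 Mb (never across a surviving het); split at variant-free
   stretches > 10 Mb.
4. **Final filter** — keep ROHs with size ≥ 1 Mb, ≥ 25 variants and ≥ 88 %
   homozygous variants.

chrX is optional: hemizygous (male) calls count as homozygous; a female X is
treated as an autosome. Detected sets are scored against a reference
(e.g. SNP-array ROHs) at base-pair level:

    sensitivity (%) = overlap(test_all, ref_filtered) / total(ref_filtered)
    specificity (%) = overlap(test_filtered, ref_all) / total(test_filtered)
    F-score = 2 · sens · spec / (sens + spec)

where "filtered" keeps ROHs larger than 1 (or 5) Mb after subtracting
assembly gaps (centromeres, telomeres, short arms, heterochromatin).

A seeded synthetic-exome generator (`rohmap.synthetic_data`) plants
autozygous segments with configurable WES-style noise, so the whole pipeline
is testable end to end without patient data.

## Worked example

`examples/01_simulate_and_detect.py` simulates a 6-chromosome exome
(~13k variant sites) with one 10 Mb autozygous segment on chr2 and 10 %
false-heterozygous noise inside it, then runs detection with defaults:

```
12881 variant sites parsed; 1 ROH(s) detected

chrom   start     end       size_Mb  n_var  %hom
chr2    39912629  50209937  10.30    183    97.81
```

One ROH is reported, covering the planted chr2:40–50 Mb segment (slight
overshoot comes from the bounded boundary extension). Despite 10 % of
in-segment calls being emitted as heterozygous, none survive the
allele-balance/binomial filters, so the segment is **not fragmented** — the
property the variant-level filtering exists to guarantee. The remaining
examples show metric computation (`02`) and the table/plot/gene-panel
outputs (`03`).

The same pipeline is available from the shell:

```bash
rohmap detect --vcf sample.vcf --repeats repeats.bed \
       --lengths chrom_lengths.tsv --out-prefix sample
rohmap evaluate --test sample.HomRegions.bed --ref array_rohs.bed \
       --gaps gaps.bed --min-size 1
rohmap simulate --config sim.yaml --out-prefix simdir
```

`detect` writes a TSV (with a parameter-provenance header), a BED3, a
genome-wide PDF ideogram, an optional gene-panel annotation and a JSONL run
log with per-stage counts.

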