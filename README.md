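# imprintomics

A tested, reusable pipeline for calling imprinted genes from
reciprocal-cross allele-specific read counts, detecting strain-dependent
(allele-specific) imprinting, calling differentially methylated regions
(DMRs) from per-cytosine bisulfite counts, and classifying DMR methylation
variability across a population of strains. A synthetic-data module with
planted truth stands in for sequencing data, so every stage is testable
offline.

## Modules

- `imprintomics.synthetic` — simulators for allele counts, paired
  methylomes, population score matrices and SNP-bearing reads, all driven
  by a `TruthConfig` (same seed ⇒ byte-identical outputs).
- `imprintomics.allelic` — strain-pair SNP list derivation, exact-binomial
  SNP error filtering, read strain-of-origin classification (RNA and
  bisulfite modes), read deduplication, strict per-gene allele counting and
  per-window maternal fractions.
- `imprintomics.imprinting` — the reciprocal-cross exact test against the
  endosperm 2:1 dosage null (maternal fraction 2/3), the imprinting-factor
  and seed-coat filters, MEG/PEG calling with the 2-of-3 replicate rule,
  the parental bias factor b(g) = log2(m+1) − log2(2p+1) and the
  ratio-plane procedure for allele-specific imprinting.
- `imprintomics.methylation` — weighted methylation in 300-nt windows
  stepped by 200 nt, shared-site pairwise Fisher comparison with BH
  correction (CG/CHG: |Δ| ≥ 0.35 over ≥ 3 shared Cs; CHH: |Δ| ≥ 0.10 over
  ≥ 10; q < 0.01), DMR merging/annotation, region weighted methylation,
  metaprofiles and Tukey-HSD strain comparisons.
- `imprintomics.variability` — per-strain DMR scoring (CpG sites ≥ 5
  reads, strains ≥ 5 sites) and the five-class variability scheme
  (very_low / low / not_bimodal / weakly_bimodal / strongly_bimodal, plus
  censoring above 70 of 140 missing strains).
- `imprintomics.association` / `imprintomics.pipeline` /
  `imprintomics.cli` — gene–DMR association (body ± 2 kb flanks), Fisher
  enrichment, TE proximity matrices and a one-command orchestration of the
  whole synthetic scenario.

## Command line

```sh
imprintomics simulate --seed 1 --out-dir sim/
imprintomics call-imprinting --counts sim/allele_counts.tsv \
    --expression sim/expression.tsv --out calls.tsv
imprintomics call-allele-specific --counts sim/allele_counts.tsv \
    --calls calls.tsv --out patterns.tsv
imprintomics call-dmrs --sample-a a.tsv --sample-b b.tsv --context CG \
    --out-windows windows.tsv --out-dmrs dmrs.tsv
imprintomics classify-variability --matrix matrix.tsv --out classes.tsv
imprintomics run-all --seed 1 --out-dir out/
```

Also available: `derive-snps`, `filter-snps`, `classify-reads` (SAM input,
requires the optional `pysam` extra) and `associate`. All tables are TSV;
intervals are BED-style 0-based half-open; cytosine reports use 1-based
positions (chrom, pos, strand, count_methylated, count_unmethylated,
context).

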