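# hrdscore

Genomic-instability scoring and homologous-recombination-deficiency (HRD)
biomarker classification for tumor allele-specific copy-number profiles.

The package computes, from already-segmented allele-specific copy-number
data (SEG-like TSV):

- **Scar scores** — LOH (loss-of-heterozygosity regions > 15 Mb, shorter
  than a whole chromosome), TAI (telomeric allelic-imbalance regions > 11 Mb
  that do not cross the centromere), LST (breakpoints between > 10 Mb
  regions after filtering out regions < 3 Mb), and the combined **GIS**
  (0–100), with HRD-positive / negative / unknown triage at the ≥ 42 cutoff.
- **Zygosity** — gene-level biallelic-loss calling from locus-overlapping
  minor-copy-zero segments, homozygous variants, or multi-variant hits, with
  boundary / assay-failure handling and manual-review style correction.
- **Biomarker groups** — tBRCAm > non-BRCA HRRm (13-gene panel) > non-HRRm
  precedence, germline/somatic/undetermined BRCA origin, and gene-level
  eligibility flags for co-occurring alterations.
- **Synthetic cohorts** — plan-then-construct simulation: event counts are
  drawn first, then a deterministic layout engine builds profiles whose
  LOH/TAI/LST scores equal the planted counts *exactly*, giving every stage
  a recoverable ground truth.
- **Summaries** — median/IQR, pooled-variance t-tests (Welch optional),
  one-decimal percentages, contingency tables, subgroup reports, and
  plot-ready GIS histograms.

Coordinates are 0-based half-open everywhere. The genome build is
configuration, not code: a 3-chromosome toy genome and an hg19-like
22-autosome spec ship as YAML presets (`toy`, `hg19`).

## CLI

```bash
# simulate a cohort with planted ground truth
hrdscore simulate --preset study --n 200 --seed 7 --outdir demo/

# score every sample in a SEG file
hrdscore score --seg demo/segments.seg --genome hg19 --out scores.tsv

# gene-level zygosity ("sim" = packaged loci matching simulated cohorts)
hrdscore zygosity --seg demo/segments.seg --variants demo/variants.tsv \
    --loci sim --genome hg19 --out zygosity.tsv

# full cohort table: group, origin, HRD status, zygosity
hrdscore classify --seg demo/segments.seg --variants demo/variants.tsv \
    --genome hg19 --loci sim --out cohort.tsv

# subgroup summaries + histogram table
hrdscore summarize --cohort cohort.tsv --by group --out report/
```

SEG input columns: `sample chrom start end major_cn minor_cn` (tab-separated,
each sample tiling every represented chromosome). Variant table columns:
`sample gene classification subtype homozygous germline_test`.

## Layout

```
src/hrdscore/
  genome_model.py     genome specs, segments, SEG I/O, normalize, arm split
  scores.py           LOH / TAI / LST / GIS and HRD classification
  zygosity.py         gene-level biallelic-loss calling
  classify.py         biomarker groups, origin, cohort assembly
  synthetic_cohort.py plan-then-construct simulator with exact ground truth
  summarize.py        descriptive statistics and group comparisons
  examples.py         worked-example cohorts (fixed printed margins)
  data/               genome + loci YAML presets
```
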