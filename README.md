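# mircnv

Analysis toolkit for copy-number-variable miRNA loci (CNV-miRNAs):

* **Interval algebra** — 1-based-inclusive region parsing (`chrN:a-b`),
  merge/intersection/overlap/flank arithmetic on 0-based half-open
  internals (`mircnv.intervals`).
* **I/O** — miRBase-style miRNA TSV/GFF-like tables, DGV-style CNV TSV,
  BED, SNP position lists, genome models, and a deterministic calls TSV
  (`mircnv.io`).
* **Statistics** — genome base-coverage fractions, support-stratified
  narrowing of region sets (base depth of records or distinct reporting
  references), an exact lower-tail binomial depletion test of covered
  miRNA loci against the genome-coverage null, a Fisher's-exact SNP
  density comparison inside vs outside loci, and a Lincoln–Petersen
  capture–recapture extrapolation of total polymorphic-CNV coverage
  (`mircnv.stats`).
* **Annotation** — CNV-miRNA calling, locus deduplication across sets,
  minimal supported regions, copy-number/multiallelic summaries, flank
  geometry classes (<5 kb / ≥20 kb), and rule-based prediction of the
  miRNA dosage effect of deletions and tandem duplications over a
  sketched gene model (`mircnv.annotation`).
* **Synthetic data** — seeded generator of genomes, non-overlapping
  miRNA loci, CNV sets with a tunable propensity `rho` to overlap loci
  (rho < 1 = purifying depletion), and SNPs at separate inside/outside
  per-bp rates (`mircnv.simulate`).
* **Fixtures** — packaged transcriptions of the published polymorphic
  and top-validated CNV-miRNA tables (`mircnv.fixtures.paper_fixtures`).

## CLI

All functionality is exposed under a single `mircnv` entry point:

```sh
mircnv coverage  --regions cnvs.tsv --genome genome.tsv
mircnv deplete   --mirnas mirnas.tsv --regions cnvs.tsv --genome genome.tsv --narrow-k 1,2,5
mircnv snp-density --snps snps.tsv --mirnas mirnas.tsv --genome genome.tsv
mircnv call      --mirnas mirnas.tsv --regions cnvs.tsv --set-label polymorphic-SMC
mircnv classify  --mirnas mirnas.tsv --regions cnvs.tsv
mircnv disease-overlap --mirnas mirnas.tsv --regions syndromes.bed
mircnv extrapolate --cov-a 0.012 --cov-b 0.023 --frac-a-in-b 0.39 --frac-b-in-a 0.20
mircnv simulate  --config sim.yaml --out dataset/
mircnv run       --config run.yaml
```

`mircnv run` orchestrates the full pipeline from a YAML config
(exit codes: 0 success, 2 validation error, 3 stage failure):

```yaml
genome: genome.tsv
mirna_table: mirnas.tsv
cnv_sets:
  - {label: polymorphic-SMC, path: smc.tsv, dialect: dgv-tsv}
  - {label: polymorphic-DC, path: dc.tsv, dialect: dgv-tsv}
snp_table: snps.tsv            # optional
thresholds: {min_overlap_bp: 1, narrow_k: [1, 2, 5]}
output_dir: out/
```

Outputs: per-set calls TSV, depletion TSV (one row per set × narrowing
stratum), SNP density report, classification summary, capture–recapture
extrapolation, and a JSON run log with version, config hash and input
checksums.

## Conventions

Printed coordinates are 1-based inclusive; everything internal is
0-based half-open. `chrM`/`chrMT` are aliased to one mitochondrial
label, which is excluded from genome denominators and locus sets by
default.
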