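# mirpopgen

Population-genetic analysis of miRNA hairpin variation, packaged as a
reusable, tested pipeline:

- **Region-aware annotation** — classify variants into seed / mature /
  stem-loop hairpin regions (seed = bases 2–8 from the 5' end of each
  mature arm, strand-aware, seed > mature > stem-loop precedence), flag
  novel variants against a known-sites list, remove novel singletons, and
  compute per-region variant density.
- **Diversity & differentiation** — per-group allele frequencies,
  Watterson's θ by sequence class, population-specific allele (PSMA)
  detection, two-group Weir–Cockerham F_ST in the allele-frequency form
  with small-sample correction, a hierarchical contrast scan (population
  pairs, region pairs, pooled African vs non-African with admixed samples
  excluded), Welch dosage t-tests, and empirical-percentile outlier
  calling (PD at the 95th, HPD at the 99th percentile, both requiring
  Welch p < 0.05).
- **Enrichment** — evidence QC (r < −0.5 in ≥ 2 datasets), bootstrap
  target- and process-enrichment against random same-size miRNA sets
  (add-one empirical p), a hypergeometric GO over-representation test
  with Benjamini–Hochberg adjustment, and a with-replacement disease
  bootstrap.
- **Synthetic data** — Balding–Nichols genotype simulation over a
  simulated hairpin catalog with planted differentiated loci, private
  alleles, and enriched gene sets, so the whole pipeline is testable
  end-to-end with known ground truth and no downloads.

## CLI

```bash
# write a synthetic fixture directory (VCF, GFF3, manifest, tables, truth JSON)
mirpopgen simulate --out fixture/ --seed 1 --n-mirna 20 --n-loci 100

# run the pipeline on it
cat > config.yaml <<EOF
vcf: fixture/variants.vcf
gff3: fixture/mirna.gff3
panel: fixture/panel.tsv
evidence: fixture/evidence.tsv
go: fixture/go.tsv
disease: fixture/disease.tsv
EOF
mirpopgen run --config config.yaml --seed 1 --out results/
```

Subcommands: `simulate`, `annotate`, `popgen`, `enrich`, `run`.
Exit codes: 0 ok, 1 input/config error, 2 runtime error.  Every output
TSV starts with `#` comment lines recording the package version and a
hash of the analysis configuration; `summary.json` collects the headline
numbers (variant counts and SNP/indel split, per-region counts and
densities, PSMA counts and per-population densities, θ per class and
group, F_ST percentile thresholds, PD/HPD miRNA lists, enrichment hits,
disease bootstrap summary).

### Input formats

- **VCF v4.x** (uncompressed is fine); multi-allelic sites are split into
  biallelic records; `./.` is treated as missing.
- **GFF3, miRBase dialect**: `miRNA_primary_transcript` hairpins with
  `miRNA` mature arms linked via `Derives_from`.
- **Panel manifest TSV**: `sample_id, population, region,
  hunter_gatherer, admixed`.
- **Known-sites TSV**: `chrom, pos[, ref, alt]` (allele-aware when
  alleles are given).
- **Evidence TSV**: `mirna_id, gene_id, dataset_id, r`.
- **GO TSV**: `gene_id, process_id`.  **Disease TSV**: `mirna_id,
  disease, direction`.

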