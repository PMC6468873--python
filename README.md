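# twohitpipe

Integrated germline–tumor analysis for tumor-suppressor gene prioritization
on paired whole-exome cohorts. The pipeline combines:

- **Sample QC** — tumors must cover ≥ 70% of shared exome regions at ≥ 10×
  (boundary inclusive).
- **Filter cascades** — germline first hits (depth ≥ 10×, population AF
  < 0.1%, truncating or missense passing ≥ 3 of 6 pathogenicity predictors)
  and somatic second hits (dual ≥ 10× coverage, tumor VAF ≥ 20%, exact
  germline matches excluded), with a per-record `filter_trace` audit log.
- **LOH calling** — folded tumor-VAF deviation at germline-heterozygous
  sites, partitioned by recursive binary segmentation with a seeded
  permutation max-t stopping rule; each segment tested with per-site exact
  binomial tests against Binomial(depth, ½) combined by Fisher's method,
  plus an effect-size floor; per-gene calls by interval overlap, including
  whether the wild-type allele was lost (tumor VAF of the germline variant
  > 0.5).
- **Two-hit pairing** — one candidate per (gene, sample) carrying a filtered
  germline first hit plus a somatic second hit (a distinct somatic SNV/indel,
  a gene-level LOH call, or both), with transparent function-keyword
  prioritization flags.
- **Mutational profiling** — 96-channel pyrimidine-reference catalogs,
  mutations/Mb under a 30 Mb exome assumption (hypermutated ≥ 90/Mb,
  ultrahypermutated > 500/Mb), and signature refitting by non-negative least
  squares against a reference signature matrix (generic or COSMIC-layout TSV).
- **Rare-variant enrichment** — per-variant Fisher's exact tests on
  case/control allele-count 2×2 tables (rare: control AF < 0.1%; pathogenic:
  CADD > 15), with genes highlighted when > 50% of tested variants are
  significant.
- **Synthetic cohorts** — a deterministic generator planting two-hit genes,
  copy-neutral LOH (tumor VAF (1+p)/2 or (1−p)/2 at purity p), signature
  mixtures and per-sample burdens, with full ground truth recorded, so every
  stage is testable without external data.

## CLI

```sh
# generate the default 18-sample synthetic cohort (2 low-QC tumors,
# 5 hypermutated samples, planted two-hit genes)
twohitpipe simulate --outdir cohort --seed 7

# full run: qc -> filter -> loh -> twohit -> signatures
twohitpipe run-all --cohort-dir cohort --outdir results --seed 7

# individual stages
twohitpipe qc --manifest cohort/manifest.yaml
twohitpipe filter --germline cohort/samples/S01/germline.tsv \
    --tumor cohort/samples/S01/somatic.tsv --out-prefix out/S01
twohitpipe loh --sites cohort/samples/S01/het_sites.tsv \
    --genes-bed cohort/genes.bed --out-prefix out/S01
twohitpipe signatures --catalog-snvs cohort/samples/S01/catalog_snvs.tsv \
    --signatures cohort/signatures.tsv --sample-id S01 --out-prefix out/S01
twohitpipe enrich --variants case_control.tsv --out-prefix out/enrichment
```

Exit codes: 0 success, 1 data error, 2 configuration error. All stage
outputs are plain TSV/BED/JSON; re-running with identical inputs and seed
reproduces every file byte-identically.

## Layout

```
src/twohitpipe/
  core.py        domain types, TSV/VCF/BED/manifest I/O, QC rule
  filtering.py   germline and somatic filter cascades + audit traces
  loh.py         segmentation and allelic-imbalance LOH calling
  twohit.py      two-hit pairing, summaries, function prioritization
  signatures.py  96-channel catalogs, burden, NNLS signature refitting
  enrichment.py  Fisher exact case-control enrichment
  synthetic.py   deterministic cohort simulator with ground truth
  pipeline.py    end-to-end orchestration
  cli.py         click command-line interface
```
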