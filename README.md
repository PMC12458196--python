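# cryoclone

Single-cell mitochondrial genotyping toolkit: per-cell heteroplasmy from
strand-specific base counts, ambient-mtDNA background removal using empty
droplets, donor demultiplexing from homoplasmic germline variants, and
clonal lineage tracing from somatic heteroplasmic variants — plus a
synthetic droplet-experiment simulator with full ground truth.

## What it does

The input is a sparse `barcode × position × base × strand` count tensor
(mgatk-dialect `A/C/G/T.txt` + `coverage.txt` + `barcodes.txt` tables) and a
per-barcode QC summary (`singlecell.csv` dialect, mitochondrial fragment
count in column 7 and `peak_region_fragments` in column 18). From these:

- **qc** — named threshold profiles (`default`, `als`, `nb`, `aorta`) with
  the exact printed inequality strictness (e.g. mtDNA depth strictly > 5,
  TSS enrichment strictly > 1.5, ALS upper bound depth strictly < 100);
  background-barcode ranking; the histology tissue score
  `TS = (I + (1−N) + (1−FA)) / 3` and its correlation with QC metrics.
- **genotyping** — per-cell allele fractions `alt/coverage` with
  missingness at zero coverage; mgatk-style variant confidence metrics
  (`n_cells_conf_detected`, strand concordance, mean coverage, log10 VMR,
  pseudobulk heteroplasmy in mean and aggregate modes); the
  high-confidence filter (`≥5` cells, concordance `>0.65`,
  log10 VMR `>−2`, mean coverage `≥5`); a seven-variant artifact
  blocklist; substitution spectra; variant-set overlaps.
- **ambient** — a deterministic, closed-form reimplementation of the
  empty-droplet background-removal concept: per-variant ambient allele
  fractions from pooled empty droplets, per-cell ambient scaling from
  marker variants where the cell is presumed negative, and expected-count
  subtraction (coverage-preserving `reassign` mode or `drop` mode).
- **demux** — bimodal (>99%/<1% at depth; relaxed presets for shallow
  coverage) homoplasmic-variant detection, donor-profile inference by
  Hamming clustering, donor assignment with collision flagging, and
  cross-donor contamination quantification.
- **clonal** — VAF-threshold presence calls (strictly `>20%` by default),
  top-variant selection by pseudobulk heteroplasmy, Jaccard/Ward clone
  clustering, and tie-corrected Kruskal–Wallis lineage-bias tests with
  Benjamini–Hochberg correction.
- **simulate** — a generative model of a two-donor mixing experiment
  (donor-distinct homoplasmic haplotypes, clones with somatic variants,
  shared ambient pool, empty droplets, strand-split counts with
  substitution errors, QC covariates), fully reproducible from a seed and
  emitting complete ground truth for parameter-recovery tests.

## CLI

```sh
cryoclone simulate --seed 1 --out sim/                 # synthetic experiment
cryoclone qc --counts sim/counts --singlecell sim/singlecell.csv \
             --profile default --out kept.tsv
cryoclone genotype --counts sim/counts --cells kept.tsv \
                   --ref sim/reference.txt --out geno
cryoclone remove-background --counts sim/counts --singlecell sim/singlecell.csv \
                            --cells kept.tsv --ref sim/reference.txt --out corrected/
cryoclone demux --counts sim/counts --cells kept.tsv --k 2 --out assignments.tsv
cryoclone clones --counts sim/counts --cells kept.tsv --ref sim/reference.txt \
                 --top 50 --threshold 0.20 --out clones.tsv
cryoclone bias --counts sim/counts --cells kept.tsv --ref sim/reference.txt \
               --groups celltypes.tsv --out bias.tsv
cryoclone run --config pipeline.yaml --out run/        # all stages + manifest
cryoclone report --manifest run/manifest.json --out report/
```

A pipeline config is a small YAML file:

```yaml
seed: 5
simulate: {n_cells_per_donor: 1000, n_empty: 5000}
qc: {profile: default}
demux: {k: 2}
clones: {top_n: 50, threshold: 0.20}
```

## Notes

- All interfaces speak 1-based mitochondrial coordinates; variant labels
  accept both the `mt.1206G>A` and `X301A>C` dialects (`mt.` is canonical).
- The quad-matrix export orders features ref-fwd, ref-rev, alt-fwd,
  alt-rev per variant.
- Simulations in tests use a scaled-down genome (default 2,000 positions)
  so that runtimes stay in seconds; per-position depth and all
  allele-fraction statistics are unaffected by genome length.
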