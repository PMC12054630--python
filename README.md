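# anchorseek

Cross-species anchor-gene correlation screening for single-cell expression
data, with the downstream phenotype-association and promoter/motif analyses,
plus a fully synthetic data generator so the entire pipeline is testable
offline.

The discovery route: in each species, rank every gene by its Spearman
correlation with a chosen *anchor* gene (e.g. a canonical stress marker)
across the cells of one cell type; take the top K per species; transport one
species' list through an explicit homolog table; intersect with the other
species' top K; and validate the conserved candidates with a
stressed-vs-control rank-sum test. Downstream utilities cover clinical
covariate association (Spearman screen plus a univariable-to-multivariable
backward-elimination cascade), an equal-weights collagen composite score,
genomic-interval arithmetic, and IUPAC-consensus / PWM motif scanning.

## Modules

| module | contents |
|---|---|
| `anchorseek.synthdata` | negative-binomial dual-species simulator with a planted anchor-correlated program, partial homolog map, synthetic clinical table, ground truth |
| `anchorseek.io_formats` | Matrix-Market count bundles (mtx + features/barcodes/cell_meta TSV), homolog/clinical TSV, FASTA, BED, JASPAR-style PWM text, JSON run manifests |
| `anchorseek.preprocess` | cell/gene QC filtering, CP10K log1p normalization, metadata subsetting |
| `anchorseek.anchor_discovery` | anchor correlation table, top-K, homolog transport, conserved intersection, Wilcoxon rank-sum DE (exact for small groups) with BH adjustment |
| `anchorseek.pheno_assoc` | Spearman association table, univariable→multivariable regression cascade with audit trail, collagen composite score |
| `anchorseek.regulatory` | 1-based-inclusive genomic intervals (with centralized BED conversion), reverse complement, consensus and PWM motif scanning |

## CLI

Every subcommand writes TSV results plus a JSON run manifest and exits
nonzero with a message on error.

```sh
# synthetic paired-species dataset with ground truth
anchorseek simulate --config cfg.yaml --out sim/

# QC filter a count bundle
anchorseek qc --in sim/species_a --out qc_a/ --min-counts 500 --min-genes 200

# per-gene anchor correlation in one cell type
anchorseek correlate --in sim/species_a --anchor Nppa --cell-type CM --out corr_a.tsv
anchorseek correlate --in sim/species_b --anchor NPPA --cell-type CM --out corr_b.tsv

# cross-species conserved set
anchorseek conserve --corr-a corr_a.tsv --corr-b corr_b.tsv \
    --homologs sim/homologs.tsv --k 50 --out conserved.tsv

# stress response of the candidates
anchorseek de --in sim/species_b --genes conserved.tsv --out de.tsv

# clinical covariate association cascade
anchorseek pheno --clinical sim/clinical.tsv --target SORBS2 --out report/

# motif scan (consensus or --pwm matrix.txt --threshold-bits T)
anchorseek motif --fasta seqs.fa --consensus WGATAA --out hits.tsv
```

A config YAML for `simulate` may set any `SimulationConfig` field, e.g.:

```yaml
n_genes: 2000
n_cells_per_group: 750
n_planted: 30
effect_size: 1.0
homolog_fraction: 0.9
seed: 1
```

## Notes

The synthetic generator's distributional choices (Gamma latent stress score,
log-normal library factors, negative-binomial counts) are explicit stand-ins
chosen for plausibility and testability, not claims about any real dataset;
dropout is implicit in NB sampling at low means (no zero-inflation term).
QC thresholds default to common stand-ins and are fully configurable.
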