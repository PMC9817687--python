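# txprot

Integrative transcriptome–proteome analysis toolkit: filtering and
left-censored imputation of label-free proteomics matrices, moderated-t
(empirical Bayes) differential abundance for RNA and protein layers,
RNA–protein fold-change concordance with studentized-residual
discordance calling, hypergeometric gene-set overlap, and isothermal
dose–response (4PL + Schild regression) Ki estimation with bootstrap
confidence intervals.

A first-class synthetic-data module generates paired multi-omics data
(negative-binomial RNA counts, protein log2 intensities with
abundance-dependent non-detection) and replicate-level dose–response
plates with full ground truth, so the entire pipeline can be exercised
and validated without any external download.

## Layout

- `src/txprot/simdata.py` — synthetic multi-omics + CETSA-style
  dose–response generator with planted ground truth
- `src/txprot/preprocess.py` — TPM, expression/detection filters,
  low-tail imputation, median centering, tryptic peptide counting, iBAQ
- `src/txprot/diffexpr.py` — group-means linear models, empirical-Bayes
  variance shrinkage, moderated t, Benjamini–Hochberg FDR
- `src/txprot/concordance.py` — fold-change pairing, OLS concordance
  fit, discordance calls, abundance correlation, detection overlap, PCA
- `src/txprot/enrichment.py` — GMT parsing and hypergeometric
  over-representation tests
- `src/txprot/schild.py` — 4PL fits, dose ratios, Schild regression,
  pA2/Ki, bootstrap CI
- `src/txprot/io.py`, `pipeline.py`, `cli.py` — file formats,
  orchestration, command-line interface

## CLI

```sh
# synthetic input bundle (TSV/GMT/CSV artifacts + ground truth)
txprot simulate --outdir sim --seed 1

# full chain on synthetic data
txprot all --simulate --outdir run --seed 1

# individual stages on your own files
txprot preprocess --rna-counts counts.tsv --protein prot.tsv \
    --lengths lengths.tsv --design design.tsv --outdir prep
txprot diffexp --matrix prep/protein_imputed.tsv --layer log2_intensity \
    --design design.tsv --condition-a agonist_antagonist \
    --condition-b agonist --timepoint late --out prot_diff.tsv
txprot concord --rna-diff rna_diff.tsv --prot-diff prot_diff.tsv \
    --threshold 3 --out concordance.tsv
txprot enrich --query discordant.txt --universe universe.txt \
    --gmt sets.gmt --fdr 0.25 --out enrichment.tsv
txprot cetsa --input plate.csv --unit nM --n-boot 1000 --seed 7 \
    --out ki.json
```

Expression matrices are features × samples TSV with `NA` for missing
protein cells; designs are TSV with columns
`sample_id condition timepoint replicate assay`; dose–response input is
CSV with columns `agonist_dose antagonist_conc replicate signal`.

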