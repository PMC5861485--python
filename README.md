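# rvinteract

Gene–gene interaction detection for **rare variants**. Rare variants in a
gene are collapsed into a single gene-level genotype under one of three
weighting schemes, gene combinations are then scored with a generalized
multifactor dimensionality reduction (MDR) engine — covariate-adjusted GLM
residuals pooled per joint-genotype cell into high/low risk labels — under
stratified cross-validation, and pairs are ranked by weighted
cross-validation consistency with permutation p-values. A companion
simulation framework generates two-gene interaction datasets under four
penetrance models for power and type-I-error studies.

## Layout

| module | contents |
|---|---|
| `rvinteract.collapse` | `GenotypeDataset`, MAF / functional / effect-based collapsing |
| `rvinteract.measures` | entropy, information gain, balanced accuracy, CVC / WCVC |
| `rvinteract.gmdr` | null-model residuals, H/L cell assignment, classification, k-fold CV |
| `rvinteract.search` | exhaustive combination search, permutation p-values, network export |
| `rvinteract.simulate` | HWE genotype simulation, penetrance models, power & type-I studies |
| `rvinteract.io_cli` | TSV / PLINK `.raw` readers, QC filters, run config, CLI |

## CLI

```bash
# write a simulated two-gene interaction dataset (TSVs)
rvinteract simulate --n 1000 --genes 4 --carrier-or 5 --seed 1 --out-prefix sim

# collapse + exhaustive pairwise search with permutation p-values
rvinteract search \
    --genotypes sim.genotypes.tsv --annotation sim.annotation.tsv \
    --phenotype sim.phenotype.tsv \
    --scheme maf --bins 2 --measure ig --permutations 999 \
    --seed 1 --outdir out/

# collapse only
rvinteract collapse --genotypes ... --annotation ... --phenotype ... \
    --scheme effect --out collapsed.tsv

# simulation studies
rvinteract power --sizes 300,1000,2000 --ratios 0.2,0.6,1.0 --out power.tsv
rvinteract null-study --replicates 500 --permutations 199 --out null.tsv
```

`search` writes `results.tsv` (rank, genes, WCVC, train/test BA, test IG,
p-value), `edges.tsv` (gene-pair network edge list) and `manifest.txt`
(config echo, seed, versions, input checksums). All randomness flows from
`--seed`; identical commands produce byte-identical outputs.

Input dialects: genotype TSV (`sample_id` + one 0/1/2 column per variant,
`NA` missing) or PLINK `.raw` additive text; annotation TSV
(`variant_id  gene  category  conservation`); phenotype TSV
(`sample_id  phenotype  [covariates...]`). QC drops variants by
missing-rate (> 0.05), control-only HWE exact test (p < 1e-6) and MAF
rarity (variants with MAF ≥ 0.01 are excluded).

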