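# copath

Stratified case-control genetics of co-occurring neuropathologies.

Autopsy cohorts stage two pathologies per individual: neurofibrillary-tangle
spread (Braak 0–VI) with neuritic-plaque density (CERAD absent→frequent), and
anatomical Lewy-body distribution (none→brainstem→limbic→neocortical).
`copath` classifies individuals into the four joint categories (AD+LB+,
AD+LB−, AD−LB+, AD−LB−) under competing decision-table schemes, then runs a
complete two-site case-control genetics workflow on top: sample QC and
kinship-based relative pruning, per-variant QC (MAF, exact Hardy–Weinberg
test, missingness, imputation R²), per-site logistic-regression GWAS with
sex, age-at-death and principal-component covariates (with a Firth fallback
for separation), fixed-effect inverse-variance meta-analysis, and a
known-risk-locus concordance/enrichment survey.

A fully synthetic cohort generator with planted ground truth (a per-allele
log-odds effect on a latent AD liability; a Lewy-body process coupled to the
realized liability but conditionally independent of the causal allele) makes
every stage testable end-to-end without access-controlled data, including a
misclassification experiment that quantifies how scheme stringency shifts the
sole-LB contrast's odds ratio.

## Command line

```sh
copath simulate --seed 7 --n-per-site 3600 1400 --n-variants 100 --out-dir sim/
copath classify  --phenotypes sim/phenotypes.tsv --scheme current
copath sample-qc --phenotypes sim/phenotypes.tsv --kinship sim/kinship.tsv --out kept.tsv
copath variant-qc --genotypes sim/dosages.tsv --report dropped.tsv
copath gwas --phenotypes sim/phenotypes.tsv --genotypes sim/dosages.tsv \
            --contrast AD_vs_ctrl --site nacc --out nacc_stats.tsv
copath meta nacc_stats.tsv rush_stats.tsv --out meta_stats.tsv
copath enrich --loci loci.tsv --stats meta_stats.tsv
copath run --config pipeline.yaml
```

`copath run` executes the whole pipeline (exclude → classify → prune →
per-site QC/PCs/association per contrast → meta → locus survey) from a YAML
config and writes per-stage TSV artifacts plus a `manifest.json` whose stage
counts reconcile exactly with the input cohort size.

Classification schemes are data, not code: three built-ins (`current`,
`tsuang`, `kaivola`) ship as YAML decision tables (56 Braak × CERAD ×
LB-status cells plus 5 Lewy-distribution cells), validated for totality at
load; pass a YAML path anywhere a scheme name is accepted to override cells.

## Library

```python
from copath import (
    SimulationConfig, generate_cohort, misclassification_experiment,
    builtin_scheme, classify_frame, tabulate,
    run_site_gwas, meta_analyze, harmonize_and_match, enrichment_summary,
)

pheno, genotypes, kinship, truth = generate_cohort(SimulationConfig(seed=1))
pheno["category"] = classify_frame(pheno, builtin_scheme("current"))
nacc = run_site_gwas(pheno, genotypes, "AD_vs_ctrl", site="nacc")
rush = run_site_gwas(pheno, genotypes, "AD_vs_ctrl", site="rush")
meta = meta_analyze([nacc, rush])
```

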