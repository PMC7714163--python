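# pleioscan

Information-theoretic dependency scans for genotype and child-development
phenotype data: exact plug-in entropy/mutual-information/delta measures on
discrete variables, pairwise and three-way (pleiotropy) scans with pooled
permutation p-values and family-wise error rates, confounder-standardized
mutual information, Gompertz-style nonlinear mixed-effects growth-curve
phenotype extraction, SNP preprocessing (constant/duplicate/high-missing
removal, MI-based collapsing, X/Y separation), integer-programming
selection of low-missingness subject/variable subsets, and a synthetic
cohort generator with planted additive and XOR-pleiotropic effects for
end-to-end validation.

## Layout

| module | contents |
| --- | --- |
| `pleioscan.info` | `JointDistribution`, entropy, MI, interaction information, asymmetric/symmetric deltas, multi-information (bits) |
| `pleioscan.simulate` | `CohortSpec`, HWE genotype simulation, correlated ordinal scales, growth trajectories, planted effects, exact XOR joint |
| `pleioscan.preprocess` | genotype cleaning pipeline + report, 4-bin discretization, categorical screening, MILP subset selection, LD r² |
| `pleioscan.growth` | 5-parameter growth model: `predict`, `fit_population` (alternating Lindstrom–Bates-style estimation), `subject_effects` |
| `pleioscan.significance` | permutation nulls, pooled p-values, FWER, ethnicity-adjusted MI, stratified two-sample K-S |
| `pleioscan.scans` | `scan_pairwise`, `scan_phenotype_dependencies`, `scan_threeway`, `scan_asymmetric`, `scan_snp_interaction`, `scan_sex_stratified` |
| `pleioscan.datatypes` | `GenotypeMatrix`, `PhenotypeTable`, `SubjectTable`, TSV round-trips, VCF import/export |

## CLI

```bash
# synthetic cohort (TSV tables; YAML spec optional)
pleioscan simulate --n-subjects 500 --n-snps 1000 --seed 1 \
    --with-trajectories --out cohort/

# genotype cleaning (constant/duplicate/missing/MI/near-constant/XY steps)
pleioscan preprocess --genotypes cohort/genotypes.tsv \
    --snp-map cohort/snp_map.tsv --out clean/

# growth-model fit and per-subject (linf, alpha, lambda) phenotypes
pleioscan fit-growth --observations cohort/growth_observations.tsv --out growth/

# pairwise SNP x phenotype MI scan with permutation p-values
pleioscan scan2 --genotypes clean/genotypes.clean.tsv \
    --snp-map clean/snp_map.clean.tsv --phenotypes cohort/bayley.tsv \
    --shuffles 1000 --seed 1 --out scan2.tsv

# three-way (SNP, neurodevelopment, growth) symmetric-delta scan
pleioscan scan3 --genotypes clean/genotypes.clean.tsv \
    --snp-map clean/snp_map.clean.tsv --bayley cohort/bayley.tsv \
    --growth growth/growth_phenotypes.tsv --shuffles 1000 --out scan3.tsv

# SNP x SNP interaction around anchor loci; sex-stratified X/Y scan; report
pleioscan interact --anchor rs1000005 ...
pleioscan scan-xy ...
pleioscan report --scan scan3.tsv --top 20 --plot scan3.png
```

Numeric phenotype columns are discretized into four bins (mean and the
medians of the below-/above-mean values) before scanning. Delta scores
are non-positive; tuples are ranked by pooled p-value, then |score|.

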