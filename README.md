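# domgblup

Genomic prediction with **locus-specific dominance weights on heterozygous
genotypes**, plus the standard additive and additive+dominance GBLUP
reference models, a native AI-REML engine, and a cross-validation /
model-comparison protocol. A trait simulator with controllable per-QTL
dominance makes everything testable without external data.

## The method in one paragraph

For each locus, the degree of dominance is estimated from the mean
corrected phenotypes of the three genotype classes:
`raw_d = 2 * (mean_het - x_min) / (x_max - x_min)` where `x_min`/`x_max`
are the smaller/larger homozygote class means. The heterozygote code 1 is
replaced by the clipped weight `C_d` in `[0, 2]` (0 = recessive,
1 = additive, 2 = complete dominance; wider bounds admit overdominance),
and when the homozygote means are reversed the codes 0 and 2 are swapped.
The re-coded matrix feeds a VanRaden-style relationship matrix
`G_ad = M_ad M_ad' / sum(2 p q)` used as the single genetic covariance in
GBLUP ("CADM"). Reference models: additive-only `G` ("AM") and the
two-component `G` + `D` model with the heterozygosity-coded dominance
matrix `D = H H' / sum((2pq)^2)` ("ADM"). During cross-validation the
weights are re-estimated from each training fold only.

## Layout

| module | contents |
| --- | --- |
| `domgblup.data_io` | VCF / PLINK-raw / TSV genotypes, phenotype tables, MAF filter, mean imputation, OLS fixed-effect correction |
| `domgblup.dominance_coding` | genotype class means, degree-of-dominance estimation, weighted re-coding |
| `domgblup.relationship_matrices` | `G`, `D`, `G_ad`, ridge stabilisation, text export |
| `domgblup.reml_blup` | AI-REML (EM warm-up, step-halving, bound pinning), Henderson-MME and direct-V BLUP |
| `domgblup.cv_compare` | fold plans, k-fold CV, predictive ability & bias, paired-bootstrap model comparison with Bonferroni letters |
| `domgblup.simulate` | HWE genotype simulator, per-QTL additive effects and dominance degrees on the 0/δ/2 scale, scenario presets |
| `domgblup.cli` | `domgblup simulate / fit / cv` |

## CLI

```bash
# write a simulated dataset (genotype TSV, phenotype CSV, QTL truth TSV)
domgblup simulate --preset mixed_dominance --n 1000 --m 2000 --seed 1 --out data/

# variance components for all three models + dominance-coding audit table
domgblup fit --genotypes data/genotypes.tsv --phenotypes data/phenotypes.csv \
    --trait trait --models cadm,am,adm --out fit/

# 5-fold x 10-replicate cross-validation with bootstrap comparison
domgblup cv --genotypes data/genotypes.tsv --phenotypes data/phenotypes.csv \
    --trait trait --models cadm,am,adm --k 5 --replicates 10 --seed 1 --out cv/
```

All outputs are plain text (TSV/JSON) and every run writes a manifest of
seeds and options; identical invocations produce byte-identical results.
Exit codes: 0 ok, 2 usage, 3 data error, 4 numerical error.

## Notes on numerical behaviour

* VanRaden-centred `G` is exactly singular (the ones-vector is in its null
  space when frequencies come from the same individuals); prediction
  therefore defaults to the direct `V^-1` route, with Henderson's MME kept
  and tested as an algebraically equivalent alternative on invertible
  matrices.
* At a locus with no phenotypic signal the estimated degree of dominance
  is `1 + Cauchy` (a ratio of class-mean noises), clipped to the bounds.
  This noise floor is intrinsic to per-locus weight estimation and is
  exercised deliberately by the `additive` preset.
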