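# paritysig

Pregnancy leaves a lasting imprint on breast tissue. Cohorts of parous and
nulliparous women show reproducible expression differences — dominated by
immune, inflammation and wound-response genes — in histologically normal
breast, and those differences partly persist in tissue from breast cancer
patients, but essentially only when the tumor is estrogen-receptor-positive
(ER+). `paritysig` is a tested, reusable implementation of the full analysis
that establishes such a result: discover a parity signature in a training
cohort, then quantify how it transfers into independent paired
tumor / cancer-adjacent cohorts, overall and by ER status.

The package is aimed at computational biologists who work with bulk
expression matrices (genes × samples, log scale, any platform after
normalization) and want the whole chain — or any single stage — as plain
functions and scikit-learn-style estimators.

## What it computes

**Signature discovery (SAM).** For gene *g*, the moderated statistic is
d_g = (x̄_parous − x̄_nulliparous) / (s_g + s₀), with s_g the pooled
two-sample standard error and s₀ the fudge factor chosen by the percentile
search that minimises the coefficient of variation of MAD(d) across s-bins.
Significance is assessed against a permutation null: for a deviation
threshold Δ on the sorted statistics versus their permutation-expected order
statistics, FDR(Δ) = (1 + pooled permuted calls)/(B + 1) / (observed calls),
and per-gene q-values are the lowest FDR at which a gene is called
(`SamSelector`, `sam_fdr`).

**Clustering accuracy.** Samples are clustered over the signature genes with
average linkage on 1 − Pearson distance (per-gene median-centered), the tree
is cut at the root, and the cluster richer in parous women yields per-class
parity prediction accuracies (`SignatureClustering`, `cluster_samples`).

**Transfer testing (GSEA variant).** Genes are ranked by the two-sample
t statistic of the parous–nulliparous comparison; a running sum gains
|t_i|^p / Σ_hits |t_j|^p at signature genes and loses 1/(N − N_hits)
elsewhere. ES is the maximum deviation from zero (|ES| ≤ 1); phenotype
permutations give NES = ES / mean |same-sign permuted ES| and a
family-wise error rate FWER = fraction of permutations with
|NES_perm| ≥ |NES_obs|, significant at ≤ 15% (`GseaPermutationTest`,
`permutation_fwer`). Leading-edge genes (hits at or before the ES peak) can
be intersected across analyses to refine a core signature
(`refine_signature`).

**Sample classification (Creighton).** A ±1 template assigns +1 to
signature genes with training fold change above the signature median, −1
below; each sample's per-gene median-centered expression is Pearson-
correlated with the template and called signature-positive iff r > 0
(`CreightonClassifier`, `score_samples`).

**Association.** Calls are cross-tabulated against parity; the
cross-product odds ratio OR = ad/bc with Wald 95% CI
exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d)), tested by Pearson χ² (1 df, no
continuity correction) or by the two-sided Fisher exact test whenever an
expected cell count is below five (`associate`).

A synthetic-data module (`SyntheticConfig`, `simulate_training_cohort`,
`simulate_test_cohort`) generates cohorts with exactly the structure the
pipeline assumes — a planted upregulated block in parous samples, and a
paired test cohort in which the planted signal is attenuated per tissue and
disrupted in ER− subjects — so every stage is testable without downloads.

## Worked example

```python
from paritysig import (SyntheticConfig, simulate_training_cohort, simulate_test_cohort,
                       SamParams, run_discovery, run_transfer, transfer_summary,
                       AnalysisConfig)

cfg = SyntheticConfig(n_genes=2000, n_signature_genes=150, seed=42)
train, train_ann, truth = simulate_training_cohort(cfg)
disc = run_discovery(train, train_ann, SamParams(n_permutations=200, target_fdr=0.05, seed=42))
print(f"signature genes: {len(disc.signature)}  achieved FDR: {disc.sam.achieved_fdr:.4f}")

test, test_ann = simulate_test_cohort(cfg, truth)
analyses = run_transfer(test, test_ann, disc.signature,
                        AnalysisConfig(gsea_n_permutations=500, seed=42))
print(transfer_summary(analyses).to_string(index=False))
```

prints

```
signature genes: 145  achieved FDR: 0.0476
         tissue     stratum    es  fwer_percent  gsea_significant  odds_ratio      p_value
adjacent_normal         all  0.87             0              True       31.59 5.196568e-10
adjacent_normal er_positive  0.89             0              True         NaN          NaN
adjacent_normal er_negative -0.20            63             False        3.89 2.039847e-01
          tumor         all  0.77             0              True        9.15 1.848751e-06
          tumor er_positive  0.82             0              True        9.53 1.344526e-05
          tumor er_negative -0.21            46             False        0.58 6.745849e-01
```

SAM recovers 145 of the 150 planted genes at an estimated FDR below 5%; the
signature is strongly enriched in the tissues where a parity effect was
planted (ES ≈ 0.8–0.9, FWER 0%), and not in the ER− strata, where the
simulation disrupts it (the ER+ adjacent-normal odds ratio is absent because
one cell of its 2×2 table is empty; the Haldane-corrected estimate is
available by flag). The same stages run from the shell:

```sh
paritysig simulate --out study/          # writes TSVs + ground truth
paritysig discover --expression study/training_expression.tsv \
    --annotation study/training_annotation.tsv --out signature.tsv
paritysig associate --counts 37,17,27,49
```

The last command prints the association for a published 2×2 table:
`"or": 3.95, "ci_low": 1.88, "ci_high": 8.29, … "test_used": "chi2"`.

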