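# Methods

This note documents the statistical procedures implemented in `paritysig`,
the defaults they ship with, the numerical choices made where the underlying
methods are under-specified in the literature, and what the synthetic-data
generator does and does not emulate.

## Data model

All analyses operate on log-scale expression matrices (genes × samples,
tab-delimited; log2 intensities or log ratios after platform-specific
normalization, which is out of scope) and a per-sample annotation with
parity (`parous` / `nulliparous`), tissue (`normal`, `adjacent_normal`,
`tumor`), tumor ER status, menopausal status, pairing (`subject_id`) and two
reproductive-history covariates (age at first birth, years since last
birth). Probe-level rows with duplicate gene symbols are collapsed before
analysis — default `max_mean` (keep the probe with the largest mean
expression; ties to the first occurrence), alternative element-wise
`median`. Missing values are imputed per gene by that gene's sample median,
with a logged count; a gene missing everywhere is an error. Signatures are
matched across platforms by gene symbol only, case-insensitively, without
alias expansion; an alignment below 50% of the signature (configurable) is a
hard error naming the missing genes.

## SAM differential expression

The per-gene statistic is d = (mean_parous − mean_nulliparous)/(s + s0),
with s the pooled two-sample standard error and the nulliparous group as
reference. The fudge factor s0 is chosen by the percentile search: candidates
are the 0th–100th percentiles of s in steps of five; the objective is the
coefficient of variation, across contiguous s-quantile bins (100 bins, fewer
for small gene counts), of the 1.4826-scaled median absolute deviation of d;
ties go to the smallest candidate. Fold changes are reported as
2^(mean log2 difference), i.e. geometric-mean ratios.

The permutation null relabels samples B times (default 1000). When at most
B distinct relabellings exist they are enumerated completely; otherwise
balanced relabellings are drawn, each pseudo-group keeping approximately
proportional representation of the two original groups. Selection uses the
canonical one-parameter threshold family: sort the observed statistics,
compute the permutation-expected order statistics, and for a deviation
threshold Δ cut the upper tail at the first sorted statistic whose deviation
reaches Δ (walking up from where the expected order statistics cross zero)
and the lower tail symmetrically; both tails are governed by the same Δ.

**False-discovery estimate.** The FDR attached to a threshold is
(1 + pooled permuted statistics beyond the cuts) / (B + 1), divided by the
number of observed calls. The plus-one-corrected *mean* false-call count is
used deliberately instead of the per-permutation median. With a median, the
single most extreme observed gene on completely null data receives an
estimated FDR of exactly zero whenever its maximum exceeds the median of
the permutation maxima — a probability-1/2 event under exchangeability — so
"select at FDR ≤ 0.01" would fire on the majority of null datasets. The
plus-one mean bounds the estimate below by 1/((B+1)·n_called), restoring a
null selection probability of about 1/(B+1) per tail; the test suite checks
this calibration over 50 seeds. Per-gene q-values are the lowest FDR over
all thresholds that call the gene, which makes selections at nested FDR
targets nested; π0 estimation is intentionally omitted. Per-gene p-values
are permutation tail fractions against the pooled |d| null and are labelled
as such.

## Clustering accuracy

Samples are clustered over the signature genes with average-linkage
agglomeration on 1 − Pearson correlation, after per-gene median centering
(the Eisen/TreeView convention). Samples with zero variance — raw or after
centering — carry no correlation information and are excluded with a
warning. The tree is cut at the root into two clusters; the cluster with the
higher parous fraction is labelled "predicted parous" (ties to the larger
cluster), and per-class accuracies are the fraction of each parity class
assigned to its predicted cluster. The two-cluster cut and the
majority-label rule are this package's choices; nothing in the source method
fixes them. The agglomeration is delegated to scipy; an independently coded
O(n³) oracle in the test suite confirms the merge heights.

## Enrichment (GSEA variant)

Genes are ranked descending by the pooled-variance two-sample t statistic
(parous − nulliparous); Welch is available by flag; ties break by gene
symbol; a zero pooled SE is capped at the largest finite metric with a
logged warning. Walking the ranked list, the running sum gains
|t_i|^p / Σ_hits |t_j|^p at signature genes and loses 1/(N − N_hits)
elsewhere, so the walk ends at zero and |ES| ≤ 1. The enrichment score is
the maximum deviation from zero; an exact tie between a positive and a
negative extremum resolves positive. The weight exponent defaults to p = 1
(increments scale with the strength of association); p = 0 gives the
unweighted Kolmogorov–Smirnov-like walk.

Phenotype labels (never genes) are permuted, B = 1000 by default, with
complete enumeration when fewer distinct relabellings exist. NES divides ES
by the mean magnitude of same-sign permuted scores, and the single-set
family-wise error rate is the fraction of permutations with
|NES_perm| ≥ |NES_obs|, significant at ≤ 15% (reported as an integer
percent). With a single gene set the max-statistic FWER reduces to exactly
this permutation p.

*Known limitation:* for large gene sets scored in very small, unbalanced
strata (a handful of samples in one parity group — the real ER− strata have
four nulliparous patients), the null ES magnitude concentrates in a narrow
band, so the two-sided |NES| comparison becomes nearly degenerate and the
FWER disperses toward 0 or 1 for individual cohorts. At the calibration
scales exercised by the test suite (30-gene sets, balanced 15 + 15 groups;
and 150-gene sets in strata of 20–120 subjects) the FWER is uniform under
the null (Kolmogorov–Smirnov check) — interpret single small-stratum FWERs
with care.

Leading-edge genes are the signature genes at or before the ES peak
(at or after it for negative ES); intersecting leading edges across several
analyses (ordered by the first) refines a core signature.

## Creighton correlation classification

The template assigns +1 to signature genes whose training fold change
exceeds the signature's median fold change and −1 below; genes exactly at
the median receive +1. The median rule is applied verbatim even for
all-upregulated signatures (half the genes then receive −1); a
direction-based fallback (+1 up, −1 down) is available for signatures
without fold changes. Expression is median-centered per gene *within the
dataset being scored* — the scored cohort defines its own centering — and
each sample's centered vector over the matched genes (≥ 3 required) is
Pearson-correlated with the template. Calls are positive strictly for
r > 0; r = 0 and undefined correlations (zero-variance vectors, flagged)
are negative.

## Association statistics

Calls × parity tables are fixed in the orientation a = nulliparous/negative,
b = nulliparous/positive, c = parous/negative, d = parous/positive. The
cross-product OR = ad/bc equals the logistic MLE for one binary covariate;
the CI is Wald on the log scale. Pearson χ² is used without continuity
correction — the uncorrected statistic reproduces the printed reference
p-values (0.0002, 0.015) from their counts, the Yates-corrected one does
not. When any expected cell count is below five, the two-sided Fisher exact
p (the sum of hypergeometric probabilities not exceeding the observed
table's) is computed by exact rational enumeration, so it agrees with brute
force to machine precision. A Wald z p-value on ln OR is reported alongside
for reference. Zero cells make the OR undefined; the Haldane–Anscombe +0.5
correction is strictly opt-in, never silent. Report output rounds OR and CI
half-up to two decimals. One reference bound is only reproducible under
double rounding: for the table (1, 3, 8, 20) the full-precision Wald lower
bound is 0.0751 while recomputing it from the two-decimal OR gives 0.0747;
comparisons in the tests therefore allow 0.006 on that single bound.

## Synthetic cohorts

The generator emulates the structure the pipeline assumes. Each gene gets a
baseline ~ N(7, 1) on the log2 scale; noise is i.i.d. N(0, noise_sd²) per
gene and sample (an optional block-correlation switch adds a shared
within-block factor). A randomly placed block of signature genes receives an
additive log2 shift, drawn uniformly per gene from `log2fc_range`, in parous
samples only. Defaults mirror the study design: 130 training samples
(76 parous / 54 nulliparous), 10,000 genes, a 251-gene block with
log2 shifts in (0.2, 0.9) (linear fold changes ≈ 1.15–1.87, the scale of
the reported top genes), noise SD 0.5; the test cohort has 150 subjects
(79% parous, 78% ER+), two samples per subject sharing a `subject_id`
(adjacent normal + tumor). The planted shift is scaled by 0.6 in ER+
adjacent-normal and 0.4 in ER+ tumor samples (the reported gradient of
enrichment loss from normal to tumor) and by 0.0 in both tissues of ER−
subjects (the reported disruption). All draws come from one seeded
generator; identical configs are bit-reproducible.

What the generator does *not* emulate: platform/batch effects, dye bias,
probe-level structure, copy-number-driven tumor expression,
non-Gaussian heavy tails, and realistic gene–gene correlation beyond the
optional block factor. Passing tests therefore demonstrate the statistical
machinery is correct and calibrated under the assumed model, not that any
particular biological cohort will behave this way.

## Pipeline, strata and reproducibility

Transfer analyses run per tissue × stratum. ER and menopausal strata filter
all samples (unknowns dropped); reproductive-history strata (age at first
birth cut at 25 years, interval since last birth cut at 10 years) restrict
the parous group only, keeping all nulliparous samples as the comparison —
strata are analysed marginally, one variable at a time. A stratum with fewer
than two samples in either parity group is skipped with a logged reason
(the real ER− strata are this small; they must not crash). Every output file
embeds the config hash (output-directory independent) and the RNG seed;
reruns with the same config are byte-identical.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run at desk scale by design:
SAM null calibration uses 50 seeds × (1,000 genes, 20 + 20 samples, 100
permutations); recovery runs once at the full study scale (10,000 × 130,
200 permutations); GSEA null calibration uses 200 runs × (500 genes, 30-gene
set, 15 + 15, 100 permutations); the end-to-end ER contrast uses 40 seeds ×
(2,000 genes, 150-gene set, 150 subjects, 200 permutations). These sizes are
the package's own choices for routine verification; all scale parameters are
plain arguments.
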