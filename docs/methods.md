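# Methods

This note documents the models and procedures implemented in `plastiscore`,
the defaults chosen where the field leaves room, and what the synthetic
validation does and does not establish.

## Scoring model

All scorers operate on a log2-scale genes × samples matrix. Probe-level
microarray data are first collapsed to gene level by the arithmetic mean of
all probes mapped to a gene (a probe annotated to several genes contributes
to each); linear-scale data are transformed as `log2(x + c)` with
pseudocount `c = 1` by default. Genes with any missing value are dropped at
load time with a logged count, because every scorer below assumes complete
per-sample vectors. Gene symbols are upper-cased on load so matrices and
gene sets from mixed-case sources match.

### Single-sample GSEA (ssGSEA)

For one sample, all N genes are ranked by expression (average ranks at
ties). Walking the ranking from top to bottom, the running sum gains
`rank^α / Σ_S rank^α` at each in-set gene and loses `1/(N − |S|)` at each
out-of-set gene; the raw score is the **integral** of the running sum over
all N positions, not the maximum deviation. The weight exponent defaults to
α = 0.75, the de-facto convention of the ssGSEA tool family, and is
configurable. Under `normalization="range"` all samples' raw scores for a
gene set are divided by the cohort's (max − min), giving the normalised
enrichment score (NES). NES values are therefore **cohort-relative**: they
are comparable within one scored matrix, not across matrices. Because the
statistic depends on expression only through within-sample ranks, it is
exactly invariant to strictly increasing per-sample transforms.

Gene-set members missing from a matrix are dropped with a warning; if the
surviving fraction falls below `min_coverage` (default 0.5) scoring
refuses. A set equal to the whole universe is rejected (the out-of-set
decrement is undefined).

### Rank-AUC activity (single cells)

Per cell, genes are ranked descending with a deterministic lexicographic
tie-break on the gene symbol. The recovery curve counts set genes among
the top k ranks for k = 1..⌈f·N⌉ with top fraction f = 0.05 by default;
the score is the area under this step curve divided by the maximal
achievable area, so a set packed at the top of the ranking scores exactly 1
and a set entirely outside the window scores 0.

### EMT metrics

* **76GS** (higher = epithelial): each signature gene g is weighted by its
  Pearson correlation with CDH1 across the cohort, and the per-sample score
  is Σ_g w_g (x_g − x̄_g). Per-gene mean-centring makes the score
  platform-offset free and gives the cohort mean score 0; it also means the
  score, like the NES, is cohort-relative, and weights re-estimated on a
  subsample can differ (direction stability under subsampling is tested at
  n ≥ 30). Spearman weights are available by flag. Zero-variance genes are
  dropped; CDH1 and at least two samples are required.
* **KS** (positive = mesenchymal, range [−1, 1]): per sample, the empirical
  CDFs of the epithelial-list and mesenchymal-list expression values are
  compared on the pooled value grid; with D+ = sup(CDF_E − CDF_M) and
  D− = sup(CDF_M − CDF_E) the score is +D+ if D+ ≥ D− and −D− otherwise,
  so its magnitude equals the two-sample Kolmogorov–Smirnov statistic and
  its sign is positive exactly when the mesenchymal values sit higher.
  When D+ and D− tie to within 1e-9 the sign is ambiguous (crossing CDFs);
  the tie is logged and +D+ is reported. The two-sided KS-test p-value is
  emitted per sample.
* **Epi / Mes / pEMT**: ssGSEA NES on the epithelial list, the mesenchymal
  list and a partial-EMT signature. A hybrid epithelial/mesenchymal sample
  scores intermediate on KS but high on pEMT — the defining behaviour of
  the partial-EMT signature, and a tested property of the pipeline.

### Pathway-activity proxies

AMPK and HIF-1α activities are computed from curated downstream target
genes as the per-sample mean of per-gene z-scores (`mean_z`, the default:
simple and reproducible); a first-principal-component variant is offered,
sign-oriented to correlate positively with `mean_z`. The FAO score is a
weighted sum of z-scored fatty-acid-oxidation enzyme genes with uniform
1/|S| weights by default; enzyme-specific weights can be supplied as a
two-column TSV, which is the faithful path when the published coefficients
are available.

## Signature curation

A gene joins the PD-L1 activity signature when Spearman ρ > 0.5 with
p < 0.01 against the anchor (CD274) in at least 15 of the compendium's
cohorts — strict inequalities, raw p-values (no multiple-testing
correction, matching the published rule). p-values use the large-sample
t-approximation. Cohorts with fewer than 4 samples are excluded with a
warning. The anchor is excluded from the returned set by default: including
it would make signature-vs-CD274 correlations partially circular.

## Correlation meta-analysis

Per dataset, metric pairs are correlated with Spearman's ρ by default
(Pearson per run config). A dataset is classified significant when
|ρ| > 0.3 **and** p < 0.05, both strict; significant datasets are counted
by sign, and datasets significant in two pairs are cross-tabulated into
sign quadrants. p-values are floored at the smallest positive double so
they remain in (0, 1]. Datasets with an undefined ρ (constant metric) are
excluded from the totals with a logged reason. A Benjamini–Hochberg
q-value column is emitted alongside every record table for transparency
but never drives the headline counts.

## Survival stratification

Samples are split at the cohort median of a PD-L1 metric and a glycolysis
metric; "high" means strictly above the median (ties to low; the rule and
thresholds are recorded in the assignment and configurable). P+G+ (high on
both) is compared with P+G− (high PD-L1 only); remaining samples are
excluded. Kaplan–Meier curves, the two-group log-rank test and a single
binary-covariate Cox proportional-hazards fit (Efron tie handling, via
lifelines) report HR, 95% CI, log2HR and p. log2HR > 0 means the P+G+
group carries an increased mortality risk. Monotone likelihood (complete
separation) is returned as a flagged infinite-HR result, not a crash.
`hazard_by_gene` applies the same median-split + Cox machinery to a single
expression column, for forest tables across cohorts.

## Synthetic data: what it emulates

Each sample carries a latent activity vector (epi, mes, pemt, pdl1,
glycolysis, hif1a, oxphos) drawn from a multivariate normal whose
correlation matrix plants the pairwise couplings; the default matrix
encodes PD-L1 +0.5 with Mes, pEMT, glycolysis and HIF-1α, −0.4 with
OXPHOS, Epi ⊥ PD-L1, Epi −0.5 with Mes, and glycolysis +0.5 with HIF-1α.
Samples belong to epithelial/hybrid/mesenchymal populations (default
fractions 0.4/0.2/0.4) that shift the E/M latents by ±1 SD; hybrids get
+0.5 on both plus +1 on the pEMT latent. Member genes read out their
latent linearly: `baseline + 2·latent + N(0, 1)` on log2 scale, with
per-gene baselines N(8, 1). CDH1 is tied to the epithelial latent and the
76-gene list mixes epithelial- and mesenchymal-tied genes, so
CDH1-correlation weights of both signs are recoverable. Compendium cohorts
plant anchor-correlated genes (Pearson loading 0.7) in an exact number of
cohorts; survival cohorts draw exponential event times with a
proportional-hazards multiplier (default 2.0) for P+G+ and independent
uniform censoring whose upper bound is solved by bisection to hit the
target censoring fraction (default 0.2). Every generator is a pure
function of (config, seed).

The generator deliberately does **not** emulate scRNA-seq count noise
(dropout, UMI sampling), batch effects, platform-specific probe noise, or
heavy-tailed expression. Passing tests therefore establish that the
statistics are implemented correctly and recover planted structure under
Gaussian log-scale noise; they do not certify behaviour under real-data
artefacts such as imputation smoothing or cohort batch structure.

## Validation problem sizes

The test suite validates oracle equivalence on 100–200 random fixtures per
scorer (universes of 50–300 genes), curation recovery on a 27-cohort ×
150-sample compendium with 2000 genes, meta-analysis recovery on 50
datasets of 100 samples (80% planted positive coupling), null calibration
on 200 zero-coupling datasets and a 2000-cell noise heatmap, and survival
recovery on 100 log-rank replicates at 150/group plus 200 Cox replicates
at 1000/group. These sizes were chosen so the planted effects dominate
sampling noise while the full suite completes in a couple of minutes.

## Known limitations

* NES and 76GS scores are cohort-relative; comparing them across
  independently scored matrices is not meaningful.
* The KS sign is undefined at exact D+/D− ties; such samples are logged.
* Spearman p-values use the t-approximation, which is anti-conservative
  below ~12 samples; curation already excludes cohorts under 4 samples,
  and smaller cohorts should be interpreted with care.
* The FAO default weights are uniform; results with the published
  enzyme-specific coefficients will differ in scale.
* No multiple-testing correction is applied to the headline counts, by
  design; BH q-values are emitted for readers who want them.
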