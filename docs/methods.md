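# Methods

## Problem setting

A subset of high-grade gliomas over-express the immunotherapy target gene
(by default labelled `IL13RA2`) so strongly that its per-sample log2
expression across a glioblastoma cohort is bimodal: a low-expressing and a
high-expressing tumor population. `gliomix` quantifies that structure and
its consequences across multiple independent expression cohorts:

1. **Over-expression frequency** — the mixing weight of the high component
   of a two-Gaussian mixture fitted to the expression density.
2. **Subtype association** — correlation of the target with mesenchymal,
   proneural, classical, neural and proliferative signature-gene scores.
3. **Grade association** — batch-adjusted fold changes across WHO grades.
4. **Prognosis** — Kaplan–Meier / Cox comparison of expression-stratified
   groups, and a genome-wide per-probe survival screen.
5. **Pathway context** — Fisher's-exact over-representation of correlated
   gene lists in gene-set collections.

## Bimodal mixture model

The density of the target's log2 expression is estimated with a
Gaussian-kernel KDE (Silverman rule-of-thumb bandwidth
`0.9·min(sd, IQR/1.34)·n^(-1/5)`, 512 grid points spanning
`[min − 3·bw, max + 3·bw]`; both are configurable since density defaults
are a modelling choice, not data). The two-component mixture

    f(x) = p·N(x; μ1, σ1) + (1 − p)·N(x; μ2, σ2)

is then fitted to the KDE curve by nonlinear least squares
(Levenberg–Marquardt), **not** by maximizing the sample likelihood — the
estimand is the curve-fit `p`, and an EM maximum-likelihood fit serves only
as an independent cross-check in the tests. Numerical safeguards:

* `p` is fitted on the logit scale and SDs on the log scale, keeping the
  solver inside the valid region without explicit constraints;
* convergence at 1e-8 relative tolerance, max ≈500 iterations; if the
  default start (component means at the 25th/75th percentile of the KDE
  mass, pooled spread, p = 0.5) fails, a 27-point coarse grid of starts is
  searched;
* components are relabelled after fitting so μ1 is always the high mean.

The default variant constrains σ1 = σ2; `select_variant` keeps the
equal-variance fit unless the unequal-variance fit reduces residual SS by
more than 20% (configurable). When the equal-variance residual is already
at numerical zero (below `1e-12·Σ density²`), the nested model wins
outright — a ratio of two zero residuals is noise.

Samples are classified high/low at the expression value where the two
weighted component densities cross (solved between μ2 and μ1, falling back
to the midpoint when no crossing exists there). This equals a posterior
probability 0.5 rule under the fitted mixture. Values exactly at the
threshold go to *low*.

## Subtype signatures

Signature probes are validated on a labeled training cohort. Per probe:
expression is unlogged (2^x), per-subtype linear means computed, and the
subtype ratio is **own-subtype mean / sum of the other subtype means**
(sum, not average — this is the convention of the source protocol, so a
probe flat across four subtypes has ratio 1/3, fold change −3). Fold change
is the signed negative-inverse transform (ratio ≥ 1 → ratio; ratio < 1 →
−1/ratio; the boundary ratio 1 maps to +1). Significance is a Welch
unequal-variance t-test on log2 values (own subtype vs all other labeled
samples), with one Benjamini–Hochberg family per validation run. A probe
is validated when fold change > 2 **and** FDR < 0.05; a probe passing for
two subtypes is assigned to the one with the larger fold change.

Per-sample subtype scores are arithmetic means of validated-probe log2
values (a linear-scale variant is available behind a flag). PCA distances
between signature probes and the target use the probe × probe correlation
matrix, eigenvectors scaled by sqrt(eigenvalue), Euclidean distance in the
first two components (component count configurable).

## Grade association

Pooled cohorts are modelled as `expression ~ grade + study` (additive OLS,
no interaction — interactions would make contrasts inestimable in the
sparse designs this is used on). Group summaries are least-squares means:
model predictions per grade averaged over study levels with *equal* weight
(sample-size weighting available). Contrasts (IV vs I–III, III+IV vs I+II,
IV vs III, histology, recurrence) are linear-contrast t-tests; fold change
is 2^(LS-mean difference). A grade level confined to a single study makes
the design rank-deficient and is reported as such rather than silently
dropped.

## Correlation atlas

Pearson correlations are computed per probe, per array, per cohort against
the target; each cohort's tested probes form one BH family (probes with
fewer than 3 paired values or zero variance are flagged degenerate and
excluded from the family). Silhouette tables keep records with FDR < 0.05,
sorted by subtype block then ascending r, ties broken by probe id.
Gene-level claims use an *at-least-one-significant-probe* rule — probes
are never averaged within genes — and the cross-cohort gene list requires
significant positive correlations in ≥ 4 distinct cohorts (quorum
configurable). Pooled signature correlations concatenate samples across
cohorts un-centered by default (reproducing the source protocol's pooling);
per-cohort mean-centering, which guards against batch-driven inflation, is
available via `center=True`.

## Survival

Kaplan–Meier estimation and Cox regression (single binary covariate, Efron
tie handling, Wald CIs) are delegated to lifelines; median survival CIs
come from the Greenwood log–log bands. The log-rank test is computed
directly from the O−E / hypergeometric-variance sums: the k-sample version
for general use, and a two-group version vectorized across label vectors
so the genome-wide screen is a single pass over thousands of probes. The
screen median-splits every probe within each cohort (ties at the median go
low; per-cohort splitting neutralizes batch shifts), pools cohorts, and
runs an **unstratified** log-rank on the pooled groups (a cohort-stratified
variant would also be defensible; the unstratified pooled test is what the
stage reproduces). Probes are ranked by p ascending; ties break by
|approximate HR − 1| descending (HR approximated as `exp((O−E)/V)` — a
standard score-based estimate; fitting a Cox model per probe would add
nothing to a tie-break), then probe id. Samples missing survival data are
dropped per analysis with a logged count.

## Enrichment

One-sided hypergeometric tail (over-representation) per gene set, BH FDR
across the collection. The universe is caller-supplied (typically all
genes measured on the platform intersection); query genes outside it are
dropped with a warning. Commercial pathway databases publish neither their
universe nor their exact tail convention, so published pathway names are
qualitative context only; the statistic here is the standard documented
one.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume, with
defaults chosen to mirror an eight-cohort glioblastoma compendium:

| parameter | default | meaning |
|---|---|---|
| `sample_counts` | (50, 159, 191, 70, 35, 56, 59, 339) | per-cohort GBM sample sizes, 959 total |
| `p_true` | 0.37–0.73, mean 0.58 | per-cohort high-component weight, one low outlier |
| `mu1`, `mu2`, `sigma` | 9, 6, 0.8 (log2) | component means/SD, 3-unit separation |
| `mes_corr` | 0.20–0.46 | per-cohort target-vs-MES-average correlation target |
| `block_corr` | MES +0.40, PN −0.30, PROLIF +0.30, CL +0.15, NL +0.05 | signed block-average correlation pattern |
| `batch_sd` | 0.3 log2 | per-cohort, per-probe additive shift |
| `hazard_ratio` | 1.34 | high vs low component hazard |
| `median_survival_low` | 15.6 months | low-group median |
| `weibull_shape` | 1.68 | survival shape; 1 = exponential |
| `censoring_fraction` | 0.35 | expected fraction censored |

A single latent factor per sample drives all signature blocks: the latent
is a noisy standardization of the target's expression (`α` chosen per
cohort so the MES block average lands on `mes_corr`), and each block probe
loads on it with a per-block loading derived analytically from the desired
block-average correlation via the K-probe attenuation formula
`corr(avg, latent) = ρ/sqrt(ρ² + (1−ρ²)/K)`. This reproduces the
block-average correlation structure the analyses measure without modelling
per-gene covariance.

Survival is Weibull proportional hazards with uniform-window censoring
(window solved numerically for the design censoring fraction). The shape
default 1.68 is the value at which a 15.6-month low-group median and a
1.34 hazard ratio coexist with a realistic high-group median near 13
months — under an exponential model those two quantities would be
mutually inconsistent (exponential medians scale as 1/HR, forcing either
the HR or the medians off). Shape 1.0 recovers the exponential model. The
survival stream is seeded separately from the expression stream so
outcomes do not depend on how many probes the panel carries.

Grade labels (in the `mixed` scheme) are drawn from design fractions
(default 2/19/29/50% for I–IV, the composition of the two grade-spanning
studies the grade analysis emulates) and the target gene receives per-grade
log2 shifts solved by least squares so the three grade-contrast folds
(3.5, 2.8, 2.5) are jointly approximated — the three printed folds
over-determine four grade means, so the solution is the closest compromise.
Grade–target co-variation therefore comes entirely from these planted
multiplicative effects.

A separate labeled *training* cohort (40 samples per subtype, +3.5 log2
own-subtype shifts) feeds probe validation, mirroring the real workflow in
which a labeled training dataset is distinct from the unlabeled analysis
cohorts. The planted 3.5-unit effect clears the own/(sum of three others)
ratio gate (2^3.5/3 ≈ 3.8 > 2) with margin.

### What the generator does *not* emulate

Affymetrix probe-level noise models, platform-specific probe sets,
multi-probe genes (one probe per gene by default), gene–gene covariance
beyond the single latent factor, non-proportional hazards, informative
censoring, and real clinical covariate structure. Passing tests therefore
demonstrate that the estimators recover the structure they assume — not
that real microarray data satisfies those assumptions.

## Problem sizes used in the validation suite

The test suite and acceptance script run the full default design (959
samples, 8 cohorts), a 2,000-background-probe survival screen, a 100-
replicate Cox coverage study at n = 870, and a 300-fit mixture-recovery
grid (5 weights × 3 sample sizes × 20 seeds). These sizes keep the whole
suite in the minutes range on a single core while leaving the Monte-Carlo
assertions comfortably powered.

## Known limitations

* The curve-fit `p` inherits KDE bias: heavy smoothing at small n shrinks
  component separation and can bias `p` toward 0.5; sample sizes below
  ~100 give noticeably wider error than the likelihood-based EM fit.
* The genome-wide screen's per-probe p-values are exchangeable across
  probes only under per-cohort median splitting; probes with extreme minor
  high/low imbalance (near-constant expression) are effectively untestable
  and rank near the bottom.
* LS means weight grade levels equally regardless of n; with a 2% grade-I
  fraction, the IV-vs-I–III contrast is dominated by grade-I noise — the
  same behavior as the classical two-way-ANOVA protocol it reproduces.
* Enrichment p-values are marginal per set; overlapping sets are not
  decorrelated.
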