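# Methods

## Clinical co-incidence model

The cohort analysis treats a patient registry as a 2×2 contingency of an
exposure (uterine fibroids, UF) against an outcome (endometrial carcinoma,
EC). All quantities are plain conditional frequencies:

    P(EC | UF)  = n_both / n_UF
    P(EC | ¬UF) = (n_EC − n_both) / (N − n_UF)
    relative change = (P(EC|¬UF) − P(EC|UF)) / P(EC|UF) × 100%

The denominator of the relative change is the incidence **among the exposed**,
so a positive value means the outcome is rarer with the exposure. Although the
calculation is sometimes described via Bayes' theorem, direct conditioning on
the four counts is algebraically identical; the identity
`P(EC|UF) = P(UF|EC)·P(EC)/P(UF)` is exposed through the counts and checked in
the tests.

**Display convention.** Percentages are reported to two decimals. The
*displayed* relative change is recomputed from the two rounded conditionals
(e.g. (1.43 − 0.95)/0.95 = 50.53%), the convention used in clinical reporting
of this quantity; the full-precision value (50.43% on the same counts) is kept
on the result object and used by all internal consistency checks. Consumers
who need the exact ratio should read `ratio_change_pct` before calling
`.rounded()`.

**Covariate screening** is ordinary least squares of the 0/1 outcome flag on
age and the other-gynecological-disease flag — a linear probability model, not
logistic regression. This mirrors the clinical analysis design the package
replicates. Limitations are the usual ones: predicted values are not confined
to [0,1] and errors are heteroscedastic, so the p-values are approximate for
rare outcomes; with ~1% outcome prevalence the model is adequate for
screening, not for risk prediction. Inference is t-based (95% CIs and
two-sided p-values on the residual degrees of freedom), with an intercept and
0/1 coding of binary covariates. Rank-deficient designs raise an error naming
the offending columns (a constant covariate is collinear with the intercept).

## Effect sizes and pooling

The per-study effect size for a gene is the raw difference of mean log2
expression, case minus control (the log2 fold change), with the Welch
(unpooled) sampling variance `s²_case/n_case + s²_control/n_control`
(sample variances, ddof=1). Raw log2 differences — not standardized mean
differences — are used because the screening thresholds are calibrated on the
fold-change scale: 2^0.59 ≈ 1.5 and 2^−1 = 0.5 correspond to 50% increases
and decreases. Welch's form is robust to unequal group variances at the tiny
group sizes typical of array studies (3–9 per arm). Zero sampling variance
(possible only in degenerate toy inputs) is floored at 1e−8 and flagged.
When a matrix carries several rows per gene symbol (probes), the row with the
highest mean expression is kept.

Fixed-effect pooling is the inverse-variance average; the between-study model
is DerSimonian–Laird:

    w_i = 1/v_i,  Q = Σ w_i (y_i − ŷ_fixed)²,  C = Σw − Σw²/Σw
    τ² = max(0, (Q − (k−1)) / C),  w*_i = 1/(v_i + τ²)

with `I² = max(0, (Q − (k−1))/Q) × 100`. Per-gene model choice follows the
conventional heterogeneity screen: the Q statistic is referred to χ²(k−1) and
the random-effects model is used when its p-value is below `het_alpha = 0.10`.
With a single contributing study the fixed model is forced (with a warning).
Pooled 95% CIs use the 1.96 normal multiplier and the p-value is the
two-sided normal test of `pooled/se`; no small-k adjustment (t or
Knapp–Hartung) is applied. Study weights are reported normalized to sum to 1.

**Known consequence of these choices.** Because the weights are built from
*estimated* variances (≈18 df per 10+10 study), `E[1/v̂] > 1/v` and the pooled
standard error is slightly underestimated; with six 10+10 studies the 95% CI
covers a planted effect about 93.5% of the time rather than 95%, and the
nominal 0.05 test rejects about 6% of null genes. This is the textbook
behaviour of normal-multiplier inverse-variance pooling at small group sizes,
not an implementation artifact; the tolerance bands in the acceptance checks
(93–97% coverage, 0.05±0.02 type-I) accommodate it.

Genes measured in only a subset of studies are pooled over that subset (k
varies per gene); genes measured nowhere are reported with k=0 and null
statistics. A Benjamini–Hochberg column is emitted as supplementary output;
the replica screen deliberately uses the raw p, as its criteria specify.

## Significance screen

A gene is significant iff k ≥ 3, pooled p < 0.05, and pooled LFC > 0.59 or
< −1 (strict inequalities). The asymmetry of the thresholds is intentional
and preserved: on the log2 scale a 50% increase (+0.59) and a 50% decrease
(−1) are not mirror images. Rejected genes carry the first failed criterion
(study count, then p, then magnitude) so rejection logs are interpretable.
The screen is a pure partition: every input gene lands in exactly one of
up/down/rejected, and tightening any single criterion can only shrink the
significant sets.

## Moderator regression

Per-study effect sizes for one gene are regressed by OLS on total sample
size (numeric), region (dummy-encoded, alphabetically first level as the
reference so replication is deterministic) and study date (numeric year),
with intercept. This is plain regression on effect sizes, not a formal
meta-regression with τ² re-estimation. With k = 4–6 studies and three encoded
covariates the design is near-saturated; fits with k ≤ (covariates + 1) are
returned as a degenerate flag rather than estimates, and estimable but barely
identified fits are reported as-is — their boundary p-values are a property
of the design, not evidence.

## Gene-set overlap

Overlap of two candidate sets within a background universe of size N is
tested against the hypergeometric null: p = P(X ≥ observed overlap), the
upper-tail sum, via Fisher's exact test. The test is one-sided (enrichment)
by default because overlap "significance" here is directional; two-sided is
available. The background size is a required input — no universe is silently
assumed. The sample odds ratio uses the Haldane–Anscombe +0.5 correction only
when a table cell is zero, flagged in the output. Symbols are case-normalized
before set operations.

## Synthetic data generator

The generator emulates the three data sources downstream stages consume, with
exact planted truth:

* **Cohort** — UF ~ Bernoulli(p_UF); EC ~ Bernoulli(p_EC|UF or p_EC|¬UF)
  conditional on the drawn UF flag, optionally tilted on the log-odds scale by
  age and/or the other-disease flag. Ages are truncated normal
  (mean 43.98, SD 9.64, minimum 23 years by default) — truncation reproduces a
  reported mean/SD/minimum jointly, which a plain normal cannot. The
  other-disease flag is independent of EC by default (the clinical analysis
  found no association); a dependence parameter exists for power studies.
  Defaults reproduce the registry scale: 4537 patients, P(UF)=1259/4537,
  P(EC|UF)=12/1259, P(EC|¬UF)=47/3278. An exact-count constructor
  (`cohort_from_counts`) builds a deterministic cohort with specified
  contingency counts, since any arrangement with the same four counts yields
  identical conditional incidences.
* **Expression studies** — simulated directly on the log2 scale: control
  samples `N(baseline_g, noise_sd²)`, case samples
  `N(baseline_g + LFC_g + u_g, noise_sd²)` with `u_g ~ N(0, τ²)` a per-study,
  per-gene deviation — the additive random-effects generating model the
  pooling stage assumes. Default noise_sd = 0.5 log2 units (a typical
  within-group SD for array data after normalization); baselines are
  N(8, 2²) log2 units. The canonical six-study layout uses the sample splits
  5/5, 5/5, 4/4, 3/6, 3/6, 3/9 with US/Japan regions and dates 2003–2017,
  matching the collection design the analysis emulates. A total sample size
  below 8 warns (the collection-time design filter) but does not error, so
  toy examples remain possible.
* **Gene sets** — two lists over a shared background with an exactly planted
  intersection size.

What the generator does **not** emulate: probe-level intensities,
normalization artifacts, batch effects, correlated genes, missing data beyond
per-study gene absence. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated generating model, not robustness
to real-array preprocessing noise — which is also why the pooled values from
the six real public series are treated as external validation rather than a
reproduction target.

## Problem sizes and numerical choices

Monte-Carlo checks use: 1000 replicates for CI coverage and for the null
type-I rate of the pooled test (six 10+10 studies, noise_sd 0.5); 1000
replicates for the OLS null rejection rate; 200 replicates for the
age-effect power check (cohorts of 2000, log-odds slope 0.1/year); 100
replicates for heterogeneity-detection and unbiasedness checks; cohort
marginal fidelity at n = 200 000 against 3 binomial SEs. Exhaustive Fisher
validation enumerates every feasible 2×2 table with background ≤ 30
(~45 000 tables). Oracle agreement tolerances: 1e−10 for closed-form pooling
and hypergeometric sums, 1e−8 for OLS against the normal equations, 1e−12
for exact rational arithmetic.

Tie-breaks and degenerate inputs: equal conditional incidences give a
relative change of exactly 0; a zero co-incidence count makes the relative
change undefined and is reported as an "infinite relative change" error;
LFC thresholds are strict inequalities, so a gene at exactly 0.59 is
rejected; τ² truncates at 0, where random-effects pooling coincides exactly
with fixed-effect pooling.

All randomness flows through `numpy.random.default_rng` seeded from explicit
integer seeds; identical configuration and seeds reproduce every output file
byte-for-byte.
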