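# Methods

This note documents the statistical procedures, the defaults chosen where
the analysis protocol left a choice open, what the synthetic-data
generator does and does not emulate, and the numerical conventions. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Compositional treatment

Abundance tables are closed row-wise to relative frequencies; a row of
zeros is rejected rather than imputed. The core microbiota is the k
genera with the largest mean relative abundance across samples, re-closed
after selection (k = 10 for descriptive summaries, k = 9 for the
regression model, both configurable). Ranking ties at the selection
boundary are broken lexicographically by genus label so the core is
deterministic.

**Zero replacement.** Multiplicative simple replacement: zeros become δ,
each nonzero part x in a row with z zeros is scaled to x·(1 − zδ). This
preserves the unit sum exactly and the ratios among observed parts —
the property that matters for log-ratio analysis. Default
δ = min(½·smallest nonzero relative abundance, ½/D²); δ must satisfy
0 < δ < 1/D. Count-model (Bayesian-multiplicative) replacement is out of
scope.

**ilr basis.** The default is the Helmert-type sequential binary
partition in table part order: row j contrasts the geometric mean of the
first j parts against part j+1, scaled by √(j/(j+1)). Any orthonormal
log-contrast basis yields identical Wilks Λ, F, p-values, Aitchison
distances and back-transformed predictions (asserted to 1e-9 in tests);
the basis affects only the intermediate coordinates, so no interpretation
is attached to individual coordinates.

## Regression and MANOVA

Ordinary least squares per ilr coordinate on the design
[1, SpO2, delivery, SpO2·delivery], delivery coded 0 = vaginal /
1 = cesarean (results are coding-invariant; predictions are produced per
level). Terms are assessed sequentially (Type I) in the order SpO2,
delivery, interaction, matching the reporting order of the study's MANOVA
table. The hypothesis SSCP of a term is the drop in residual SSCP when
its column joins the preceding ones; the error SSCP is the full model's.
Wilks' Λ is converted by Rao's F approximation, which is exact for the
1-df hypotheses used here, with df (p, ν_e − p + 1); for a single
response this reduces to the univariate sequential ANOVA F (asserted
against statsmodels). With the cohort's 13 patients and a 9-genus core,
p = 8 and ν_e = 9, so every term's F has df (8, 2): the design is at the
edge of identifiability, and the tests deliberately pin this df structure.

**Prediction.** Design rows are built per SpO2 grid point (default
85–100 % in 0.5 steps) and per delivery level, multiplied by the fitted
coefficients, and mapped through the inverse ilr (a numerically
stabilised softmax), so predicted rows are strictly positive and sum to
one by construction. Grid points beyond the observed SpO2 range ± 2
percentage points are logged as extrapolation but computed — composition-
versus-oxygenation curves intentionally extend past the data.

## Clustering

Patient compositions are imputed, ilr-transformed and clustered
agglomeratively on Euclidean distances of the coordinates (= Aitchison
distances, making the result invariant to per-sample sequencing depth).
Default linkage is complete (configurable: ward, average); merge-distance
ties follow scipy's smallest-index rule, so the tree is deterministic
given input order, and partition recovery is order-invariant (tested).
Cutting at k labels groups 1..k by decreasing size, then leaf order. The
"visually extracted" third cluster of the original analysis is
operationalised as a k = 3 cut plus a manual-override mechanism that
records sample, old label, new label and provenance; no attempt is made
to automate visual judgment. Heatmap export keeps genera whose maximum
relative abundance reaches the threshold (default 0.1, inclusive),
columns in dendrogram leaf order. Cluster-wise clinical comparisons use
two-sided Wilcoxon rank-sum tests — exact enumeration when the pooled
pair has n ≤ 20 without ties, normal approximation with tie correction
otherwise — reported raw (descriptive stance); a Holm adjustment is
available behind a flag.

## Cohort test battery

Fisher's exact test uses the point-probability two-sided rule (sum of
hypergeometric probabilities not exceeding the observed table's). The
Welch test is computable from mean/SD/n summaries with Welch–Satterthwaite
df and is identical to the raw-data test applied to those summaries. The
two-sample proportion test is the 2×2 chi-squared with the Yates
correction clipped at zero per cell, max(0, |O−E| − 0.5) — the clipping
matters: when both proportions are within the correction the statistic is
exactly 0 and p = 1. The r×c chi-squared drops zero-total rows/columns
first (an all-zero category has undefined expected counts) and warns, not
errors, on expected counts below 5. P-values are held at full precision
and rounded to two decimals only in report output.

## Perfusion physiology

FTOE = (SpO2 − SO2)/SpO2 with the regional SO2 argument explicit — the
caller chooses the liver or periumbilical probe; the package does not
guess. Negative FTOE (regional SO2 above SpO2) is physiologically
possible measurement noise and is logged, not rejected. Global gut
perfusion is v̄·π(d/2)²·60 in ml/min from portal-vein mean velocity (cm/s)
and diameter (cm); the tissue-probe velocity values in arbitrary units
are never fed into this formula. Per-kg normalisation divides by body
weight.

## Synthetic-data generator

The generator's defaults are the study conditions: 13 CHD and 30 HC
subjects; delivery split apportioned exactly per group (6/13 and 17/30
cesarean) and shuffled; feeding, maternal nutrition, antibiotics and GBS
colonization drawn at the published proportions; birth weight, gestational
age and sampling age from the published mean/SD; patient SpO2 ~
N(90.9, 3.4) truncated to (70, 100], controls without SpO2; patients
contribute 2–3 replicate samples (visits), controls one.

Compositions follow a logistic-normal model: ilr mean = group baseline
+ (SpO2 − 90)·effect + delivery effect, plus isotropic Gaussian noise
(σ = 0.5), inverse-ilr to the simplex, multinomial counts at depth 50,000.
This is exactly the family under which the ilr linear regression is
correctly specified, which is what makes parameter recovery and null
calibration meaningful checks. SpO2 is centred at 90 % inside the
generator only so baselines stay interpretable; the fitted slope is
unaffected. Optional planted clusters replace the baseline by one of
several ilr centers, apportioned exactly and shuffled. Zero inflation
models sequencing dropout: nonzero cells below 1 % relative abundance are
zeroed with probability 0.05, so the imputation stage has real work.
Perfusion records use regional SO2 = a + 1.15·SpO2 + N(0, 0.4) with
region-specific intercepts, and Doppler/anthropometric values drawn from
the published cohort ranges.

What the generator does **not** emulate: taxonomic-profiler error,
read-level noise, overdispersion beyond the logistic-normal, longitudinal
dynamics between visits, or correlation between the microbiota and the
perfusion measurements. Passing tests therefore demonstrate correctness
of the statistical machinery under its own assumptions, not robustness of
the original biological findings to real-data artefacts.

## Validation experiments and problem sizes

`neocoda.validation` runs four experiments (used by the test suite and
the acceptance script):

* **Null calibration** — 500 simulated null cohorts at the study's size
  (n = 13, 9-genus core): the SpO2 MANOVA p-value must be uniform
  (Kolmogorov–Smirnov at α = 0.01) with type-I rate ≈ 0.05 at α = 0.05.
* **Permutation oracle** — the analytic Wilks-F p is compared with a
  2,000-permutation p of the same statistic on 5 seeded datasets. This
  runs at n = 50 (same D = 9 model structure): at n = 13 the
  unconditional F-based p and the data-conditional permutation p differ
  systematically by up to ≈ 0.05 — a known finite-sample effect, not an
  error in either — so agreement within Monte-Carlo error is only a
  meaningful check once n is moderate.
* **Slope recovery** — 100 replicates at n = 200 with a planted SpO2
  effect of 0.05 per % on every coordinate; all fitted slopes must lie
  within 3 standard errors of truth in ≥ 95 % of replicates.
* **Planted-cluster recovery** — 20 seeds, 3 clusters at 13 subjects,
  centers on distinct ilr axes with between-center distance ≥ 10× the
  within-cluster spread; the k = 3 cut must match the planted labels at
  adjusted Rand index 1.0 for every linkage.

These experiments run with zero inflation off: they probe the inferential
procedure under the model family it assumes, while the dropout-plus-
imputation path is exercised separately by the pipeline and unit tests.

## Numerical conventions

Rows are accepted as "on the simplex" within 1e-9 and re-closed exactly
after every simplex-altering step. The ilr round-trip and the
isometry-vs-Aitchison-distance identity hold to 1e-10; basis invariance
of MANOVA to 1e-9. Table orientation is never guessed — the caller states
taxa-rows or samples-rows. Missing metadata fields are allowed but any
operation needing one fails loudly. All numeric output files carry 6
significant digits; tests that compare against printed two-decimal
p-values round, not truncate.

## Known limitations

The df (8, 2) regime means the cohort-sized MANOVA has very low power and
its significance flips easily with the data — the package reproduces the
df structure and calibration, not any claim of robustness at that sample
size. Replicate merging (`mean_relative` by default) is a convention, not
a study-documented procedure. The Wilcoxon exact/asymptotic switch
follows sample size and ties, so p-values near the switch boundary can
shift slightly between datasets. The generator draws perfusion and
microbiota independently, so cluster-versus-perfusion comparisons on
synthetic data are null by construction.
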