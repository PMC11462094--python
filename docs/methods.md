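# Methods

This note documents the models and procedures implemented in `actiphen`,
the defaults they use, and what the synthetic cohort does and does not
emulate.

## Data model

A cohort consists of daily wearable records (participant, date, device
brand, steps, distance in miles, MVPA minutes, activity kcal) and biannual
questionnaires (six PROMIS T-scores; SCDAI for Crohn disease or SCCAI for
ulcerative/indeterminate colitis; sociodemographic and treatment
covariates). Scoring bands follow the instruments: SCDAI < 150 remission,
150–219 mild, 220–450 moderate, > 450 severe; SCCAI in [0, 19] with ≥ 2.5
indicating active disease. PROMIS T-scores are consumed as given
(population mean 50, SD 10); item-level scoring is out of scope. SCDAI
values above 600 are accepted with a warning since the index is unbounded
above.

A "day used" is any calendar day with at least one non-missing activity
metric; no minimum step count is required. This is the permissive reading
of device use — a stricter rule (e.g. steps > 0) would only matter for
devices that report exact zeros, which the generator never emits.

## Preprocessing

Cleaning blanks offending cells and keeps the row, so one implausible
metric does not discard the other metrics of the same day. Two passes:

* **Hard bounds** — MVPA ≥ 1440 min (a full day), steps > 200,000,
  distance > 150 miles, calories > 20,000 kcal.
* **Tukey fences** — per feature, cohort-wide over all daily values:
  quartiles by linear interpolation, values outside
  [Q1 − 1.5·IQR, Q3 + 1.5·IQR] blanked. Fences are computed over the pooled
  cohort (not per participant or per brand): it is the conservative literal
  reading of applying Tukey's rule to the daily data, and grouping is a
  config-level change away. The default applies the fences once; the
  `until_stable` option iterates fence computation to a fixed point, which
  makes cleaning exactly idempotent (a single pass is only approximately
  so — rerunning it moves ~1% of cells because the fences tighten on their
  own output).

Windows cover the `window_days` (default 42) days strictly before — never
including — questionnaire completion. Per-feature means use only days where
that feature is present. Eligibility requires
`days_used ≥ ceil(min_coverage × window_days)` (21 of 42 at the default
50%). A 42-day span always contains exactly 30 weekdays and 12 weekend
days, which the wear summary uses as capacities; for other window lengths
capacities are computed from the calendar. When questionnaires are closer
together than the window length, each day is attributed to the nearest
following questionnaire so no day is double-counted.

## Aggregation-lag selection

For each candidate lag (1, 2, 4, 6, 8, 12, 24 weeks) windows are rebuilt at
7·lag days under the same coverage rule, and mean steps are
Spearman-correlated with SCDAI (CD windows) and SCCAI (UC/IC windows)
separately. Spearman uses average ranks for ties and the t approximation
`t = ρ·sqrt((n−2)/(1−ρ²))` for p-values; zero-variance inputs yield a
flagged NaN. The two indices are combined as the subgroup-size-weighted
mean of |ρ| — the selection must use both subtypes and this is the natural
pooling; both per-index values are always reported alongside. Ties break
toward the shorter lag; lags with fewer than 10 eligible pairs are skipped.
Each (window, score) pair enters once with no within-person adjustment,
matching how such scans are usually run; the resulting p-values are
therefore anticonservative when participants contribute many windows.

## Clustering core

k-means/Lloyd with k-means++ seeding (`D²` sampling), `n_init = 10`
restarts keeping the lowest-SSE run, `max_iter = 300`, and convergence when
the Frobenius norm of the centroid displacement drops below `tol = 1e-4`.
Assignment ties break to the lowest cluster index and an emptied cluster is
reseeded at the point farthest from its own centroid — both standard
choices that make runs deterministic given a seed. The seed defaults to 0
for reproducibility; `seed=None` gives OS-entropy seeding.

Silhouettes are computed over all windows (each window is one point):
`a_x` excludes the point itself, `b_x` is the minimum mean distance to
another cluster, singletons score 0. K is selected as the argmax of the
average silhouette over K = 2…5 (ties to smaller K); the SSE-vs-K elbow
table is emitted for inspection but not auto-detected. The feature subset
is an exhaustive search over all subsets of size ≥ 2 of
{steps, distance, MVPA minutes, calories, weekday days, weekend days}.

Clustering runs on **raw, unscaled** features by default: that is the
procedure being reproduced, and on strongly inter-correlated activity
features scaling changes little. Note the consequence: with steps in the
thousands, Euclidean distance is effectively one-dimensional in steps.
Z-score and min-max scaling are available behind a flag. With K = 3,
clusters are labelled low/moderate/high by ascending centroid steps; other
K fall back to `level_1..level_k`.

## Association and transitions

The unit of analysis is the window (period), not the participant, so
participants with several questionnaires contribute several observations
and no repeated-measures correction is applied — this reproduces the
published analysis design and its caveat. Continuous variables use one-way
ANOVA computed from sums of squares (degenerate inputs are explicit: all
values identical → F = 0, p = 1; zero within-group variance with unequal
means → flagged, p below machine precision); a Welch variant exists behind
a flag but is off by default. Categorical variables use Pearson chi-square
with expected counts from the margins and a warning when any expected cell
is < 5. Disease indices are profiled only within their own subtype. Raw
p-values at α = .05, no multiplicity adjustment.

Consecutive questionnaire pairs qualify when their gap lies in [90, 270]
days (a tolerant reading of "biannual"; config-exposed). Disease-score
change is SCDAI for CD and SCCAI for UC/IC, never mixed; pooled percentages
use all pairs. Per-cell changes get two-tailed paired t tests
(`t = mean(d)/(sd(d)/√n)`, df = n−1) with tests suppressed for cells under
5 pairs (small-cell reporting). Percentages are rounded to one decimal in
reports only.

## Synthetic cohort

The generator emulates a 430-participant IBD wearable cohort with three
latent activity phenotypes:

* **Phenotype chain.** Each participant completes `max(1, round(N(3, 2)))`
  questionnaires 182 days apart; the phenotype follows a Markov chain with
  initial distribution (0.337, 0.460, 0.203) and a transition matrix
  row-normalised from the reference cohort's pooled transition counts
  (self-transitions average 0.678; low↔high moves 1.2% of pairs).
* **Wear.** Each day in the window is worn with probability 37.3/42.
* **Features.** Window-level targets are truncated-at-zero normals with
  the reference per-phenotype moments (steps 5000.3/8229.5/12319.4 with
  SDs 1062.4/1033.0/1899.6, and analogously for distance and MVPA). The
  window SD is decomposed into a participant shift (one shared latent per
  participant, SD = 0.3 × the between-phenotype spread of means, inducing
  within-person and cross-feature correlation), day-level noise
  (proportional to the person's level, CV 0.35 — activity variability
  scales with activity), and a window residual sized so the observed
  window-mean SD matches the configured SD. Because a zero-truncated
  normal's mean exceeds its location, the generator solves for the
  location that makes the post-truncation mean equal the target; configured
  means are matched in expectation, while truncation shrinks the realised
  SD of high-CV features (MVPA; its reference CV ≈ 1.3 makes this
  unavoidable for any zero-truncated symmetric model).
* **Calories** are affine in daily steps (126.1 + 0.05/step) plus N(0, 80)
  noise, calibrated to the reference daily mean of ~520 kcal.
* **PROs and covariates** draw from per-phenotype reference moments
  (SCDAI clipped at 0, SCCAI to [0, 19]), so lower activity co-occurs with
  worse scores; age/BMI/disease duration condition on the first phenotype
  and treatment indicators on the current one.
* **Background days.** When daily history beyond the 42-day window is
  generated (for lag scans), each period gets one persistent background
  activity level drawn from the phenotype mixture independently of the
  disease state: activity is linked to disease only inside the window, and
  background activity is persistent rather than white noise.

What the generator does **not** emulate: device-brand measurement bias,
circadian/within-day structure, seasonality, missing-not-at-random wear
gaps, zero-inflation of sedentary days, and the right-skew of real activity
distributions beyond what zero-truncation induces. Tests passing on this
cohort show the pipeline recovers planted structure under a well-specified
noise model; they do not certify behaviour on real registry data.

`planted_lag_config` is a purpose-built variant for lag-recovery testing:
tight phenotype spreads, strong phenotype–score coupling, no participant
shift, day-noise CV 1. Under the default (reference-moment) coupling the
true steps-vs-disease correlation is only ≈ −0.15, and adjacent lags differ
by less than sampling noise at realistic cohort sizes, so the default
cohort cannot discriminate lags reliably; the planted-lag variant makes the
6-week optimum sharply identifiable (shorter lags lose day-averaging
precision, longer lags are diluted by background days).

## Numerical choices and problem sizes

Truncated-normal sampling uses the inverse-survival-function form, stable
even when nearly all untruncated mass lies below zero; the location
correction solves a scalar monotone equation by bisection with an
asymptotic Mills-ratio guard. Quantiles interpolate linearly. Reported
percentages round half-even to one decimal.

The test suite and acceptance script run on cohorts of 80–1500 participants
(up to ~55k device-days), 100-instance exhaustive k-means comparisons at
n ≤ 8, and 1000-replicate null calibrations; these sizes give stable
3-standard-error margins for every stochastic assertion while keeping a
full run in a few minutes on one CPU.

## Known limitations

* Raw-feature Euclidean clustering is dominated by the steps axis; on the
  reference-moment mixture the adjusted Rand index against latent truth is
  bounded by the one-dimensional Bayes classifier at ≈ 0.74 (the package
  measures ≈ 0.73–0.80 across seeds). Scaled clustering would recover more
  (3-D Bayes ≈ 0.88) but changes the procedure and, on these moments,
  shifts the silhouette-selected K to 2.
* ANOVA and lag-scan p-values ignore within-participant correlation, as in
  the reproduced design.
* The transition analysis describes movement; it makes no causal claim
  about activity changing disease activity or vice versa.
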