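# Methods

`wakemark` re-implements a metabolomic biomarker-discovery analysis for
acute sleep deprivation as a tested, configurable pipeline. This note
documents the models, the synthetic data the pipeline is validated
against, the numerical choices, and the limits of what the tests show.

## The scientific problem

During a constant routine (extended wake under controlled posture, light
and feeding), plasma metabolite levels move for two distinct reasons:
homeostatic drift — monotone change with accumulated time since wake
(TSW) — and circadian cycling driven by the internal clock. A deployable
biomarker of sleep deprivation should track the sleep homeostat and *not*
the clock, because field samples are collected at arbitrary and unknown
circadian phases. The pipeline therefore (1) screens every LC-MS feature
for linear and 24-h cosinor trends, (2) keeps features that drift
consistently across individuals while excluding those that cycle in a
substantial minority of them, (3) reduces the survivors to a small
candidate panel by three-stage random-forest selection, (4) validates the
panel by hold-out classification (well-rested, TSW 0–16 h, vs
sleep-deprived, TSW 24–38 h) and TSW regression on an independently
collected experiment, and (5) checks that the candidates reverse (or stop
changing) after a night of sleep in a matched-control protocol.

## Trend models

Per feature, per participant and pooled at the group level:

* **Linear:** OLS `y ~ 1 + t`, two-sided t-test for the slope.
* **Cosinor:** OLS `y ~ 1 + cos(2πt/24) + sin(2πt/24)`; amplitude
  `A = √(β_c² + β_s²)`, acrophase `atan2(β_s, β_c)·24/2π (mod 24)`,
  significance from the joint F-test of both harmonic coefficients.

The two models are fit separately (no shared linear covariate); a linear
trend therefore leaks slightly into the amplitude estimate when sampling
spans a non-integer number of cycles (bias ≈ 0.03 in amplitude units per
0.01/h of slope over the 2–38 h span; exact orthogonality holds only in
the continuous-time limit). Group-level fits are plain pooled OLS;
moderated test statistics would change nothing material at ~200 samples
per experiment. Benjamini–Hochberg FDR is applied across features,
separately per (level, model family) — and per participant at the
individual level. Constant series are reported as slope 0 / amplitude 0
with p = 1.

Category bins for the between-experiment χ² comparison are
{linear-only increasing, linear-only decreasing, cycling-only,
cycling+linear, neither}; zero columns are dropped and the Pearson
statistic is computed without continuity correction.

## Preprocessing

1. **Zero filter:** drop features with strictly more than 20% zero values
   (configurable; zeros are always treated as left-censored, never true).
2. **Imputation:** each zero is replaced by a draw from a normal
   truncated to (0, observed minimum). Location and scale come from
   quantile matching: the observed nonzero values are treated as the
   upper tail of a normal censored at fraction c, giving
   `min_obs = μ + σ·z(c)` and `median_obs = μ + σ·z(c + (1−c)/2)`. This
   is a deliberate simplification of quantile-regression left-censored
   imputation; a deterministic half-minimum mode is available. Fully
   censored features fall back to half the global minimum with a warning.
3. **Median normalization:** each sample is scaled so its across-feature
   median equals the median of per-sample medians. The reference choice
   is a global scalar and cannot affect rank- or forest-based results.
   One real side effect is documented below (synthetic-data section).
4. **Within view:** per participant, per feature z-scores (sample sd,
   ddof = 1) across that participant's time points; zero-variance cells
   become 0 with a logged warning. The between view stops after step 3.

For hold-out evaluation the test experiment adopts the training
experiment's retained feature universe (information flows train→test
only; no statistic of the test data feeds any training-side decision).

## A priori filter

A feature becomes a modeling candidate iff, on the training experiment's
within view, all of:

* raw p < 0.05 for the linear fit, with slope sign equal to the majority
  sign among significant participants, in **strictly more than 50%** of
  participants;
* group-level linear p < 0.05 with the same sign;
* cosinor raw p < 0.05 in **no more than 25%** of participants
  (strictly more than 25% excludes).

Raw p-values (not FDR) are used inside the filter; the characterization
FDR is a separate reporting concern. Every failure records its reasons
(insufficient linear fraction / no direction consensus / group not
significant / group direction mismatch / cyclic).

## Forest engine

Selection and modeling use a bagging layer over scikit-learn decision
trees (`forest.OobRandomForest`) that exposes the out-of-bag machinery
the method is defined in terms of: OOB error (training accuracy is
1 − OOB error, with a Clopper–Pearson CI on the OOB-correct counts), OOB
permutation importance (mean decrease in accuracy for classification,
percent increase in MSE for regression), and class scores as the
fraction of trees voting sleep-deprived. Defaults for modeling: seed 123,
mtry 3, 500 trees, terminal node size 1 (classification) / 5
(regression). All randomness flows from the seed; runs are bit-stable.

## Three-stage variable selection

Replicated importance ranking (40 forests of 300 trees by default) gives
per-variable importance mean and sd. **Thresholding** keeps variables
whose mean importance clears the minimum of a CART fit (unlimited depth,
leaf size 1) of importance sd against rank — with replicated forests a
noise variable's mean importance almost never exceeds the smallest sd in
the ranking. **Interpretation** grows nested models in importance order
(30 forests of 100 trees per size) and keeps the smallest model whose
mean OOB error is within one sd of the minimum; under redundant
predictors this correctly truncates to the smallest sufficient set.
**Prediction** adds interpretation variables stepwise (10 forests of 100
trees), admitting a variable only when it beats the mean absolute
first-difference of the OOB errors of the interpretation-rejected
models (0 when none exist). mtry defaults to ⌈√p⌉ inside selection
because p changes per stage. Consensus across the four analysis routes
(classification/regression × within/between) keeps variables present in
a strict majority of interpretation sets, ranked by frequency then mean
importance, trimmed to the configured panel size (default 5).

## Evaluation

Confusion-matrix rates are computed in exact rational arithmetic and
named by their conditioning event (true-WR rate tn/(tn+fp), true-SD rate
tp/(tp+fn), predicted-WR rate tn/(tn+fn), predicted-SD rate tp/(tp+fp));
undefined rates are reported absent rather than zero. Binomial CIs are
Clopper–Pearson (beta-quantile form) — the convention is identifiable
from a perfect 16-sample participant, whose lower bound is
0.025^(1/16) = 79.4%. AUC is the trapezoid/Mann–Whitney estimate with a
DeLong asymptotic CI (seeded bootstrap available). Test-set R² is the
signed 1 − SSE/SST and may be negative. The specificity-targeted
operating point maximizes sensitivity subject to specificity ≥ target.
Combination scans test every candidate subset of size ≥ 2 (26 subsets
for 5 candidates) with a one-sided exact binomial test of test accuracy
against the majority-class no-information rate, Bonferroni-corrected
across subsets.

## Recovery after sleep

Candidate z-scores in 4-h blocks before/after the habitual sleep time
are contrasted per (metabolite, protocol) with a linear mixed model
(value ~ period, random participant intercept; statsmodels MixedLM).
Designs: clock-matched (sleep deprivation 2–6 h vs 26–30 h TSW; control
day-2 2–6 h vs day-3 2–6 h) and evening/morning (12–16 h vs 26–30 h;
control day-2 12–16 h vs day-3 2–6 h). Degrees of freedom use the
between-within approximation df = n_obs − n_participants − 1
(Satterthwaite df are not available in the mixed-model backend; for this
balanced two-period design the approximation is standard), with a paired
t-test on participant means as deterministic fallback for singular fits.
FDR is applied across all metabolite×protocol tests within a design.
The meal-timing comparison fits value ~ TSW × protocol with a random
participant intercept on data re-z-scored **within the compared
well-rested day** — z-scores spanning the full 38-h wake episode would
mechanically shrink the sleep-deprivation slope and fabricate an
interaction.

## Synthetic data

The generator emulates the study design: two sleep-deprivation
experiments (12 and 11 participants, bi-hourly sampling at TSW 2–38 h —
19 scheduled times; 10 and 11 samples missing completely at random,
giving 218 and 198 samples) and a 3-day matched control (5 participants,
bi-hourly 2–16 h TSW on two days; 15 samples per 3-point pre/post
block). Missing samples are removed as an exact count
(round(rate·n_scheduled)) so the study's sample bookkeeping is
deterministic.

Feature model: intensity = baseline·e^(participant offset)
+ slope·(TSW − 20 h) + A·cos(2π(clock − φ)/24) + noise, floored at 0.
Baselines are log-normal (log-mean 10, log-sd 0.5, natural-log
relative-peak-area scale); participant offsets are multiplicative
(log-sd 0.3); the homeostatic term is centered at mid-protocol so a
decreasing feature starts above baseline and decays through it instead
of crashing into the nonnegativity floor (contrasts and z-scores are
unaffected by the centering). In the matched control TSW restarts at
each wake (the homeostatic term resets); the cosine runs on continuous
clock time. Default effect sizes, chosen once as plausible for features
that survive an abundance-based screen: |slope| uniform 1–3% of baseline
per hour with random sign, circadian amplitude 10–30% of baseline,
residual noise 8% of baseline. Default class mix 2% linear / 25%
circadian / 5% mixed / 68% null. Left-censoring zeros a feature's values
below its empirical lod quantile (10% of features draw a heavy quantile
of 25–45%, placing them beyond the 20% zero filter; the rest draw
0–8%).

What the generator does **not** emulate: batch drift beyond a scalar
per-experiment factor, correlated feature modules, isotopes/adducts,
heteroscedastic or heavy-tailed noise, participant-specific circadian
phase, and any real metabolite biology. Passing the planted-truth suites
therefore demonstrates that the *pipeline machinery* recovers the
structures it is designed for at realistic sizes and noise levels — not
that the original study's accuracies would replicate on new plasma data.

One emergent artifact worth knowing about: when a large fraction of the
panel cycles (e.g. the 25% default), the per-sample median itself
oscillates, so median normalization injects a small shared anti-phase
rhythm into every feature. Group-level cosinor tests can then flag many
null features. The a priori filter is robust to this by construction —
its cyclic-exclusion rule operates per participant, where the injected
rhythm is far below detection — which is precisely the robustness the
filter is meant to provide against shared time-of-day confounds.

## Problem sizes in tests and the acceptance script

Unit tests run on compact studies (4–6 participants, ~50 features) with
reduced forest replication; the acceptance suites use the training-scale
design (12 participants, 19 times, 1000 features mixed 20 linear / 50
circadian / 30 mixed / 900 null) for filter recovery, the paper-default
selection parameters (ntree 300/100/100, replicates 40/30/10) for the
selection-recovery fixture, and full 500-tree forests for hold-out
modeling. Filter recovery is quoted among features that enter the filter
(i.e. survive the zero-value pre-filter), since an upstream QC drop is
not a filter error. The selection-recovery fixture plants five
*complementary* informative variables (each a weak classifier on its
own, ~1.3 sd class separation) plus five correlated shadows and ten
noise variables: five redundant copies of one strong signal would be —
correctly — truncated by the interpretation step and say nothing about
recovery.

## Known limitations

* The mixed-model p-values use an approximate df, not Satterthwaite;
  with ~130+ residual df in the study-sized designs the difference is
  negligible, but small designs will be slightly anti-conservative.
* Cosinor screening fits no joint linear covariate (kept as an option),
  so strongly drifting features can mask their own cycling and vice
  versa; the mixed class exists in the generator to expose this.
* The CLI covers simulate / preprocess / discover / recover; the finer
  stages (characterize, filter, select, combos) are exposed as library
  functions rather than subcommands.
* YAML configs must quote the `null` class key (bare `null` is parsed as
  a YAML null); the CLI normalizes this.
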