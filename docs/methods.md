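# Methods

## The screening problem

Oscillometric blood-pressure monitors observe, per cuff inflation, a short
sequence of pressure pulse waves whose peak times yield pulse-to-pulse
intervals (PPIs). Screening for atrial fibrillation (AFib) from a *single*
measurement means deciding, from ~22 intervals, whether their pattern is
"irregularly irregular" (AFib) rather than regular (sinus) or irregular but
*patterned* (premature contractions, PCs). The package implements that
decision end to end: simulation of the three regimes, the oscillometric
front end, distributional features, an AdaBoost.M1 classifier, and the
diagnostic-accuracy statistics used to validate such screens.

## Rhythm models

All generators take an explicit seed (`numpy.random.default_rng`); nothing
uses global random state, and equal seeds give byte-identical serialized
output.

**Sinus** — intervals are `mean_interval` + N(0, `jitter_sd`²), truncated
positive by redrawing. Defaults: mean 0.75 s (80 bpm), jitter 0.02 s, a
typical resting heart-rate variability; the resulting irregularity index
(SD/mean ≈ 0.027) sits far below the AFib regime.

**AFib** — i.i.d. draws with mean `mean_interval` and SD `cv ×
mean_interval`, default cv = 0.13, the irregularity index reported for AFib
in the screening literature (97.5 ms at 0.75 s). The default family is a
Gamma distribution parameterized by mean and cv — positive support and the
mild right skew of real AFib RR interval data; a truncated normal is
available via `distribution="truncnorm"`. Independence between consecutive
draws models the "irregularly irregular" ventricular response; the lag-1
autocorrelation of generated intervals is ~0.

**Premature contractions** — each beat carries a premature flag (every 2nd
beat for bigeminy, every 3rd for trigeminy, i.i.d. Bernoulli(`pc_probability`)
for the random pattern). A flagged beat's interval is scaled by the coupling
fraction c (default 0.7); the interval after a flagged beat is scaled by
(2 − c), the full compensatory pause, so each premature/pause pair conserves
two base intervals and the zero-jitter bigeminy mean is exactly the base
interval. A premature beat immediately following another keeps its coupling
interval (the pause is overridden). With this convention the expected
fraction of short (coupling) intervals in the random pattern equals
`pc_probability` exactly.

**Missed beats** — `inject_missed_beats` replaces k randomly chosen adjacent
interval pairs by their sums, emulating skipped pulse detections. Total
duration is conserved exactly; the series shortens by one interval per
merge.

**Cohorts** — `generate_dataset` draws per-measurement interval counts from
N(22, 3²), rounded and truncated at 10, matching the ~22 ± 3 pulses a single
cuff inflation captures. The default study composition (also the
`PipelineConfig` default) is 1,000 AFib / 500 sinus / 250 bigeminy /
250 random-PC measurements — balanced AFib vs non-AFib, with the non-AFib
half split between the regular and the patterned-irregular confounders.

## Oscillometric front end

`synthesize_ppw` places one Gaussian pulse (σ = `pulse_width`/2, default
width 0.08 s) per beat at the cumulative interval times — n intervals, n+1
pulses — optionally modulated by a raised-cosine "oscillometric bell"
(0.4–1.0) mimicking the oscillation envelope during cuff deflation, with
per-pulse attenuation (`amplitude_dips`) and additive Gaussian noise.
`detect_pulse_peaks` is a functional stand-in for a proprietary detector:
local maxima (scipy `find_peaks`) with a refractory spacing (default 0.3 s)
and an amplitude gate at `threshold_fraction` (default 0.3) of the rolling
maximum (3 s window). Defaults were chosen so that the clean round trip
synthesize → detect → extract recovers intervals to within two sample
periods at 100 Hz, and a 10× attenuation of one pulse falls below the gate,
merging exactly one interval pair into its sum — the missed-pulse phenomenon
the robustness analysis exercises.

The bench emulation (`cufflink_experiment`) reproduces the accuracy
experiment done with a constant-rate pulse simulator: 30 repeats of a
constant 0.75 s series at 250 Hz, intervals perturbed by Gaussian device
timing error (default SD 11 ms, calibrated to the ~10–15 ms per-measurement
PPI SDs such bench runs report). The timing error is applied to the
*intervals* (per-beat timing error accumulates into the interval) rather
than independently to each peak time, so the per-measurement interval SD
directly reflects the device jitter parameter; jittering times independently
would inflate it by √2.

## Features and the clustered standard deviation

Features of one measurement (schema `pulseaf-features-1`): mean, max, min,
SD, C_STD (seconds); percentiles 5/25/50/75/95 of *mean-normalized*
intervals (dimensionless, heart-rate invariant, linear interpolation);
cv = SD/mean; cstd_ratio = C_STD/SD (defined 1 when SD = 0); and the
interval count. All variances use the population (1/N) convention so that
C_STD = SD holds exactly in the single-cluster case. Higher moments
(kurtosis etc.) are deliberately excluded. Measurements with fewer than 10
intervals (below mean − 3 SD of the observed counts) are rejected as
insufficient; the appropriate minimum count for reliable single-measurement
screening is an open question.

Clustering is 1-D sorted-gap splitting: sort the multiset, break wherever
adjacent values gap by more than the threshold. The published C_STD
definition references an external construction without details; sorted-gap
splitting realizes the described behavior with a single parameter, kept
configurable (`gap_threshold`, or `relative_gap` × median, default 0.12 —
about 90 ms at 0.75 s). At that default a 22-beat AFib draw forms one
cluster in ~69% of seeds and at most two in >90% (the Gamma tail
occasionally sheds an outlier); bigeminy always splits into its two tight
clusters. The discrimination survives the occasional split: the median
cstd_ratio is > 0.8 for AFib and < 0.2 for zero-jitter bigeminy.

A caveat the tests document: far above the modeled regime (cv ≳ 0.2) the
spread becomes so wide that sorted-gap clustering fragments it, pulling
C_STD back down; the margin-vs-irregularity sweep is therefore monotone
only up to cv ≈ 0.13.

## Classifier

AdaBoost.M1 over depth-limited CART-style trees. Per round: fit a tree to
the weighted sample; weighted error ε_t; stop if ε_t ≥ 0.5; β_t =
ε_t/(1 − ε_t); multiply the weights of correctly classified rows by β_t and
renormalize; vote weight ln(1/β_t). A perfect round (ε_t = 0) gets a capped
vote weight ln(10⁶) — large enough to dominate, finite so margins stay
defined — and stops boosting. Prediction is the weighted vote; the margin
(signed, normalized to [−1, 1]) is positive for AFib and exact ties are
called non-AFib, the specificity-preferring choice for a screening tool.

Tree fitting is exhaustively deterministic: features scanned in schema
order, thresholds at midpoints between adjacent distinct sorted values,
weighted Gini impurity, ties broken by the first split found. A best split
is accepted even at zero immediate gain (parity-style structure only pays
off one level deeper). This removes every source of hidden nondeterminism:
retraining on identical inputs yields a byte-identical model file.

Defaults: 50 rounds, depth 2 — the standard boosting regime for ~13
weakly-redundant features, training in about a second on the default
cohort. Hyperparameters of the commercial product are not public; these are
engineering choices validated on the synthetic study. Feature importance is
the vote-weight-weighted sum of impurity decreases per feature, normalized;
on default runs the C_STD features dominate.

Models serialize to structural JSON (format `pulseaf-model-1`) with the
full tree structure, vote weights and feature schema version;
`load_model(save_model(m))` reproduces margins bit-for-bit, and version or
schema mismatches raise explicit errors.

## Evaluation statistics

Sensitivity TP/(TP+FN) and specificity TN/(TN+FP), each with a
Wilson score interval (statsmodels), clipped to [0, 1]. Wilson was selected
because it reproduces the published validation CIs at their printed
precision — verified for 11 of the 12 printed bounds; the remaining one
(34/34, printed lower bound 90.0) is 89.7–89.8 under every standard interval
(Wilson, Clopper–Pearson, Jeffreys, Agresti–Coull) and is treated as an
upstream rounding slip, with the Wilson value 89.8 reported.

Subgroup comparisons use the Pearson chi-square **without** continuity
correction — required to reproduce the published subgroup p-values (0.49,
0.44, 0.75, 0.36) — despite small expected counts in some cells; users
comparing their own small subgroups should prefer an exact test. McNemar's
test offers both the exact binomial form (doubled smaller tail, capped at 1)
and the continuity-corrected chi-square, because the variant behind the
published paired-device p-values is not identifiable from the printed
marginals (the discordant counts were not published); those p-values are
accordingly not replay targets. Percent rendering rounds half-up to one
decimal, printing exact hundreds as "100".

## What the synthetic study does and does not show

The synthetic hold-out study (2,000 training + 2,000 held-out measurements,
five seeds) checks that the feature/classifier construction separates the
modeled regimes — it reaches ≥ 95% sensitivity and specificity with a large
margin. It does **not** reproduce the clinical headline accuracies: the
clinical dataset is not public and the deployed model is proprietary, so
the published counts enter only as replay inputs to the statistics layer.
Real data differ from the generators in ways that matter: atrioventricular
refractory structure (real AFib intervals are not perfectly i.i.d.), mixed
and drifting ectopy patterns, motion artifacts beyond isolated missed
beats, and heart rates far from 80 bpm. Passing the synthetic study is
evidence the algorithm is implemented correctly, not a clinical performance
claim.

## Numerical and edge-case choices

- Population (1/N) variance everywhere; C_STD = SD exactly for one cluster.
- Interval series must be strictly positive and finite; QC clips to
  0.3–2.0 s (200–30 bpm) and logs removals.
- Feature vectors below 10 intervals raise an insufficient-data error
  carrying the count; the CLI flags such rows as `INSUFFICIENT` rather than
  dropping them.
- Tie margins classify as non-AFib; leaf-class ties in a tree also resolve
  to the negative class.
- Seeds derived inside generators stay below 2³¹.

## Problem sizes

Default test and acceptance runs use the study conditions above: cohorts of
2,000 measurements (~22 intervals each), five seeds for seed-averaged
rates, 1,000 draws for Monte-Carlo rates, 20,000 draws for distributional
checks. The complete suite runs in well under a minute.
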