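# Methods

This note records the models, conventions and numerical choices behind
`circaclust`, the reasoning where the design was genuinely open, and
what the synthetic-data tests do and do not demonstrate about real
accelerometer data.

## Data model and day-window construction

Epoch records hold ENMO (Euclidean Norm Minus One: vector magnitude of
triaxial acceleration minus 1 g, negatives clipped to zero, in mg) on a
uniform grid, with per-epoch wear flags. Epochs are half-open
`[t, t + epoch)` and a window owns the epoch containing its start, which
prevents double counting at boundaries. Timestamps are naive local
clock time; daylight-saving transitions are undefined behaviour (the
simulator never crosses one).

A *full day window* is one waking period (waking up for the day until
sleep onset at night) plus the following sleep period. `n` annotated
nights yield `n − 1` windows. The two wear protocols supported —
diary-anchored recording with partial first/last days dropped, and
first-to-last-sleep-onset retention — differ only in which boundary
days were discarded upstream, so one windowing routine serves both. A
window is valid when wear covers at least 2/3 of the waking **and** of
the sleep sub-period; a participant is analysed with at least five
valid windows. Non-wear epochs are excluded from every metric
denominator (the alternative, imputation, is out of scope; the choice
matters only for participants near the validity threshold).

Non-wear detection is a low-variance-run utility (60-min windows with
ENMO SD < 2 mg, boundary inclusive, AND-ed with existing flags). It is
**not** applied automatically in the cohort pipeline: with epoch ENMO
alone it cannot distinguish a motionless sleeper from a device on a
table, so wear status is expected from upstream processing, as in
standard raw-data toolchains. Raw triaxial input is supported through a
pass-through ENMO aggregator; auto-calibration is deliberately not
reimplemented.

## Sleep-period detection

The reference detector works on epoch ENMO: sustained-inactivity blocks
are maximal runs of the 5-min rolling median below 20 mg lasting at
least 30 min; blocks separated by gaps under 60 min merge; the longest
merged candidate inside the noon-to-noon night anchor defines the sleep
period. With a diary, the search is restricted to diary times ± 2 h,
falling back to the diary itself when no block lies in the corridor.
Within the sleep period, wake epochs are runs above 30 mg persisting
≥ 2 min; everything else is sleep. All thresholds are parameters of
`SptParams`, and the detector is pluggable.

Two limitations are inherent and documented rather than patched:

* Quiet evening sitting is accelerometrically similar to sleep, so the
  detected onset can extend into pre-sleep sedentary time, inflating
  sleep duration for sedentary phenotypes. The bias is
  phenotype-consistent and does not impair clustering, but absolute
  sleep times from ENMO alone should be treated cautiously — this is
  precisely why wrist-angle-based detectors are preferred when raw data
  are available.
* When nocturnal movement bouts exceed the 20-mg inactivity threshold
  and arrive frequently, sub-30-min quiet runs between bouts are
  discarded and holes longer than the 60-min merge horizon can split
  the night. Accurate boundary recovery is therefore only guaranteed
  when sleep movement stays below the threshold; the detector-recovery
  test (median onset/wake error ≤ 10 min over 50 nights at 2 bouts/h)
  pins restlessness at 15 mg for this reason.

## The 36 metrics

Cosinor parameters come from least squares of `log(ENMO + 1)` on
`[1, cos ωt, sin ωt]` (ω = 2π/24, t clock hours): mesor is the
intercept, amplitude the harmonic norm, acrotime the fitted peak time,
R² the coefficient of determination. The +1 offset handles zeros and is
configurable. IS and IV use hourly means (hours with < 50 % wear are
dropped from numerator and denominator; IV differences spanning a
dropped hour are skipped):

    IS = n · Σ_h (x̄_h − x̄)² / (24 · Σ_i (x_i − x̄)²)
    IV = n · Σ (x_i − x_{i−1})² / ((n − 1) · Σ_i (x_i − x̄)²)

Cosinor, IS and IV are computed once on the concatenated multi-day
series; bout, transition, sleep and timing metrics are computed per day
window and averaged over valid windows — each metric's natural support.

M10/L5 are rolling 10-h/5-h window means at epoch stride. L5 uses
noon-to-noon days (the sleep trough is contained whole); M10 uses
calendar days, because a noon-anchored day cuts the typical
09:00–19:00 most-active window at its boundary and would pin M10 start
to noon, destroying its chronotype information. Days missing more than
1/3 of epochs are skipped and a window must be at least half observed.

Intensity classes use the common 30/100 mg cut-points (SB < 30,
MVPA ≥ 100). A bout is a maximal run (minimum length 1 epoch, no
interruption tolerance; both configurable). Transition probabilities
are transition counts divided by time spent in the source state,
reported **per minute** (the literature leaves the unit open; per
minute makes 60-s and 30-s epoch runs comparable), and day boundaries
break runs. The intensity gradient regresses ln(minutes per 25-mg bin)
on ln(bin midpoint) over non-empty bins up to 4000 mg and needs ≥ 3
non-empty bins.

Sleep metrics follow from the wake/sleep classification per night:
sleep duration, efficiency (= sleep / worn sleep-period time), WASO,
bout statistics and night transition probabilities; mean bout lengths
pool epochs over nights (more stable than averaging per-night means).
A night with no classified wake leaves the wake→sleep transition
undefined (0/0); it propagates as missing and the participant drops
from complete-case clustering, mirroring how rate metrics go missing in
cohort practice.

Timing metrics live on a noon-anchored hour scale — clock hour, plus 24
if before noon — so onsets of 23:00 and 01:00 average to midnight
(24.0), not noon. This replaces full circular statistics and matches
the circular mean to within ~1 min for times concentrated within ± 6 h
of midnight; it is documented as inaccurate for phenotypes sleeping
near midday. M10 start stays on the plain clock scale because its
distribution straddles noon, not midnight.

## Two-step clustering

The participant × 36 matrix is standardised column-wise (sample SD,
ddof = 1, as R's `scale`), complete cases only. PCA is an
eigendecomposition of the correlation matrix with deterministic sign
fixing; the retained count is `max(#{λ ≥ 1}, smallest m with cumulative
variance ≥ 0.75)` — the two published criteria combined so both
constraints hold, with both candidate counts reported. k-means (Lloyd,
k-means++ starts, best inertia across restarts) sweeps K = 4…12; the
published protocol uses 5,000 restarts and 10,000 iterations, and the
restart count is a cost knob, not a correctness knob (tested: 50 vs
5,000 restarts change inertia by < 0.1 % on blob benchmarks). Candidate
K whose smallest cluster falls below `min_size` (default 200, the
published threshold for cohorts of 4,000–55,000 participants) are
ineligible; eligible K are ranked by silhouette, then Davies–Bouldin.
Silhouette is computed on the full score matrix up to N = 20,000 and on
a seeded subsample beyond. Cluster profiles report standardized and raw
means/SDs and |z|-ranked metric tables; the medoid is the participant
nearest its centroid in score space (ties → lowest id).

## Downstream statistics

The reference cluster is the largest among those with every |z-mean|
< 1; if none qualifies the min–max cluster is used with a warning, and
a qualitative "better health status" preference is an explicit user
override, not encoded. Multinomial logistic regression (maximum
likelihood, Newton) enters all covariates jointly, categoricals as
drop-first dummies; Wald 95 % CIs on the log-odds scale; significance
flags at 0.05/0.01 with no multiplicity correction (matching
per-coefficient reporting practice). Cox proportional hazards on the
retained components uses the Efron tie approximation (lifelines).
Harrell's C counts comparable pairs (event vs longer survivor), risk
ties one half; its CI and the paired difference test for two models use
a participant-level bootstrap (two-sided; identical models give ΔC = 0
and p = 1 by construction). The 10-metric comparison set is IS, IV,
relative amplitude, cosinor mesor/amplitude/acrotime, and M10/L5 mean
and start.

## Synthetic cohorts

`simulate_participant` emits epoch ENMO from noon of day 0 over
`n_days` noon-to-noon blocks. Per night, onset and duration are
Gaussian around the phenotype's means (onset clock hours may exceed 24
for past-midnight types); sleep ENMO is zero except wake bouts arriving
as a Poisson process (`frag_rate`/h, exponential lengths, mean 5 min)
with lognormal intensity around `restlessness_mg`. Waking epochs follow
a semi-Markov chain over SB/LIPA/MVPA with geometric dwell times (means
in minutes) and entry weights; run entries are drawn independently, so
consecutive same-state runs merge — bout statistics remain
phenotype-discriminative, which is all the clustering needs. Emissions
are lognormal (σ = 0.3 on the log scale, heavy-tailed and positive like
accelerometry) around the state mean, modulated by the cosinor envelope
`exp(mesor + amp·cos(2π(t − acrophase)/24))` normalised to mean 1 over
waking epochs so state means are the realised intensity levels (an
unnormalised mode exists, in which a cosinor fit of the log signal
recovers all three planted parameters exactly). Diaries report the
realised epoch-aligned boundaries. Covariates (age, sex, BMI, season)
get per-phenotype shifts; survival is exponential with hazard
`baseline · exp(phenotype log-hazard)` (default 0.008/year, ~8 %
12-year mortality at the reference, matching an older cohort) and
administrative censoring at 12 years. One master seed drives
everything; participant i uses `SeedSequence(seed, spawn_key=(i,))`, so
cohorts are reproducible under parallel generation.

The nine default phenotypes span robust-vs-poor rest-activity rhythm,
high/low daytime activity, short-fragmented vs long-efficient sleep,
delayed chronotype and restless sleep, with deliberate separation
margins; the 4-phenotype set is a maximally distinct subset. They are
plausible, not calibrated to any cohort: recovery tests show the
pipeline finds well-separated structure, not that real populations are
this separable. Other idealisations: no within-phenotype trait
variance (between-participant spread comes only from finite-sample
noise), no naps, no posture/angle information, no autocorrelated sensor
noise, exact diaries.

## Problem sizes and numerical choices

Recovery checks run at N = 2,000 participants × 7 days × 60-s epochs
with 100 k-means restarts and a minimum cluster size of 100 — 5 % of N,
scaling the published absolute threshold (200 at N ≈ 4,000–55,000)
to the simulated cohort, where 9 equal phenotypes put ~222 expected per
cluster and a fixed 200 would fail on binomial noise alone. Statistical
recovery uses N = 20,000 (multinomial), 5,000 (Cox) and 1,500
(C-index comparison, 100–200 bootstrap replicates). Degenerate inputs:
constant signals yield amplitude 0 with R² 0 (warned); zero-variance
hourly series make IS/IV undefined; M10 = L5 = 0 makes relative
amplitude undefined; empty transition sources and < 3 intensity bins
propagate as missing. Matrix work uses `eigh` on the correlation
matrix, `lstsq` for cosinor, and k-means ties are resolved by inertia.
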