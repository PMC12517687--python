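# Methods

`neurodisc` analyzes head-fixed (or home-cage) Go/No-Go pure-tone
discrimination sessions: a trial table, a lick-event stream, and sorted
spike trains on a shared clock in seconds. This note documents the models,
the conventions chosen where several readings were possible, what the
synthetic generator does and does not emulate, and the problem sizes the
validation suite runs at.

## Behavioral model and statistics

Outcomes are classified from the lick stream: a go trial with at least
`lick_threshold` licks inside the half-open response window
`[anchor, anchor + 2 s)` is a hit, otherwise a miss; no-go trials become
false alarms / correct rejects the same way. The anchor is the tone offset
(the home-cage protocol uses a 5-lick threshold, the head-fixed protocol a
1-lick threshold). Probe tones are never rewarded or punished and never
enter the rates.

Sensitivity and criterion follow the equal-variance Gaussian model:

    d' = Phi^-1(H) - Phi^-1(F),     c = -(Phi^-1(H) + Phi^-1(F)) / 2

with hit and false-alarm rates clipped to [0.01, 0.99] before the inverse
normal. The clip is symmetric (the published convention states only the
upper rounding); symmetry keeps `d'(H,F) = -d'(F,H)` exact, which the
suite tests. Negative criterion means a liberal (over-licking) observer.
Session endpoints use the last 100 trials by default; running d' uses
25-trial bins per task, and the behavioral CV is the SD/|mean| of all
defined running-d' bins.

The psychometric curve is the unity-normalized lick rate fitted with
`S(t) = a / (1 + exp(-(t - b)/c))` over `t = log2(frequency / 1 kHz)`.
The direction of the curve (rising vs falling with frequency) is detected
from the sign of the Spearman correlation and the fit run on the mirrored
axis when falling, so the steepness `c` stays positive. Initialization is
deterministic (a = max rate, b = frequency of half-max, c = span/10); a
flat curve (range < 0.05) is returned flagged degenerate rather than fit.

## Single-unit inclusion and firing properties

A unit is *excited auditory responsive* when per-trial evoked rates
(tone onset to 50 ms after offset) exceed per-trial baseline rates
(200 to 50 ms before onset) under a right-sided Wilcoxon signed-rank test
at alpha = 0.05 (zero differences excluded; exact distribution below 25
informative trials, normal approximation above). Suppressed and
non-responsive units are excluded everywhere downstream. Two baseline
conventions deliberately coexist: the test baseline is [-0.2, -0.05) s,
the reported spontaneous rate [-0.2, 0) s — each matches its own standard
definition. Rates from equal-width windows are compared after rounding the
window width at nanosecond resolution, so float arithmetic cannot create
spurious rank-test wins; sub-nHz rate differences count as ties.

PSTHs are 1 ms histograms in Hz smoothed with a 5 ms Gaussian (reflective
boundary, mass-preserving to < 1% for interior mass). Latency-to-peak is
the argmax of the smoothed PSTH in the evoked window; minimal latency is
the median across trials of the first spike after onset (the median is a
robustness choice — no aggregator is standard); FWHM is the width of the
PSTH around its peak at half height above the spontaneous floor. Lifetime
sparseness over the n learned tones is

    S = (1 - (sum r_i / n)^2 / (sum r_i^2 / n)) / (1 - 1/n),

0 for uniform profiles, 1 for one-hot, invariant to rate rescaling.
The fraction of responsive trials uses strict inequality (evoked rate
strictly above baseline rate).

## Sliding-window ROC discriminability

Per-trial counts are taken in 50 ms windows advanced in 25 ms steps over
[-0.2, 0.6] s; the window's timestamp is its center. Per window, the
Mann-Whitney AUC (ties 0.5) is computed on 20 trials drawn without
replacement from each class and averaged over 100 resamples; the
convention is AUC = P(count_b > count_a). The averaged trace is
re-referenced to the mean over windows fully inside the pre-onset span,
`adjusted = raw - baseline + 0.5`, clipped to [0, 1].

The shuffle null permutes the pooled trial labels once per draw and runs
the identical pipeline (resampling and baseline adjustment) on the
pseudo-classes, 100 draws by default. Permuting inside every resample
instead would average trial-level noise out of the null and make it far
too narrow — the null must carry the same finite-trial noise as the
statistic it calibrates. Significance per window is a deviation from the
per-window null mean of more than 3 null SDs, two-sided by default: the
contrast classes are fixed by outcome (hit vs FA, FA vs CR), so the sign
of a real class difference depends on each unit's tuning and choice
preference, and the "mean +- 3 SD" band needs both branches. A one-sided
mode (upper branch only) is available. Onset latency is the first
significant window center at t >= 0; duration counts all significant
post-onset windows times the step (a contiguous mode measures the longest
run); the maximal AUC is taken over the whole trace.

Stimulus contrasts compare hits to false alarms within a task; the choice
contrast compares false alarms to correct rejects per task, with metrics
averaged across tasks; novice-mode compares all go to all no-go trials.
Miss trials are never used. The empirical false-positive rate of the 3-SD
rule (fraction of null units with at least one significant window over the
32-window trace) is bounded in the tests, not assumed.

## Population decoding

Sessions qualify with >= 20 responsive units and >= 20 hit and correct-
reject trials in the task (inclusive thresholds). The decoder is a
pooled-covariance LDA with analytic (Ledoit-Wolf) shrinkage toward scaled
identity — stable at ~40 trials by >= 20 units; accuracy is the mean over
100 random holdouts of 10 trials per class (the holdout size is the
published protocol; the repeat count is a free parameter here).
Time-resolved decoding fits an independent LDA per 50 ms bin (20 repeats
per bin by default, a tractability choice). Decoding latency reads a
100 Hz trace — 50 ms windows advanced in 10 ms steps, timestamped at
window centers — against the mean + 3 SD of windows fully inside
[-0.5, -0.05) s; the center timestamp was chosen because it recovers
planted population onsets with ~5 ms bias in simulation, whereas start/end
stamps are biased by roughly half a window. Sessions that never cross
within the search range return no latency and are excluded from
summaries.

Class separation is the closed-form Fisher ratio
`S = dmu^T (Sigma1 + Sigma2 + eps I)^-1 dmu` with
`eps = 1e-6 x mean diag(Sigma1 + Sigma2)` (scale-free conditioning of
rank-deficient covariances). Single-trial variance z-scores each unit
across all trials, then averages the per-unit within-class variance with
equal unit weight, excluding zero-variance units. The easy-vs-hard
separation relationship is a no-intercept Huber robust regression
(`S_hard = beta * S_easy`) per group.

## Passive-listening tuning

The passive protocol presents 20 tones log-spaced over the 4-40 kHz decade
(log2(10)/20 = 0.16610 octaves per step) at 32-72 dB SPL in 10 dB steps,
16 repetitions per cell, one tone per second. All tuning statistics are
evaluated at 62 dB SPL (closest to the behavioral level; configurable).
FRA cells are mean rates over [0, 0.15) s. Per-frequency significance is
the same right-sided signed-rank test against the pre-tone baseline; an
overall excitation gate across all analysis-level trials is applied first,
because ~alpha of 20 per-frequency tests fire on a purely spontaneous
unit. Best frequency is the significant frequency with the maximal rate.

Bandwidth counts the largest contiguous significant run containing the
best frequency ("adjacent" implies contiguity; isolated significant cells
outside the run are ignored), subtracts the expected false positives
`alpha x n_freqs` (fractional subtraction, floored at zero), and
multiplies by the octave step. Population sparseness is the fraction of
significant (unit, frequency) responses. The pairwise neural d' between
frequencies p and q is `|mu_p - mu_q| / mean_{i,j} |p_i - q_j|` over all
cross-trial pairs — for scalar single-neuron rates this is the only
dimensionally consistent reading of the published expression, whose
denominator is ambiguous as printed; identical trial sets give 0, and the
ratio is invariant to rate rescaling. The learned-spectrum mean averages
pairs with both frequencies in [7.07, 14.14] kHz.

### Protocol tone frequencies

The easy pair is (7070, 14140) Hz — exactly one octave. The hard pair is
stated as 0.25 octaves around the 10 kHz boundary; the package uses
(9170.0, 10905.1) Hz = 10 kHz x 2^(+-0.125), which realizes that spacing
exactly (a printed value of 10.95 kHz would be 0.256 octaves from 9.17 kHz
and is treated as a rounding slip).

## The synthetic generator

Behavior follows the planted SDT model exactly: P(lick|go) = Phi(d/2 - c),
P(lick|no-go) = Phi(-d/2 - c) with d per task, probes at Phi(-c). Response
trials receive a lick train (truncated-normal first-lick latency after
offset, ~8-12 Hz train, at least the threshold count inside the window),
so planted (d, c) are exactly what the behavior module estimates. Default
conditions: 45% no-go, 10% probes, 6-8 s inter-trial onset intervals,
100 ms tones, 2 s response window.

Spiking is an exact inhomogeneous Poisson superposition: a homogeneous
baseline over the session, plus per-trial evoked transients (Gaussian
log2-frequency tuning, alpha kernel `(t/tau) exp(1 - t/tau)` delayed by
the evoked latency) drawn by thinning against the analytic kernel peak,
plus a choice step of `choice_gain` Hz from `choice_onset` to the end of
the response window on lick trials only — applied regardless of category,
so the FA-vs-CR contrast carries it by construction. Per-trial
multiplicative gain noise is gamma with mean 1 (CV 0.2 by default),
independent across units unless `shared_gain` is set. Defaults emulate a
deep-layer auditory cortical unit: 5 Hz baseline, 30 Hz evoked peak,
15 ms latency, 40 ms decay.

What the generator does **not** emulate: noise correlations beyond the
optional shared gain, adaptation or history dependence across trials,
non-Poisson spiking statistics, behavioral lapses or impulsivity
structure, drift in excitability or criterion over a session. Tests that
pass on this generator therefore certify the estimators' correctness and
calibration under the stated model, not robustness to every property of
real recordings.

## Problem sizes in the validation suite

The recovery suite runs at desk scale: the behavior grid uses 2000 trials
per (d, c) cell; onset recovery uses 20 units per planted onset on a
600-trial session with a liberal criterion (ample false alarms); decoder
calibration uses 50 permuted-label populations of 20 units x 60 trials,
and latency recovery 6 sessions of 25 units; the determinism check runs
the full pipeline twice on a 250-trial, 4-unit session with reduced
iteration counts. These sizes keep the whole suite in single-digit
minutes while leaving sampling error well below the tolerances tested.

## Known limitations

- Eq.-level ambiguities (pairwise d' denominator, bandwidth correction,
  AUC window placement) are resolved by documented conventions; other
  readings would shift absolute values, though not orderings.
- The LDA timecourse to 10 s spans subsequent trials under realistic
  inter-trial intervals, as in the source protocol; interpret late bins
  accordingly.
- Huber regression uses statsmodels' default tuning constant; slopes from
  very small cohorts (3-5 sessions) remain noisy.
- The loader accepts only the package's TSV session layout; converters
  from sorter-native binary formats are out of scope.
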