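# Methods

## The detection model

`hrsleep` treats sleep detection as a within-day distributional problem.
Resting heart rate during sleep sits below the waking level for almost
everyone, whatever the absolute values, so the day's own empirical CDF of
heart rate is used as the reference: an epoch is a sleep candidate when
its heart rate falls at or below the sample quantile `Q` of that ECDF.
The ECDF inverse is the left-continuous generalized inverse — the
smallest *observed* value whose cumulative ratio reaches `Q` — so the
threshold is always attained by data and ties at the threshold are
labelled sleep (a "dip to the threshold" counts as a dip).

Days are 24-hour windows anchored at a configurable clock time
(default 15:00).  The anchor only decides how the recording is cut;
nothing downstream consults the clock, which is what makes the method
valid for shift workers.  The anchor is deliberately placed mid-afternoon
so a conventional night never straddles a window boundary; for cohorts of
daytime sleepers the anchor should be moved to the subjects' waking
period (e.g. midnight), exactly as a night-sleeper's anchor avoids the
night.

The candidate labels then pass through:

- a 5-minute centred rolling median (windows stated in minutes are
  converted to an odd epoch count, rounding up, so cohorts with 15 s or
  30 s epochs behave like 60 s cohorts);
- run-length filtering: sleep runs strictly longer than `L` minutes
  survive; surviving runs whose gaps are strictly shorter than `G`
  minutes merge, left to right, into single blocks;
- main-window selection: the longest block wins, ties to the earliest;
- limit refinement: within a search window from 240 min before to 60 min
  after each candidate limit, onset moves to the *last* epoch of high
  heart-rate volatility (rolling 10-min standard deviation ≥ 6 bpm,
  sample convention) and offset to the *first* high-volatility epoch at
  or after the candidate, falling back to the last one before it, then to
  the unrefined limit; a refinement that would invert the window is
  discarded with a warning;
- nap labelling: merged blocks lying entirely outside a 180-min buffer
  around the main window and strictly shorter than 60 min (the length cap
  can be toggled off, since a buffer-only rule is also defensible);
- awakening labelling: inside the window, heart-rate excursions strictly
  above the `AV` = 0.80 quantile of the day's 08:00–22:00 ECDF, strictly
  longer than 5 min, merged across sleep gaps shorter than 5 min, and
  discarded if they reach 60 min (an hour-long excursion is treated as
  evidence of wake, not an awakening).  `AV` has no published reference
  value; re-using the night-time quantile 0.80 is this package's default
  and is exposed as an ordinary parameter.

Final epoch labels for a detected day are sleep throughout
[onset, offset) minus awakening intervals; TST is the sleep-labelled time
in that window.  A day is flagged *polyphasic* when more than two merged
blocks exceed 90 min (reporting only), and *low confidence* when the
detected window covers ≥ 95 % of the day, as happens on degenerate
near-constant traces where every epoch ties with the threshold.

### The eligibility rule

Candidate blocks are additionally screened by a lookback rule: a block
preceded by more than 90 min of cumulative wake in the prior 4 h is
demoted.  Wake accounting is cumulative rather than contiguous (the
natural reading of "90 minutes of wake in the previous 4 hours") and
missing epochs count as neither state.  Taken as an absolute filter this
rule would reject every ordinary night, because the main sleep onset
always follows an evening of wake; it is therefore applied as a
*discriminator among competing candidates*: when it eliminates every
block, selection falls back to the full merged-block list, and only a day
with no surviving runs at all is reported as "no sleep detected".

## Parameters

| name | default | unit | meaning |
| --- | --- | --- | --- |
| `quantile` (Q) | 0.325 full-day / 0.80 night-only | — | ECDF level separating candidate sleep from wake |
| `min_length` (L) | 20 | min | minimum surviving sleep run |
| `merge_gap` (G) | 90 full-day / 420 night-only | min | largest gap merged between runs |
| `smooth_window` | 5 | min | rolling-median width |
| `vol_window` / `vol_threshold` | 10 / 6 | min / bpm | volatility definition for refinement |
| `search_before` / `search_after` | 240 / 60 | min | refinement search span around each limit |
| `elig_lookback` / `elig_max_wake` | 240 / 90 | min | block eligibility lookback |
| `day_start` | 15:00 | clock | day-window anchor |
| `nap_buffer` / `nap_max_len` | 180 / 60 | min | nap rules |
| `awakening_quantile` (AV) | 0.80 | — | daytime ECDF level for awakenings |
| `awk_min_len` / `awk_merge_gap` / `awk_max_len` | 5 / 5 / 60 | min | awakening rules |
| `coverage_floor` | 0.5 | — | minimum non-missing fraction for a usable day |

The full-day and night-only `(Q, L, G)` presets are grid-search optima
against reference sleep labels; the full-day quantile of 0.325 is
intuitive — people sleep roughly a third of the day, so the lowest third
of the day's heart rates marks sleep.  The night-only preset compensates
for the missing daytime distribution with a much higher quantile and an
aggressive merge gap.

## Evaluation machinery

Epoch error is the misclassification fraction
`MSE = Σ(predᵢ − truthᵢ)²/n` over epochs where both labellings are
defined; on binary labels this equals the Hamming distance over n, is
symmetric, is 0 iff the labellings agree, equals the truth's sleep
proportion against an all-wake prediction, and equals the sum of both
sleep proportions when the sleep sets are disjoint.  Cohen's κ is
computed from the 2×2 table per night; degenerate tables (both labellings
constant) return 1 when identical and 0, with a warning, otherwise.
Mismatched epoch grids are aligned by down-sampling the finer series to
the coarser by majority vote, ties resolving to sleep.  Summary CIs use
the normal 1.96 multiplier (switchable to the t quantile), matching the
Bland–Altman convention of mean difference ± 1.96 SD.  The paired t-test
is two-sided.

Grid search evaluates mean per-day MSE over the lattice
Q ∈ [0.10, 0.95] step 0.025, L ∈ [10, 120] step 5 min,
G ∈ [30, 420] step 30 min (11 270 points) exhaustively; the per-day
quantile labelling, smoothing and volatility traces depend only on Q (or
on nothing), so they are cached per `(day, Q)` and the inner `(L, G)`
loop reduces to cheap run-length arithmetic.  Ties on the minimum resolve
to the smallest Q, then L, then G, and are flagged.

## The synthetic generator

`simulate_subject` emulates exactly the features the detector exploits:
a two-level heart-rate profile (wake 75 bpm, sleep 55 bpm by default —
typical adult values), a 5-bpm 24-h sinusoid on waking heart rate
peaking mid-afternoon, smooth 10-min ramps at state changes, an extra
8-bpm noise burst within ±10 min of each transition (the settling-down /
getting-up volatility the refinement stage needs), additive Gaussian
noise of 3 bpm (optionally AR(1)), scheduled naps and brief awakenings,
and uniform missingness.  Ground-truth labels follow the schedule
exactly, before missingness.  All randomness flows from one integer
seed; cohort subject *k* draws from `SeedSequence((seed, k))` so any
subject reproduces in isolation.  Scenario presets: `monophasic`
(23:00–07:00), `shift_worker` (09:00–17:00), `biphasic_nap` (40-min
afternoon nap far outside the nap buffer), `fragmented` (three 6–15-min
awakenings).

What the generator does **not** emulate: heart-rate variability spectra,
respiratory modulation, movement artefacts, fever or alcohol effects on
nocturnal heart rate, device-specific sampling jitter, and diurnal
activity bouts (exercise dips and spikes).  Passing tests on synthetic
data therefore demonstrate the algorithm's correctness under its own
signal model — a clean sleep-time dip with transition volatility — not
field accuracy on any particular device or population.

## Numerical and design choices

- Missing heart rate is excluded from ECDFs and rolling windows, never
  imputed; rolling standard deviations over fewer than two values are
  missing; missing labels break runs.
- `regularize` averages samples within an epoch and fills sample-free
  epochs from the nearest observation only within `max_gap` (default
  5 min); epochs holding only NA readings stay missing.
- Days with under 50 % non-missing epochs are returned but skipped by the
  detector (a quantile over a sparse day is unstable); the floor is
  configurable.
- Timestamps are timezone-naive local clock time; daylight-saving jumps
  are taken as given.
- The ECDF rank is settled by direct comparison (`k/n ≥ q`) rather than a
  bare `ceil(qn)`, which can land one rank off in floating point.
- The sub-epoch aggregation rule (mean within epoch) is a package choice;
  high-rate optical heart-rate streams may warrant median aggregation
  upstream.

## Problem sizes in shipped checks

The test suite and the acceptance script run entirely on synthetic data:
50 single-night subjects for schedule recovery, a 3-subject × 2-day
cohort for the full-lattice grid search, 500 pairs for Bland–Altman
coverage, and 4 nights for the clock-shift equivariance check.  These
sizes give stable medians and sub-minute runtimes; the statistics they
produce (onset error ≈ 10 min, epoch MSE ≈ 0.008, κ ≈ 0.98) describe the
generator's conditions, not any real cohort.

## Known limitations

- On near-constant traces the quantile threshold always labels roughly a
  `Q`-fraction of the day as sleep; such days are flagged rather than
  rejected.
- The refined onset tends to sit at the *end* of the pre-sleep
  volatility burst, biasing onset slightly late (≈ 10 min under the
  default generator) — the cost of robustly excluding quiet reading-in-bed
  time.
- Only one main window per day is reported; genuinely polyphasic sleep is
  flagged but not decomposed.
- Naps and awakenings depend on a daytime ECDF; recordings without
  daytime coverage skip awakening detection with a warning.
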