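# Methods

## The measurement procedure

### Optotype sizing and crowding geometry

A letter at logMAR `L` viewed from distance `d` subtends `5·10^L`
arcminutes, giving a physical height `h = d·tan(5·10^L·π/10800)`. The
exact tangent is used rather than the small-angle linearisation so that
heights are bit-stable across distances; the familiar decade rule
(`h(L+1)/h(L) = 10`) consequently holds only to first order — within
0.1% while the larger letter is at or below 1.4 logMAR (125 arcmin), and
progressively worse above that.

Letters are modelled as 5×5 stroke-width squares (stroke = height/5).
Real test letters have per-glyph width variation; the square
simplification makes every layout ratio an exact constant and is the
documented abstraction throughout. Crowded lines place letters half a
letter width (2.5 strokes) apart and surround them with a crowding box
one stroke thick, offset 2.5 strokes from the letter borders. Hence a
single crowded letter occupies 12×12 strokes (2.4× the letter height)
and a k-letter chunk is `5k + 2.5(k−1) + 7` strokes wide.

### Calibration

The screen scale factor is the ratio of a ruler-measured calibration
cross to its nominal size in internal units. A mis-measured cross scales
every displayed letter by the same factor `c`, which on the logarithmic
acuity scale is an additive offset of `log10(c)` logMAR — e.g. a 12.2%
over-measurement makes every test ~0.05 logMAR too easy. Implied display
densities outside 20–600 units/inch raise a warning, not an error: the
window is generous enough for unusual hardware but catches
order-of-magnitude ruler mistakes.

### Line chunking and screen feasibility

When a full five-letter line does not fit the presentation window, it is
split greedily into the largest chunks of 3, 2 or 1 crowded letters that
fit; five letters are always presented and scored per size. The
feasibility calculator takes the presentation window to cover a linear
fraction (default 2/3) of each screen dimension — the maximised 16:9
video-call window — and reports the largest grid size whose *single*
crowded letter (box included) fits; under these assumptions a 24″ 16:9
screen at 3 m supports 1.2 logMAR. Published device tables for
comparable systems quote somewhat higher maxima; those tables do not
state their window or crowding assumptions, and no single consistent
geometric rule reproduces them, so this calculator documents its own
assumptions instead of fitting to any published table.

### The staircase

Range finding presents one crowded letter in 0.2 logMAR steps from 0.8,
descending while correct (ascending if the first response is wrong)
until the smallest recognised size is found; thresholding starts 0.2
above it, clamped to the grid ceiling. Thresholding presents five
letters per line, descending 0.1 per line, and terminates when all five
letters on one line are wrong, or when the floor line (−0.3 by default)
has been completed. If the first thresholding line contains any error,
larger lines are presented (in 0.1 steps — the finer of the two step
sizes, chosen because the ascent is part of thresholding) until one is
fully correct; the descent then resumes, and sizes already attempted are
*not* re-presented — their recorded responses are reused, so exactly
five letters are scored per size. An ascent that reaches the ceiling
without a fully-correct line ends the test off-scale-high; by the same
rule a test whose thresholding must start at the ceiling is off-scale if
that single available line contains an error.

Scoring: the anchor is the largest fully-correct line and each correct
letter strictly below it earns 0.02 logMAR. This anchor convention is a
design choice (the alternative — crediting from the starting line — is
start-dependent); it makes a perfect step observer score exactly the
smallest 0.1-grid size at or above its threshold, and the `0.02×5 = 0.1`
identity guarantees every score is a multiple of 0.02 with full credit
reaching the floor exactly.

The optional **refresh** re-presents a single letter when a lapse of
attention is suspected. No published trigger rule exists, so the policy
here is: a thresholding line with *exactly one* incorrect response is
refreshed (an isolated error on an otherwise-clean line being the
natural signature of a lapse), at most once per line, never during
range finding, the new response replacing the original. It is off by
default.

Internally all sizes are integer hundredths of a logMAR, so the
staircase arithmetic is exact; floats appear only at the API boundary.

## The synthetic observers

The psychometric observer answers each letter independently with
`P(correct|s) = g + (1−g−l)·F(β(s−t))`, `F` logistic. The logistic (vs
Weibull) choice keeps the midpoint semantics simple — at `s = t`
performance is halfway between floor and ceiling — and lives behind the
observer interface, so other shapes can be substituted. Defaults:
`g = 0.1` (a reduced-letter-set forced choice task has a non-trivial
guessing floor; the true set size is test-specific, so this is a
parameter, not a constant), `l = 0.01` (occasional attention lapses),
`β = 30 /logMAR` (a steep, attentive responder; at slope 30 the
staircase recovers thresholds with ≈ +0.03 logMAR mean bias — the
measured VA is the smallest *grid* size readable, which sits above the
continuous threshold on average).

Per-letter independence within a line is a simplification: real crowded
acuity shows serial position and inter-letter correlation effects. It
matters mainly for the tails of the line-score distribution.

Condition effects reduce to one additive offset on presented sizes:
`log10(size_scale_error) − jitter`, with the jitter drawn once per
session from `N(0, threshold_jitter_sd²)`. The default home condition
uses `size_scale_error = 1.0` and `threshold_jitter_sd = 0.03` logMAR —
an **illustrative** magnitude for uncontrolled home variation (screen
brightness, room lighting, seating distance); no quantitative
characterisation of home-condition noise exists to calibrate against,
so conclusions from the simulator are structural (orderings,
monotonicities, degeneracies), not predictions of clinical TRV values.

## The simulated study

Thirty-six subjects by default, one (worse) eye each, true thresholds
drawn uniformly on [−0.14, 1.06] logMAR — the printed range of the
motivating clinical cohort; the clinical distribution is skewed toward
good acuity, so uniform is a documented default rather than a clinical
claim. Each subject undergoes four tests (clinic ×2, home ×2). Test
order (58% clinic-first by default) is recorded but not modelled, and is
assigned deterministically (the first `round(0.58·n)` subjects) since
randomising an inert covariate would only complicate reproducibility.

Seeding: every random stream derives from `master_seed`. Session streams
use `SeedSequence([master_seed, subject_index, setting_code, test_index])`
(clinic=0, home=1), split into one child for the observer's response
draws and one for the condition jitter, so any single transcript can be
regenerated in isolation. Off-scale sessions are flagged and excluded
per comparison, never silently dropped.

The three summaries mirror standard reporting: `home1_vs_clinic1`
(differences taken home − clinic, stated in the output header),
`clinic_trv` (test − retest) and `home_trv`. Limits of agreement use the
mean ± 2·SD convention exactly (multiplier 2, with 1.96 as an option);
the CI of the bias is t-based with n−1 df; Shapiro–Wilk is the
normality diagnostic (α = 0.05), reported but never used as a gate.
Report tables round to 2 decimals; full precision is retained
internally.

## Numerical and degenerate-input choices

* Sizes off the 0.01 logMAR grid are rejected at configuration time;
  grid arithmetic is integer.
* The deterministic observer treats the threshold boundary as correct,
  with a 1e-9 tolerance so grid floats compare reliably.
* Zero-variance paired differences are valid (SD 0, LoA collapse to the
  bias); their normality statistic is undefined and reported as absent.
* A constant vector raises on a direct normality call; `bland_altman`
  converts this to an absent diagnostic.
* Fewer than two pairs is an error; subgroup summaries skip such groups
  with a recorded reason.

## Problem sizes used in validation

The validation suite sweeps deterministic thresholds in 0.01 steps over
[−0.2, 1.3]; runs 200 seeded tests per threshold on a 0.05 grid in
[0, 1] for parameter recovery; 100 replicate studies of n = 36 for the
jitter-widening property; and 1000 random datasets for Bland–Altman
formula equivalence. These sizes give stable Monte-Carlo estimates
(recovery-bias SE ≈ 0.003 logMAR) while keeping the whole suite fast.

## Known limitations

* Square-letter geometry and per-letter response independence, as above.
* Letter identity is not modelled (no confusion matrix), so the guess
  floor is a single scalar.
* The slope→step-observer limit requires the guess and lapse rates to
  vanish as well; with a non-zero guess floor, responses at the
  threshold itself remain stochastic at any slope.
* The simulator does not model order effects, learning/fatigue across
  the four tests, or timing.
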