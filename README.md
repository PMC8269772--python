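# teleacuity

Simulation and agreement statistics for **remote computerised logMAR
visual-acuity (VA) testing**.

Tele-ophthalmology lets an eye-care professional run a calibrated,
semi-automated acuity test on a patient's own screen at home, over a
screen-sharing video call. Whether such "at home" measurements can be
trusted is a method-comparison question: are they unbiased relative to
"in clinic" measurements, and is their test–retest variability (TRV)
acceptable? `teleacuity` implements, entirely on synthetic observers,
every computational ingredient of that question:

* **Optotype geometry & calibration** — physical letter sizes from logMAR
  and viewing distance (`h = d·tan(5·10^L arcmin)`), crowded-line layouts
  (letters 2.5 stroke widths apart inside a one-stroke crowding box),
  ruler-based screen calibration, breaking large lines into
  single/pair/triplet chunks, and the largest logMAR size testable on a
  given screen.
* **Adaptive staircase** — two-phase thresholding: single-letter range
  finding in 0.2 logMAR steps from 0.8, then five crowded letters per
  line descending in 0.1 logMAR steps until all five letters on a line
  are wrong, with an ascend-on-first-line-errors rule and an optional
  single-letter "refresh". Single-letter scoring credits 0.02 logMAR per
  correct letter: `VA = anchor − 0.02 × (letters correct below the
  anchor)`, where the anchor is the largest fully-correct line.
* **Synthetic observers** — deterministic step observers, scripted
  fixtures, and forced-choice psychometric observers
  `P(correct|s) = g + (1−g−l)·logistic(β(s−t))`, plus clinic/home
  condition effects (calibration scale error as an additive
  `log10(scale)` logMAR offset; between-session threshold jitter).
* **Bland–Altman statistics** — bias (mean paired difference), its 95% CI
  (t-based), SD, 95% limits of agreement `bias ± 2·SD`, Shapiro–Wilk
  normality diagnostics, subgroup summaries, and the logMAR↔ETDRS-letter
  conversion (1 letter = 0.02 logMAR).
* **Study simulator** — the full 2×2 design (clinic/home × test/retest,
  worse eye, 36 subjects by default) wired through the staircase and
  summarised as the three standard comparisons: home-vs-clinic bias,
  clinic TRV and home TRV.

## Worked example

A perfect step observer with a true threshold of 0.25 logMAR:

```python
from teleacuity import deterministic_observer, run_test

result = run_test(deterministic_observer(0.25))
print(result.va_logmar, result.anchor_logmar,
      result.letters_correct_below_anchor, len(result.trials))
# 0.3 0.6 15 29
```

Range finding descends 0.8✓ 0.6✓ 0.4✓ 0.2✗, so thresholding starts at
0.6; lines at 0.6–0.3 are fully correct and the 0.2 line is failed
outright (29 letter presentations in total). The anchor is 0.6 with 15
correct letters below it: VA = 0.6 − 0.02×15 = **0.30**, the smallest
0.1-grid size the observer can actually read.

A full simulated study, summarised Bland–Altman style (logMAR):

```python
from teleacuity import StudyConfig, simulate_study, summarize_study

summary = summarize_study(simulate_study(StudyConfig(master_seed=1)))
print(summary.table())
#                         home1_vs_clinic1   clinic_trv     home_trv
# n                                     36           36           36
# Mean difference                    -0.01         0.01         0.01
# 95% CI of mean               -0.04, 0.01  -0.01, 0.03  -0.02, 0.03
# SD of differences                   0.08         0.07         0.07
# 95% limits of agreement          +/-0.15      +/-0.14      +/-0.13
```

With the default (noisy psychometric) observers the home-vs-clinic bias
is statistically indistinguishable from zero — the CI of the mean spans
0 — and the limits of agreement quantify how far a repeat measurement
may plausibly stray.

The same functionality is exposed on the command line:

```sh
teleacuity simulate --n 36 --seed 1 --out study_out/
teleacuity score study_out/sessions/S001_clinic_1.json
teleacuity agree pairs.csv --group group
teleacuity feasibility --diag 10 --distance 3000
# max testable crowded logMAR at 3000 mm: 0.8
```

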