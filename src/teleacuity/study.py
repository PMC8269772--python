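"""Simulated 2x2 acuity study: clinic/home x test/retest.

Each synthetic subject has one (worse) eye with a true acuity threshold
drawn uniformly over a configurable range, and undergoes four staircase
tests — two 'in clinic' and two 'at home' — each run through the full
range-finding/thresholding procedure with that setting's condition
effects applied (calibration scale error, between-session threshold
jitter).  The dataset is then reduced to the three standard comparisons:

* ``home1_vs_clinic1`` — first home test minus first clinic test
  (method-comparison bias between settings);
* ``clinic_trv`` — clinic test minus clinic retest;
* ``home_trv`` — home test minus home retest;

each summarised by a Bland-Altman analysis (bias, 95% CI of the mean,
SD, mean +/- 2SD limits of agreement).

Reproducibility: every source of randomness derives from ``master_seed``.
Per-session streams use ``SeedSequence([master_seed, subject_index,
setting_code, test_index])`` (setting_code: clinic=0, home=1), split into
one child for the observer's response draws and one for the condition's
threshold-jitter draw, so any single transcript can be regenerated
independently of the rest of the study.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .agreement import AgreementSummary, bland_altman, summary_frame
from .errors import DomainError, InsufficientDataError
from .observers import (ConditionEffect, DeterministicObserver, Observer,
                        ObserverParams, PsychometricObserver, apply_condition)
from .session_io import SessionLog
from .staircase import StaircaseConfig, TestStatus, run_test

SETTINGS = ("clinic", "home")
_SETTING_CODE = {"clinic": 0, "home": 1}
TESTS_PER_SETTING = 2

#: the three standard comparisons as (name, (setting, test) a, (setting, test) b)
COMPARISONS = (
    ("home1_vs_clinic1", ("home", 1), ("clinic", 1)),
    ("clinic_trv", ("clinic", 1), ("clinic", 2)),
    ("home_trv", ("home", 1), ("home", 2)),
)


@dataclass(frozen=True)
class StudyConfig:
    """Design of the simulated study.

    Defaults follow the validation-study conditions: 36 subjects, worse-eye
    true thresholds spanning -0.14 to 1.06 logMAR, 58% tested clinic-first.
    The default home condition adds a modest 0.03 logMAR between-session
    threshold jitter as an illustrative stand-in for uncontrolled home
    variability; the clinic condition is noise-free by default.
    """

    n_subjects: int = 36
    acuity_low: float = -0.14
    acuity_high: float = 1.06
    observer_type: str = "psychometric"  # or "deterministic"
    slope: float = 30.0
    guess_rate: float = 0.1
    lapse_rate: float = 0.01
    clinic_effect: ConditionEffect = field(default_factory=ConditionEffect)
    home_effect: ConditionEffect = field(
        default_factory=lambda: ConditionEffect(threshold_jitter_sd=0.03))
    order_fraction: float = 22.0 / 36.0
    master_seed: int = 0
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise DomainError("need at least 2 subjects")
        if self.acuity_low >= self.acuity_high:
            raise DomainError("acuity_low must be below acuity_high")
        if not 0 <= self.order_fraction <= 1:
            raise DomainError("order_fraction must be in [0, 1]")
        if self.observer_type not in ("psychometric", "deterministic"):
            raise DomainError(f"unknown observer_type {self.observer_type!r}")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    true_threshold_logmar: float
    clinic_first: bool
    # (setting, test_index 1|2) -> session log
    sessions: dict[tuple[str, int], SessionLog]

    def flags(self) -> str:
        bad = [f"{s}{i}:{log.result.status.value}"
               for (s, i), log in sorted(self.sessions.items())
               if log.result.status is not TestStatus.OK]
        return ";".join(bad)


@dataclass(frozen=True)
class StudyDataset:
    config: StudyConfig
    subjects: list[SubjectRecord]

    def measurements_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {"subject_id": s.subject_id,
                   "true_threshold": s.true_threshold_logmar,
                   "order": "clinic_first" if s.clinic_first else "home_first"}
            for setting in SETTINGS:
                for i in (1, 2):
                    row[f"{setting}{i}"] = s.sessions[(setting, i)].result.va_logmar
            row["flags"] = s.flags()
            rows.append(row)
        return pd.DataFrame(rows, columns=[
            "subject_id", "true_threshold", "order",
            "clinic1", "clinic2", "home1", "home2", "flags"])

    def session_logs(self) -> list[SessionLog]:
        return [log for s in self.subjects
                for _key, log in sorted(s.sessions.items())]


def session_seed_sequence(master_seed: int, subject_index: int,
                          setting: str, test_index: int) -> np.random.SeedSequence:
    """Documented per-session seed derivation (independently reproducible)."""
    return np.random.SeedSequence(
        [int(master_seed), int(subject_index),
         _SETTING_CODE[setting], int(test_index)])


def _build_observer(config: StudyConfig, threshold: float,
                    setting: str, subject_index: int,
                    test_index: int) -> Observer:
    ss = session_seed_sequence(config.master_seed, subject_index,
                               setting, test_index)
    obs_ss, cond_ss = ss.spawn(2)
    if config.observer_type == "deterministic":
        base: Observer = DeterministicObserver(threshold)
    else:
        base = PsychometricObserver(ObserverParams(
            threshold_logmar=threshold, slope=config.slope,
            guess_rate=config.guess_rate, lapse_rate=config.lapse_rate,
            seed=obs_ss))
    effect = config.clinic_effect if setting == "clinic" else config.home_effect
    return apply_condition(base, effect, session_seed=cond_ss)


def simulate_study(config: Optional[StudyConfig] = None) -> StudyDataset:
    """Run the full simulated study; bit-reproducible from the config."""
    cfg = config or StudyConfig()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.master_seed]))
    thresholds = rng.uniform(cfg.acuity_low, cfg.acuity_high, cfg.n_subjects)
    n_clinic_first = int(round(cfg.order_fraction * cfg.n_subjects))
    subjects = []
    for i, t in enumerate(thresholds):
        sessions: dict[tuple[str, int], SessionLog] = {}
        for setting in SETTINGS:
            for test_index in (1, TESTS_PER_SETTING):
                observer = _build_observer(cfg, float(t), setting, i, test_index)
                result = run_test(observer, cfg.staircase)
                sessions[(setting, test_index)] = SessionLog(
                    subject_id=f"S{i + 1:03d}", setting=setting,
                    test_index=test_index, config=cfg.staircase,
                    result=result)
        subjects.append(SubjectRecord(
            subject_id=f"S{i + 1:03d}", true_threshold_logmar=float(t),
            clinic_first=i < n_clinic_first, sessions=sessions))
    return StudyDataset(config=cfg, subjects=subjects)


@dataclass(frozen=True)
class StudySummary:
    comparisons: dict[str, AgreementSummary]
    skipped: dict[str, str]
    n_subjects: int

    def table(self) -> pd.DataFrame:
        return summary_frame(self.comparisons)


def summarize_study(dataset: StudyDataset, *,
                    loa_multiplier: float = 2.0) -> StudySummary:
    """The three Bland-Altman comparisons of the 2x2 design.

    Subjects with an off-scale result in either member of a pair are
    excluded from that comparison (and counted in ``skipped``'s reason),
    never silently dropped from the dataset.
    """
    comparisons: dict[str, AgreementSummary] = {}
    skipped: dict[str, str] = {}
    for name, key_a, key_b in COMPARISONS:
        a, b, excluded = [], [], 0
        for s in dataset.subjects:
            ra = s.sessions[key_a].result
            rb = s.sessions[key_b].result
            if ra.status is TestStatus.OK and rb.status is TestStatus.OK:
                a.append(ra.va_logmar)
                b.append(rb.va_logmar)
            else:
                excluded += 1
        try:
            comparisons[name] = bland_altman(a, b, loa_multiplier=loa_multiplier)
        except InsufficientDataError:
            skipped[name] = (f"only {len(a)} usable pair(s) "
                             f"({excluded} excluded as off-scale)")
            continue
    return StudySummary(comparisons=comparisons, skipped=skipped,
                        n_subjects=len(dataset.subjects))


def config_to_dict(config: StudyConfig) -> dict:
    return asdict(config)
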