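"""Two-phase adaptive acuity staircase with single-letter scoring.

The test mirrors computerised clinical logMAR thresholding:

1. **Range finding** — a single crowded letter is presented in 0.2 logMAR
   steps from 0.8 logMAR, descending while responses are correct (or
   ascending if the first response is wrong) until the smallest
   recognised size is found.
2. **Thresholding** — five crowded letters per line, starting 0.2 logMAR
   above the smallest recognised size, descending in 0.1 logMAR steps
   until all five letters on one line are wrong.  If errors occur on the
   first line, larger lines are presented until one is fully correct,
   then the descent resumes; sizes already attempted are never
   re-presented (their recorded responses are reused).
3. **Scoring** — single-letter scoring: the anchor is the largest
   fully-correct line, and each correct letter at sizes below it earns
   0.02 logMAR of credit, so

       VA = anchor - 0.02 x (letters correct below the anchor).

   The 0.02 x 5 = 0.1 identity makes a perfect step observer score
   exactly the smallest grid size it can read.

All sizes live on a 0.1 logMAR grid between a configurable floor and
ceiling; internally they are held as integer hundredths of a logMAR so
the staircase arithmetic is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

from .errors import DomainError, ProtocolError
from .geometry import DEFAULT_GRID_CEILING, DEFAULT_GRID_FLOOR
from .observers import Observer


class Phase(str, Enum):
    RANGE_FINDING = "range_finding"
    THRESHOLDING = "thresholding"


class TestStatus(str, Enum):
    OK = "ok"
    OFF_SCALE_HIGH = "off_scale_high"
    OFF_SCALE_LOW = "off_scale_low"


def _centi(x: float, name: str = "value") -> int:
    """Exact integer hundredths of a logMAR; rejects off-grid inputs."""
    v = round(x * 100)
    if abs(v - x * 100) > 1e-6:
        raise DomainError(f"{name} must lie on a 0.01 logMAR grid, got {x!r}")
    return int(v)


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of the two-phase staircase.

    The scoring identity ``score_increment * letters_per_line ==
    thresh_step`` (0.02 x 5 = 0.1) is enforced: without it, single-letter
    credit and whole-line steps would disagree and scores would drift off
    the 0.02 grid.
    """

    start_logmar: float = 0.8
    range_step: float = 0.2
    thresh_step: float = 0.1
    letters_per_line: int = 5
    fail_wrong_per_line: int = 5
    score_increment: float = 0.02
    grid_floor: float = DEFAULT_GRID_FLOOR
    grid_ceiling: float = DEFAULT_GRID_CEILING
    refresh_enabled: bool = False
    max_refresh_per_line: int = 1

    def __post_init__(self) -> None:
        if min(self.range_step, self.thresh_step, self.score_increment) <= 0:
            raise DomainError("all step sizes must be positive")
        if self.letters_per_line < 1 or self.fail_wrong_per_line < 1:
            raise DomainError("letters_per_line and fail_wrong_per_line must be >= 1")
        if self.fail_wrong_per_line > self.letters_per_line:
            raise DomainError("fail_wrong_per_line cannot exceed letters_per_line")
        if (_centi(self.score_increment, "score_increment") * self.letters_per_line
                != _centi(self.thresh_step, "thresh_step")):
            raise DomainError(
                "score_increment x letters_per_line must equal thresh_step "
                f"({self.score_increment} x {self.letters_per_line} != {self.thresh_step})")
        floor = _centi(self.grid_floor, "grid_floor")
        ceil = _centi(self.grid_ceiling, "grid_ceiling")
        start = _centi(self.start_logmar, "start_logmar")
        if not floor < start <= ceil:
            raise DomainError("require grid_floor < start_logmar <= grid_ceiling")
        if self.max_refresh_per_line < 0:
            raise DomainError("max_refresh_per_line must be >= 0")


@dataclass
class LetterTrial:
    """One letter presentation. ``refreshed`` marks a replaced response."""

    phase: Phase
    size_logmar: float
    letter_index: int
    correct: bool
    refreshed: bool = False


@dataclass(frozen=True)
class RangeFindResult:
    smallest_recognized_logmar: Optional[float]
    thresholding_start_logmar: Optional[float]
    status: TestStatus
    trials: list[LetterTrial] = field(default_factory=list)


@dataclass(frozen=True)
class TestResult:
    """Full record of one acuity test."""

    va_logmar: Optional[float]
    anchor_logmar: Optional[float]
    letters_correct_below_anchor: Optional[int]
    trials: list[LetterTrial]
    status: TestStatus
    smallest_recognized_logmar: Optional[float] = None

    @property
    def ok(self) -> bool:
        return self.status is TestStatus.OK


def _respond(observer: Observer, size_cl: int) -> bool:
    try:
        r = observer.respond(size_cl / 100.0)
    except (TypeError, AttributeError) as exc:
        raise ProtocolError(f"observer failed to answer: {exc}") from exc
    if r is None:
        raise ProtocolError("observer returned no response")
    return bool(r)


class _Session:
    """Mutable state of one running test, in integer centi-logMAR."""

    def __init__(self, observer: Observer, config: StaircaseConfig):
        self.obs = observer
        self.cfg = config
        self.floor = _centi(config.grid_floor)
        self.ceil = _centi(config.grid_ceiling)
        self.trials: list[LetterTrial] = []
        # final per-line responses, size_cl -> list[bool]
        self.lines: dict[int, list[bool]] = {}

    def _ask(self, size_cl: int, phase: Phase, letter_index: int = 0) -> LetterTrial:
        t = LetterTrial(phase=phase, size_logmar=size_cl / 100.0,
                        letter_index=letter_index,
                        correct=_respond(self.obs, size_cl))
        self.trials.append(t)
        return t

    # -- phase 1: range finding ------------------------------------------
    def range_find(self) -> RangeFindResult:
        step = _centi(self.cfg.range_step)
        size = _centi(self.cfg.start_logmar)
        first = self._ask(size, Phase.RANGE_FINDING)
        smallest: Optional[int] = None
        if first.correct:
            smallest = size
            while size > self.floor:
                size = max(size - step, self.floor)
                if self._ask(size, Phase.RANGE_FINDING).correct:
                    smallest = size
                else:
                    break
        else:
            while size < self.ceil:
                size = min(size + step, self.ceil)
                if self._ask(size, Phase.RANGE_FINDING).correct:
                    smallest = size
                    break
        if smallest is None:
            return RangeFindResult(None, None, TestStatus.OFF_SCALE_HIGH,
                                   self.trials)
        start = min(smallest + step, self.ceil)
        return RangeFindResult(smallest / 100.0, start / 100.0,
                               TestStatus.OK, self.trials)

    # -- phase 2: thresholding -------------------------------------------
    def _present_line(self, size_cl: int) -> list[bool]:
        cfg = self.cfg
        line = [self._ask(size_cl, Phase.THRESHOLDING, i)
                for i in range(cfg.letters_per_line)]
        if cfg.refresh_enabled:
            # a single isolated error on a line reads as a suspected
            # attention lapse: re-present that letter once, the new
            # response replacing the original
            refreshes = 0
            while refreshes < cfg.max_refresh_per_line:
                wrong = [t for t in line if not t.correct]
                if len(wrong) != 1:
                    break
                t = wrong[0]
                t.correct = _respond(self.obs, size_cl)
                t.refreshed = True
                refreshes += 1
        responses = [t.correct for t in line]
        self.lines[size_cl] = responses
        return responses

    def run_thresholding(self, start_cl: int) -> TestStatus:
        cfg = self.cfg
        step = _centi(cfg.thresh_step)
        size = start_cl
        resp = self._present_line(size)
        if not all(resp):
            # ascend until a fully-correct line anchors the descent
            while not all(resp):
                if size >= self.ceil:
                    return TestStatus.OFF_SCALE_HIGH
                size = min(size + step, self.ceil)
                resp = self._present_line(size)
        # descend from the clean line, reusing any recorded responses
        while size > self.floor:
            size = max(size - step, self.floor)
            resp = self.lines.get(size)
            if resp is None:
                resp = self._present_line(size)
            if sum(not r for r in resp) >= cfg.fail_wrong_per_line:
                break  # failure criterion met
            if size == self.floor:
                break  # floor line completed; credit whatever was read
        return TestStatus.OK


def range_find(observer: Observer, config: Optional[StaircaseConfig] = None
               ) -> RangeFindResult:
    """Run the single-letter range-finding phase alone."""
    return _Session(observer, config or StaircaseConfig()).range_find()


def run_thresholding(observer: Observer, start_logmar: float,
                     config: Optional[StaircaseConfig] = None
                     ) -> tuple[list[LetterTrial], TestStatus]:
    """Run the five-letter thresholding phase from a given start size."""
    cfg = config or StaircaseConfig()
    session = _Session(observer, cfg)
    start = _centi(start_logmar, "start_logmar")
    if not session.floor <= start <= session.ceil:
        raise DomainError(f"start {start_logmar} outside the logMAR grid")
    status = session.run_thresholding(start)
    return session.trials, status


def letter_score(trials: Sequence[LetterTrial],
                 config: Optional[StaircaseConfig] = None
                 ) -> tuple[Optional[float], Optional[float], Optional[int]]:
    """Single-letter score of a trial log: (va, anchor, letters_below).

    The anchor is the largest thresholding size with every letter correct;
    credit of ``score_increment`` is given per correct letter at sizes
    strictly below the anchor (each size counted once — refreshed
    responses already replaced the originals in the log).  Returns
    ``(None, None, None)`` when no fully-correct line exists.
    """
    cfg = config or StaircaseConfig()
    per_size: dict[int, dict[int, bool]] = {}
    for t in trials:
        if t.phase is Phase.THRESHOLDING or t.phase == Phase.THRESHOLDING.value:
            per_size.setdefault(_centi(t.size_logmar, "trial size"), {})[
                t.letter_index] = t.correct
    full = [sz for sz, letters in per_size.items()
            if len(letters) == cfg.letters_per_line and all(letters.values())]
    if not full:
        return None, None, None
    anchor = max(full)
    below = sum(sum(letters.values())
                for sz, letters in per_size.items() if sz < anchor)
    va_cl = anchor - _centi(cfg.score_increment) * below
    return va_cl / 100.0, anchor / 100.0, below


def run_test(observer: Observer,
             config: Optional[StaircaseConfig] = None) -> TestResult:
    """Run a complete acuity test: range finding, thresholding, scoring."""
    cfg = config or StaircaseConfig()
    session = _Session(observer, cfg)
    rf = session.range_find()
    if rf.status is not TestStatus.OK:
        return TestResult(None, None, None, session.trials, rf.status)
    status = session.run_thresholding(_centi(rf.thresholding_start_logmar))
    if status is not TestStatus.OK:
        return TestResult(None, None, None, session.trials, status,
                          rf.smallest_recognized_logmar)
    va, anchor, below = letter_score(session.trials, cfg)
    if va is None:
        return TestResult(None, None, None, session.trials,
                          TestStatus.OFF_SCALE_HIGH,
                          rf.smallest_recognized_logmar)
    # scoring identity, asserted on every run
    assert abs(va - (anchor - cfg.score_increment * below)) < 1e-9
    return TestResult(va, anchor, below, session.trials, TestStatus.OK,
                      rf.smallest_recognized_logmar)
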