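"""Session logs: JSON round-trip and flat CSV export of staircase runs.

A session log records who was tested, in which setting, the staircase
configuration and the complete letter-by-letter transcript, so a test can
be re-scored offline from the log alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .errors import DomainError
from .staircase import (LetterTrial, Phase, StaircaseConfig, TestResult,
                        TestStatus, letter_score)

PathLike = Union[str, Path]


@dataclass(frozen=True)
class SessionLog:
    subject_id: str
    setting: str
    test_index: int
    config: StaircaseConfig
    result: TestResult


def session_to_dict(log: SessionLog) -> dict:
    r = log.result
    return {
        "subject_id": log.subject_id,
        "setting": log.setting,
        "test_index": log.test_index,
        "config": asdict(log.config),
        "trials": [
            {"phase": t.phase.value, "size_logmar": t.size_logmar,
             "letter_index": t.letter_index, "correct": t.correct,
             "refreshed": t.refreshed}
            for t in r.trials
        ],
        "anchor_logmar": r.anchor_logmar,
        "letters_correct_below_anchor": r.letters_correct_below_anchor,
        "va_logmar": r.va_logmar,
        "status": r.status.value,
        "smallest_recognized_logmar": r.smallest_recognized_logmar,
    }


def session_from_dict(payload: dict) -> SessionLog:
    try:
        config = StaircaseConfig(**payload["config"])
        trials = [LetterTrial(phase=Phase(t["phase"]),
                              size_logmar=t["size_logmar"],
                              letter_index=t["letter_index"],
                              correct=t["correct"],
                              refreshed=t.get("refreshed", False))
                  for t in payload["trials"]]
        result = TestResult(
            va_logmar=payload["va_logmar"],
            anchor_logmar=payload["anchor_logmar"],
            letters_correct_below_anchor=payload["letters_correct_below_anchor"],
            trials=trials,
            status=TestStatus(payload["status"]),
            smallest_recognized_logmar=payload.get("smallest_recognized_logmar"),
        )
        return SessionLog(subject_id=payload["subject_id"],
                          setting=payload["setting"],
                          test_index=payload["test_index"],
                          config=config, result=result)
    except (KeyError, TypeError, ValueError) as exc:
        raise DomainError(f"malformed session log: {exc}") from exc


def write_session_json(log: SessionLog, path: PathLike) -> None:
    Path(path).write_text(json.dumps(session_to_dict(log), indent=1) + "\n")


def read_session_json(path: PathLike) -> SessionLog:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise DomainError(f"{path}: invalid JSON at line {exc.lineno}: "
                          f"{exc.msg}") from exc
    return session_from_dict(payload)


def rescore(log: SessionLog) -> Optional[float]:
    """Re-run single-letter scoring on the logged transcript."""
    va, _anchor, _below = letter_score(log.result.trials, log.config)
    return va


def trials_frame(logs: Iterable[SessionLog]) -> pd.DataFrame:
    """Flat export: one row per letter presentation across sessions."""
    rows = []
    for log in logs:
        for t in log.result.trials:
            rows.append({
                "subject_id": log.subject_id,
                "setting": log.setting,
                "test_index": log.test_index,
                "phase": t.phase.value,
                "size_logmar": t.size_logmar,
                "letter_index": t.letter_index,
                "correct": t.correct,
                "refreshed": t.refreshed,
            })
    return pd.DataFrame(rows, columns=[
        "subject_id", "setting", "test_index", "phase", "size_logmar",
        "letter_index", "correct", "refreshed"])
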