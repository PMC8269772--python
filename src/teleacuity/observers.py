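"""Synthetic observers: the package's generator of simulated responses.

Every acuity test in this package is answered by an observer object with a
single method ``respond(size_logmar) -> bool``.  Three kinds are provided:

* :class:`DeterministicObserver` — an all-or-none step function, correct
  iff the presented size is at least its threshold.  The exact-oracle
  observer for staircase tests.
* :class:`PsychometricObserver` — a forced-choice letter identifier whose
  per-letter probability of a correct response follows a logistic
  psychometric function with a guessing floor and a lapse ceiling:

      P(correct | s) = g + (1 - g - l) * logistic(beta * (s - t))

  where ``t`` is the true threshold (logMAR), ``beta`` the slope per
  logMAR, ``g`` the guess rate and ``l`` the lapse rate.  At ``s = t``
  performance sits halfway between floor and ceiling.  Responses to
  successive letters are independent draws from a seeded generator.
* :class:`ScriptedObserver` — replays a fixed response sequence; used for
  exact trial-by-trial staircase fixtures.

:func:`apply_condition` wraps any observer with a testing-condition
perturbation: a calibration scale error (displayed letters uniformly too
large or too small, which on the logMAR scale is an additive offset of
``log10(scale)``) and a per-session threshold jitter draw modelling
uncontrolled between-session variation (lighting, screen brightness,
positioning) in home testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Protocol, runtime_checkable

import numpy as np

from .errors import DomainError, ScriptExhaustedError


@runtime_checkable
class Observer(Protocol):
    def respond(self, size_logmar: float) -> bool:
        """Answer one letter presentation at the given physical size."""
        ...


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the logistic forced-choice observer.

    threshold_logmar is the size at which performance is halfway between
    the guessing floor and the lapse-limited ceiling.  slope is in units
    of 1/logMAR (larger = steeper = a more reliable responder).
    """

    threshold_logmar: float
    slope: float = 30.0
    guess_rate: float = 0.1
    lapse_rate: float = 0.01
    seed: object = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise DomainError("psychometric slope must be positive")
        if not 0 <= self.guess_rate < 1 - self.lapse_rate <= 1:
            raise DomainError(
                "require 0 <= guess_rate < 1 - lapse_rate <= 1, got "
                f"guess={self.guess_rate}, lapse={self.lapse_rate}")


class DeterministicObserver:
    """All-or-none observer: correct iff presented size >= threshold."""

    # small tolerance so grid sizes compare reliably against equal thresholds
    _EPS = 1e-9

    def __init__(self, threshold_logmar: float):
        self.threshold_logmar = float(threshold_logmar)

    def respond(self, size_logmar: float) -> bool:
        return size_logmar >= self.threshold_logmar - self._EPS


class PsychometricObserver:
    """Stochastic observer drawing per-letter responses from a seeded RNG."""

    def __init__(self, params: ObserverParams):
        self.params = params
        self._rng = np.random.default_rng(params.seed)

    def p_correct(self, size_logmar: float) -> float:
        p = self.params
        x = p.slope * (size_logmar - p.threshold_logmar)
        if x >= 0:
            f = 1.0 / (1.0 + math.exp(-x))
        else:  # numerically stable for large negative x
            e = math.exp(x)
            f = e / (1.0 + e)
        return p.guess_rate + (1.0 - p.guess_rate - p.lapse_rate) * f

    def respond(self, size_logmar: float) -> bool:
        return bool(self._rng.random() < self.p_correct(size_logmar))


class ScriptedObserver:
    """Replays a pre-recorded response list, one entry per presentation."""

    def __init__(self, responses: Iterable[bool]):
        self._responses = [bool(r) for r in responses]
        self._pos = 0

    @property
    def remaining(self) -> int:
        return len(self._responses) - self._pos

    def respond(self, size_logmar: float) -> bool:
        if self._pos >= len(self._responses):
            raise ScriptExhaustedError(
                f"script exhausted after {self._pos} responses "
                f"(next presentation at {size_logmar:g} logMAR)")
        r = self._responses[self._pos]
        self._pos += 1
        return r


@dataclass(frozen=True)
class ConditionEffect:
    """Perturbations a testing condition applies to every session.

    size_scale_error: multiplicative error on displayed sizes from an
    imperfect ruler calibration; a value of 1.122 makes every letter 12.2%
    too large, i.e. an additive +0.05 shift of each presented logMAR size.
    threshold_jitter_sd: SD (logMAR) of a zero-mean normal draw added to
    the observer's effective threshold once per session, modelling
    uncontrolled between-session variation in the home environment.
    """

    size_scale_error: float = 1.0
    threshold_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.size_scale_error <= 0:
            raise DomainError("size_scale_error must be positive")
        if self.threshold_jitter_sd < 0:
            raise DomainError("threshold_jitter_sd must be non-negative")


class ConditionedObserver:
    """An observer evaluated under a testing-condition perturbation.

    Both effects reduce to one additive offset on presented sizes: a size
    scale error of c shifts each presented size by +log10(c), and a
    threshold shift of +j is equivalent to presenting sizes shifted by -j.
    """

    def __init__(self, inner: Observer, logmar_offset: float):
        self.inner = inner
        self.logmar_offset = logmar_offset

    def respond(self, size_logmar: float) -> bool:
        return self.inner.respond(size_logmar + self.logmar_offset)


def deterministic_observer(threshold_logmar: float) -> DeterministicObserver:
    return DeterministicObserver(threshold_logmar)


def psychometric_observer(params: ObserverParams) -> PsychometricObserver:
    return PsychometricObserver(params)


def scripted_observer(responses: Iterable[bool]) -> ScriptedObserver:
    return ScriptedObserver(responses)


def apply_condition(observer: Observer, effect: ConditionEffect,
                    session_seed: object = None) -> ConditionedObserver:
    """Wrap an observer with a condition's size-scale and jitter effects.

    The threshold jitter is drawn once, from ``session_seed``, and applies
    to every presentation of that session; identical seeds give identical
    sessions.  With ``size_scale_error == 1`` and zero jitter the wrapper
    is an exact identity.
    """
    jitter = 0.0
    if effect.threshold_jitter_sd > 0:
        rng = np.random.default_rng(session_seed)
        jitter = float(rng.normal(0.0, effect.threshold_jitter_sd))
    offset = math.log10(effect.size_scale_error) - jitter
    return ConditionedObserver(observer, offset)
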