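"""Bland-Altman agreement and test-retest variability statistics.

For paired acuity measurements (a_i, b_i) the per-pair difference is
``d_i = a_i - b_i`` (first-listed minus second-listed).  The summary
reports

* bias: mean(d);
* sd: sample standard deviation of d (n - 1 denominator);
* 95% CI of the bias: bias +/- t_{0.975, n-1} * sd / sqrt(n);
* 95% limits of agreement: bias +/- 2 * sd.  The multiplier is exactly 2
  by default — the convention used in clinical test-retest reporting of
  "mean +/- 2SD" — with the asymptotic 1.96 available by option;
* a Shapiro-Wilk normality p-value on the differences, reported as a
  diagnostic and never used as a gate.

Acuities are logMAR throughout; 0.02 logMAR corresponds to one letter of
single-letter (ETDRS-style) scoring, so a difference of 0.12 logMAR is
six letters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InsufficientDataError

LOGMAR_PER_LETTER = 0.02

PAIR_COLUMNS = ("subject_id", "a", "b")


@dataclass(frozen=True)
class AgreementSummary:
    """Bland-Altman summary of one set of paired measurements."""

    n: int
    bias: float
    sd: float
    ci_low: float
    ci_high: float
    loa_low: float
    loa_high: float
    loa_multiplier: float
    normality_stat: Optional[float] = None
    normality_p: Optional[float] = None

    def __post_init__(self) -> None:
        half = self.loa_multiplier * self.sd
        if not (math.isclose(self.loa_low, self.bias - half, abs_tol=1e-12)
                and math.isclose(self.loa_high, self.bias + half, abs_tol=1e-12)):
            raise DomainError("limits of agreement inconsistent with bias and SD")
        if not self.ci_low - 1e-12 <= self.bias <= self.ci_high + 1e-12:
            raise DomainError("bias outside its own confidence interval")

    @property
    def loa_half_width(self) -> float:
        return self.loa_multiplier * self.sd


def normality_check(differences: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk test of the paired differences.

    Requires at least three non-identical values; a constant vector has no
    defined normality statistic and raises :class:`DomainError`.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 3:
        raise InsufficientDataError("normality test needs n >= 3")
    if np.ptp(d) == 0:
        raise DomainError("normality undefined for a constant vector")
    stat, p = stats.shapiro(d)
    return float(stat), float(p)


def bland_altman(a: Sequence[float], b: Sequence[float], *,
                 loa_multiplier: float = 2.0) -> AgreementSummary:
    """Bland-Altman summary of paired measurements ``a`` and ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DomainError("a and b must be 1-d arrays of equal length")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DomainError("measurements must be finite")
    n = a.size
    if n < 2:
        raise InsufficientDataError(f"need at least 2 pairs, got {n}")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    t_crit = float(stats.t.ppf(0.975, n - 1))
    sem = sd / math.sqrt(n)
    stat = p = None
    if n >= 3 and np.ptp(d) > 0:
        stat, p = normality_check(d)
    return AgreementSummary(
        n=n, bias=bias, sd=sd,
        ci_low=bias - t_crit * sem, ci_high=bias + t_crit * sem,
        loa_low=bias - loa_multiplier * sd,
        loa_high=bias + loa_multiplier * sd,
        loa_multiplier=loa_multiplier,
        normality_stat=stat, normality_p=p)


def bland_altman_pairs(pairs: pd.DataFrame, *,
                       loa_multiplier: float = 2.0) -> AgreementSummary:
    """Bland-Altman summary of a paired-measurements table (columns a, b)."""
    _validate_pairs(pairs)
    return bland_altman(pairs["a"].to_numpy(), pairs["b"].to_numpy(),
                        loa_multiplier=loa_multiplier)


def logmar_to_letters(delta_logmar: float) -> Union[int, float]:
    """Convert a logMAR difference to letters at 0.02 logMAR per letter.

    Returns an exact ``int`` when the quotient is within 1e-9 of an
    integer (the usual case for on-grid scores), otherwise a float.
    """
    letters = delta_logmar / LOGMAR_PER_LETTER
    nearest = round(letters)
    if abs(letters - nearest) <= 1e-9:
        return int(nearest)
    return letters


@dataclass(frozen=True)
class SubgroupResult:
    summaries: dict[str, AgreementSummary]
    skipped: dict[str, str]


def subgroup_summaries(pairs: pd.DataFrame, group_field: str = "group", *,
                       min_n: int = 2,
                       loa_multiplier: float = 2.0) -> SubgroupResult:
    """Per-group Bland-Altman summaries; undersized groups are skipped."""
    _validate_pairs(pairs)
    if group_field not in pairs.columns:
        raise DomainError(f"no such group field: {group_field!r}")
    summaries: dict[str, AgreementSummary] = {}
    skipped: dict[str, str] = {}
    for label, sub in pairs.groupby(group_field, sort=True):
        if len(sub) < min_n:
            skipped[str(label)] = f"only {len(sub)} pair(s), need {min_n}"
            continue
        summaries[str(label)] = bland_altman(
            sub["a"].to_numpy(), sub["b"].to_numpy(),
            loa_multiplier=loa_multiplier)
    return SubgroupResult(summaries=summaries, skipped=skipped)


def read_pairs_csv(path) -> pd.DataFrame:
    """Read a paired-measurements CSV: subject_id, a, b[, group]."""
    df = pd.read_csv(path)
    _validate_pairs(df)
    return df


def _validate_pairs(df: pd.DataFrame) -> None:
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"paired table missing column(s): {missing}")
    for c in ("a", "b"):
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            bad = df.index[vals.isna()][0]
            raise DomainError(f"non-numeric value in column {c!r} at row {bad}")


def summary_frame(summaries: dict[str, AgreementSummary],
                  decimals: int = 2) -> pd.DataFrame:
    """Report table: one column per comparison, clinical 2-dp rounding."""
    rows = ["n", "Mean difference", "95% CI of mean", "SD of differences",
            "95% limits of agreement"]
    data = {}
    for name, s in summaries.items():
        data[name] = [
            s.n,
            f"{s.bias:.{decimals}f}",
            f"{s.ci_low:.{decimals}f}, {s.ci_high:.{decimals}f}",
            f"{s.sd:.{decimals}f}",
            f"+/-{s.loa_half_width:.{decimals}f}",
        ]
    return pd.DataFrame(data, index=rows)


def plot_frame(a: Sequence[float], b: Sequence[float],
               summary: Optional[AgreementSummary] = None) -> pd.DataFrame:
    """Bland-Altman plot data: per-pair mean vs difference plus the bias
    and limits-of-agreement lines, as columns ready for external plotting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if summary is None:
        summary = bland_altman(a, b)
    return pd.DataFrame({
        "pair_mean": (a + b) / 2.0,
        "difference": a - b,
        "bias": summary.bias,
        "loa_low": summary.loa_low,
        "loa_high": summary.loa_high,
    })
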