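"""Concordance with a reference assay: confusion matrix, diagnostics, exact tests.

Diagnostic metrics keep their numerator/denominator pairs so reported
percentages can always be traced back to counts; an undefined metric (zero
denominator) is flagged rather than silently reported as 0.  Display
percentages are rounded half-up to one decimal, the precision clinical
reports use.

The two-sided Fisher exact p-value follows the minimum-likelihood rule
(the convention of mainstream statistical software): sum the hypergeometric
probabilities of every table with the observed margins whose probability
does not exceed that of the observed table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

from scipy import stats

from .errors import ValidationError

__all__ = [
    "ConfusionMatrix",
    "Proportion",
    "DiagnosticMetrics",
    "TwoByTwo",
    "confusion_matrix",
    "diagnostic_metrics",
    "fisher_exact_two_sided",
    "chi_square_test",
    "pearson_r",
    "round_percent",
]


def round_percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage rounded half-up, e.g. 22/23 -> 95.7, 5/63 -> 7.9."""
    if denominator == 0:
        raise ValidationError("cannot form a percentage with denominator 0")
    pct = Decimal(numerator) / Decimal(denominator) * 100
    quantum = Decimal(1).scaleb(-ndigits)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Proportion:
    """A proportion with its counts retained for audit."""

    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def value(self) -> Optional[float]:
        return self.numerator / self.denominator if self.defined else None

    @property
    def percent(self) -> Optional[float]:
        """One-decimal display percentage (half-up), or None when undefined."""
        return round_percent(self.numerator, self.denominator) if self.defined else None


@dataclass(frozen=True)
class ConfusionMatrix:
    """Joint counts of test vs. reference calls.

    tp: both positive; fn: reference positive, test negative;
    fp: reference negative, test positive; tn: both negative.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("confusion-matrix counts must be >= 0")
        if self.total == 0:
            raise ValidationError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: Proportion
    specificity: Proportion
    ppv: Proportion
    npv: Proportion


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 table: rows are groups, columns are outcome +/-."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("2x2 counts must be >= 0")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("2x2 table is empty")

    @property
    def rows(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def confusion_matrix(
    test_calls: Mapping[str, str], reference_calls: Mapping[str, str]
) -> ConfusionMatrix:
    """Cross-tabulate per-sample "positive"/"negative" calls.

    Samples present on only one side are reported with a warning and
    excluded; an empty intersection is an error.
    """
    shared = sorted(set(test_calls) & set(reference_calls))
    if not shared:
        raise ValidationError("test and reference calls share no samples")
    dropped = sorted(set(test_calls) ^ set(reference_calls))
    if dropped:
        warnings.warn(f"samples present on one side only (excluded): {dropped}", stacklevel=2)
    tp = fn = fp = tn = 0
    for s in shared:
        t_pos = _as_positive(test_calls[s], s, "test")
        r_pos = _as_positive(reference_calls[s], s, "reference")
        if t_pos and r_pos:
            tp += 1
        elif r_pos:
            fn += 1
        elif t_pos:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def _as_positive(value: str, sample: str, side: str) -> bool:
    v = str(value).strip().lower()
    if v not in {"positive", "negative"}:
        raise ValidationError(f"{side} call for sample {sample!r} must be positive/negative, got {value!r}")
    return v == "positive"


def diagnostic_metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV and NPV against the reference assay."""
    return DiagnosticMetrics(
        sensitivity=Proportion(cm.tp, cm.tp + cm.fn),
        specificity=Proportion(cm.tn, cm.tn + cm.fp),
        ppv=Proportion(cm.tp, cm.tp + cm.fp),
        npv=Proportion(cm.tn, cm.tn + cm.fn),
    )


def fisher_exact_two_sided(table: TwoByTwo) -> float:
    """Two-sided Fisher exact p by the minimum-likelihood method.

    A zero margin makes every table with the given margins identical, so
    p = 1 by convention (with a warning).
    """
    if 0 in table.margins:
        warnings.warn("2x2 table has a zero margin; Fisher p = 1 by convention", stacklevel=2)
        return 1.0
    p = stats.fisher_exact(table.rows, alternative="two-sided").pvalue
    return float(min(p, 1.0))


def chi_square_test(table: TwoByTwo, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table (1 df), by default without continuity correction."""
    if 0 in table.margins:
        raise ValidationError("2x2 table has a zero margin: use Fisher's exact test instead")
    res = stats.chi2_contingency(table.rows, correction=yates)
    return float(res.statistic), float(res.pvalue)


def pearson_r(paired_scores: Sequence[tuple[float, float]]) -> float:
    """Sample Pearson correlation of (test, reference) score pairs."""
    if len(paired_scores) < 3:
        raise ValidationError(f"correlation needs >= 3 pairs, got {len(paired_scores)}")
    x = [float(a) for a, _ in paired_scores]
    y = [float(b) for _, b in paired_scores]
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValidationError("correlation undefined: one side is constant")
    r = stats.pearsonr(x, y).statistic
    return float(r)
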