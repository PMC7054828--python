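"""Diagnostic test characteristics of an algorithm against the reference
standard.

Predicted labels are cross-tabulated against chart-review reference labels
into TP/TN/FP/FN; sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
PPV = TP/(TP+FP), NPV = TN/(TN+FN), and the positivity rate is the percent
of the classified cohort called positive. Each proportion carries a 95%
Wald interval p ± 1.96·√(p(1−p)/n), clipped to [0, 1]; a zero denominator
yields an absent estimate rather than a silent zero.

Display rounding is half-up: 3 decimals for proportions, 1 for the rate.
"""

from __future__ import annotations

import dataclasses
import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import pandas as pd

from oacphen.errors import LinkageError, UndefinedMetricError

Z_95 = 1.96


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals (display rule)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def round_rate(x: float) -> float:
    """Display rounding for the positivity rate: half-up at two decimals,
    then half-up at one.

    The two-stage rule matches the display convention evident in the
    reported validation table (e.g. 13.6476% prints as 13.7, via 13.65).
    """
    return round_half_up(round_half_up(x, 2), 1)


@dataclasses.dataclass(frozen=True)
class Counts2x2:
    """TP/TN/FP/FN of predicted labels against the reference standard."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("2x2 cells must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def transpose(self) -> "Counts2x2":
        """Swap the roles of predicted and reference labels."""
        return Counts2x2(tp=self.tp, tn=self.tn, fp=self.fn, fn=self.fp)


@dataclasses.dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its 95% confidence interval."""

    point: float
    ci_low: float
    ci_high: float

    def rounded(self, ndigits: int = 3) -> tuple[float, float, float]:
        return (
            round_half_up(self.point, ndigits),
            round_half_up(self.ci_low, ndigits),
            round_half_up(self.ci_high, ndigits),
        )


def proportion_ci(numerator: int, denominator: int) -> MetricEstimate:
    """Binomial proportion with a 95% Wald interval.

    Raises :class:`UndefinedMetricError` when the denominator is zero; the
    caller decides whether that propagates or becomes an absent estimate.
    """
    if denominator <= 0:
        raise UndefinedMetricError("proportion undefined: zero denominator")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    p = numerator / denominator
    half = Z_95 * math.sqrt(p * (1.0 - p) / denominator)
    return MetricEstimate(p, max(0.0, p - half), min(1.0, p + half))


def tabulate(predicted: pd.DataFrame, reference: pd.DataFrame) -> Counts2x2:
    """Cross-tabulate predicted vs reference labels into a 2x2.

    ``predicted`` needs ``patient_id`` and ``positive``; ``reference`` needs
    ``patient_id`` and a boolean label column (``reference_label`` or
    ``ed_oac_prescribed``). The id sets must match exactly.
    """
    label_col = "reference_label" if "reference_label" in reference else "ed_oac_prescribed"
    pred_ids = set(predicted["patient_id"])
    ref_ids = set(reference["patient_id"])
    if pred_ids != ref_ids:
        raise LinkageError(
            f"label sets differ: {len(pred_ids - ref_ids)} predicted-only, "
            f"{len(ref_ids - pred_ids)} reference-only"
        )
    m = predicted[["patient_id", "positive"]].merge(
        reference[["patient_id", label_col]], on="patient_id", validate="1:1"
    )
    pos = m["positive"].to_numpy(dtype=bool)
    ref = m[label_col].to_numpy(dtype=bool)
    return Counts2x2(
        tp=int((pos & ref).sum()),
        tn=int((~pos & ~ref).sum()),
        fp=int((pos & ~ref).sum()),
        fn=int((~pos & ref).sum()),
    )


@dataclasses.dataclass(frozen=True)
class ValidationResult:
    """One algorithm's full row of test characteristics."""

    algo_id: int
    counts: Counts2x2
    sensitivity: Optional[MetricEstimate]
    specificity: Optional[MetricEstimate]
    ppv: Optional[MetricEstimate]
    npv: Optional[MetricEstimate]
    rate_percent: Optional[float]

    def to_row(self) -> dict:
        """Flat dict for results.csv, display-rounded."""
        row: dict = {
            "algo_id": self.algo_id,
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
        }
        for name, est in [
            ("sens", self.sensitivity),
            ("spec", self.specificity),
            ("ppv", self.ppv),
            ("npv", self.npv),
        ]:
            if est is None:
                row[name] = row[f"{name}_lo"] = row[f"{name}_hi"] = None
            else:
                row[name], row[f"{name}_lo"], row[f"{name}_hi"] = est.rounded(3)
        row["rate_percent"] = (
            None if self.rate_percent is None else round_rate(self.rate_percent)
        )
        return row


def _maybe(numerator: int, denominator: int) -> Optional[MetricEstimate]:
    try:
        return proportion_ci(numerator, denominator)
    except UndefinedMetricError:
        return None


def evaluate(counts: Counts2x2, algo_id: int = 0) -> ValidationResult:
    """Compute all test characteristics from a 2x2 table.

    A metric with a zero denominator is absent; the others are still
    computed.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    rate = 100.0 * (tp + fp) / counts.n if counts.n else None
    return ValidationResult(
        algo_id=algo_id,
        counts=counts,
        sensitivity=_maybe(tp, tp + fn),
        specificity=_maybe(tn, tn + fp),
        ppv=_maybe(tp, tp + fp),
        npv=_maybe(tn, tn + fn),
        rate_percent=rate,
    )
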