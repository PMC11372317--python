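"""Evaluation of extraction methods against reference labels.

The positive class throughout is "patient has sensitive reproductive
information" (FRA).  Precision is tp/(tp+fp): of the patients the method
flags, how many truly are FRA.  Recall is tp/(tp+fn): of the true FRA
patients, how many the method finds.  Ratios with a zero denominator are
reported as not-applicable (None), never as zero.  Confusion matrices are
oriented rows = prediction, columns = reference.

Rates are kept as exact rationals internally; display values are
percentages rounded half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional

import pandas as pd

from .emr_model import Corpus
from .rounding import percentage
from .rule_engine import RuleSet

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion",
    "precision_recall",
    "compare_methods",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 cross-tabulation, FRA = positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )

    def to_frame(self) -> pd.DataFrame:
        """Rows = prediction (1/0), columns = reference (1/0)."""
        return pd.DataFrame(
            [[self.tp, self.fp], [self.fn, self.tn]],
            index=pd.Index([1, 0], name="prediction"),
            columns=pd.Index([1, 0], name="reference"),
        )


@dataclass(frozen=True)
class EvalReport:
    """Precision/recall of one method, with exact and display values."""

    matrix: ConfusionMatrix
    precision: Optional[Fraction]
    recall: Optional[Fraction]
    n: int
    method_label: str = ""

    @property
    def precision_pct(self) -> Optional[float]:
        if self.precision is None:
            return None
        return percentage(self.precision.numerator, self.precision.denominator)

    @property
    def recall_pct(self) -> Optional[float]:
        if self.recall is None:
            return None
        return percentage(self.recall.numerator, self.recall.denominator)

    def summary(self) -> str:
        fmt = lambda v: "n/a" if v is None else f"{v:.2f}%"
        m = self.matrix
        return (
            f"{self.method_label or 'method'}: n={self.n} "
            f"tp={m.tp} fp={m.fp} fn={m.fn} tn={m.tn} "
            f"precision={fmt(self.precision_pct)} recall={fmt(self.recall_pct)}"
        )


def confusion(pred: Mapping[str, bool], truth: Mapping[str, bool]) -> ConfusionMatrix:
    """Cross-tabulate per-patient predictions against reference labels.

    The two mappings must cover exactly the same patients; a mismatch is a
    hard error reporting the symmetric difference.
    """
    diff = set(pred) ^ set(truth)
    if diff:
        raise ValueError(f"pred/truth patient sets differ: {sorted(diff)[:20]}")
    tp = fp = fn = tn = 0
    for pid, p in pred.items():
        t = truth[pid]
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp, fp, fn, tn)


def precision_recall(matrix: ConfusionMatrix, method_label: str = "") -> EvalReport:
    """Exact precision and recall from a confusion matrix."""
    precision = (
        Fraction(matrix.tp, matrix.tp + matrix.fp) if matrix.tp + matrix.fp > 0 else None
    )
    recall = (
        Fraction(matrix.tp, matrix.tp + matrix.fn) if matrix.tp + matrix.fn > 0 else None
    )
    return EvalReport(matrix, precision, recall, matrix.n, method_label)


def compare_methods(
    corpus: Corpus,
    truth: Mapping[str, bool],
    rulesets: Mapping[str, RuleSet],
    stratify_by: Optional[str] = None,
) -> tuple[dict[str, EvalReport], Optional[pd.DataFrame]]:
    """Evaluate several rule sets on one corpus against shared truth labels.

    Returns one report per method and, optionally, per-hospital or
    per-year 0/1 stratified counts (the stratified counts always sum to
    the global matrix).
    """
    from .extraction import run_eppgi, stratify as _stratify

    reports: dict[str, EvalReport] = {}
    results = {}
    patient_ids = corpus.patient_ids()
    for label, ruleset in rulesets.items():
        result = run_eppgi(corpus, ruleset)
        results[label] = result
        pred = {pid: result.patient_flags.get(pid, False) for pid in patient_ids}
        ref = {pid: truth[pid] for pid in patient_ids}
        reports[label] = precision_recall(confusion(pred, ref), method_label=label)
    table = _stratify(results, corpus, by=stratify_by) if stratify_by else None
    return reports, table
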