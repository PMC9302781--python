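"""Scoring against the gold standard: confusion matrix, sensitivity,
specificity and lesion-zone agreement.  MF is the positive class."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "sensitivity_specificity",
    "zone_agreement",
]

_LABELS = {"MF", "NF+BF"}
_ZONES = {"upper", "lower"}


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(pred: Sequence[str], gold: Sequence[str]) -> ConfusionMatrix:
    """Cross-tabulate aligned label lists with MF positive."""
    if len(pred) != len(gold):
        raise EvaluationError("prediction and gold lists differ in length")
    bad = {l for l in (*pred, *gold)} - _LABELS
    if bad:
        raise EvaluationError(f"unknown labels: {sorted(bad)}")
    tp = sum(p == g == "MF" for p, g in zip(pred, gold))
    tn = sum(p == g == "NF+BF" for p, g in zip(pred, gold))
    fp = sum(p == "MF" and g == "NF+BF" for p, g in zip(pred, gold))
    fn = sum(p == "NF+BF" and g == "MF" for p, g in zip(pred, gold))
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def sensitivity_specificity(cm: ConfusionMatrix) -> tuple[float, float]:
    """(sensitivity %, specificity %) = (100 TP/(TP+FN), 100 TN/(TN+FP)).

    Undefined when a class is empty.  Values are percentages in [0, 100];
    report them rounded to 2 decimal places.
    """
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise EvaluationError("sensitivity/specificity undefined for empty class")
    return 100.0 * cm.tp / (cm.tp + cm.fn), 100.0 * cm.tn / (cm.tn + cm.fp)


def zone_agreement(
    pred_zones: Mapping[str, str | None],
    gold_zones: Mapping[str, str],
) -> float:
    """Fraction of comparable breasts whose predicted zone matches the gold.

    Only breasts with a single stated zone ("upper"/"lower"; roster strings
    "Upper Zone"/"Lower Zone" are accepted) are comparable; entries such as
    "More Areas" or "Not Available" are excluded.  A missing prediction for
    a comparable breast counts as a mismatch.
    """
    normalize = {"upper": "upper", "lower": "lower",
                 "upper zone": "upper", "lower zone": "lower"}
    matched = comparable = 0
    for breast_id, gz in gold_zones.items():
        g = normalize.get(str(gz).strip().lower())
        if g is None:
            continue
        comparable += 1
        p = pred_zones.get(breast_id)
        if p is not None and normalize.get(str(p).strip().lower()) == g:
            matched += 1
    if comparable == 0:
        raise EvaluationError("no comparable zone entries")
    return matched / comparable
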