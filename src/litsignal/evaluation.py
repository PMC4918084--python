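"""Gold-standard evaluation: confusion matrices, precision/recall/F1, ROC.

The gold standard is a list of (subject, outcome, label) control pairs in
the style of the OMOP drug-safety reference set: a handful of adverse-event
outcomes, each with positive and negative drug controls.  Evaluation aligns
detector output with the gold standard at the drug or the drug-class level,
counts a passing signal on a positive control as TP and on a negative
control as FP, and treats a subject–outcome with no score at all — e.g. a
drug with no supporting article in the literature — as a non-signal ranked
below every scored pair.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import rankdata

from .abstraction import AbstractionLevel
from .candidates import DrugMap
from .errors import ConfigurationError, ParseError, ValidationError

log = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class GoldCase:
    """One control pair: subject (ingredient or ATC4 class), outcome term,
    positive/negative label."""

    subject: str
    outcome: str
    positive: bool


def load_gold(path: str | Path) -> list[GoldCase]:
    """Read the gold TSV: ``subject<TAB>outcome_term<TAB>label``."""
    path = Path(path)
    cases: dict[tuple[str, str], bool] = {}
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected subject, outcome_term, label")
            subject, outcome, label = fields[0], fields[1], fields[2].strip().lower()
            if label not in (POSITIVE, NEGATIVE):
                raise ParseError(f"{path}:{lineno}: label must be positive/negative, got {label!r}")
            key = (subject, outcome)
            positive = label == POSITIVE
            if key in cases and cases[key] != positive:
                raise ParseError(f"{path}:{lineno}: conflicting labels for {key}")
            cases[key] = positive
    return [GoldCase(s, o, p) for (s, o), p in sorted(cases.items())]


def write_gold(cases: Iterable[GoldCase], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("# subject\toutcome_term\tlabel\n")
        for case in sorted(cases, key=lambda c: (c.subject, c.outcome)):
            label = POSITIVE if case.positive else NEGATIVE
            handle.write(f"{case.subject}\t{case.outcome}\t{label}\n")


def lift_gold_to_classes(gold: Iterable[GoldCase], drug_map: DrugMap) -> list[GoldCase]:
    """Propagate drug-level labels to all ATC4 classes of each drug.

    A class receiving both a positive and a negative member label for the
    same outcome becomes a positive control and is removed from the
    negatives (the class-conflict rule).
    """
    labels: dict[tuple[str, str], set[bool]] = defaultdict(set)
    for case in gold:
        for atc4 in drug_map.classes_of(case.subject):
            labels[(atc4, case.outcome)].add(case.positive)
    return [
        GoldCase(subject, outcome, True in seen)
        for (subject, outcome), seen in sorted(labels.items())
    ]


def map_outcome_to_level(outcome: str, level: AbstractionLevel) -> frozenset[str]:
    """Representatives of a gold-standard outcome under the level.

    Raises a configuration error when the outcome is excluded — the chosen
    IC range cannot represent it, so evaluation at this level is undefined.
    A multi-classified outcome may map to several representatives; the
    caller decides how to use them.
    """
    reps = level.map_term(outcome)
    if not reps:
        raise ConfigurationError(
            f"outcome {outcome!r} is excluded by the abstraction level "
            f"(ic range [{level.ic_min}, {level.ic_max}), tree level {level.level})"
        )
    return reps


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


def confusion_at_threshold(
    scores: Mapping[tuple[str, str], float],
    gold: Iterable[GoldCase],
    threshold: float,
    direction: str = "less",
) -> ConfusionMatrix:
    """Count the confusion matrix of one threshold over the gold standard.

    `scores` maps (subject, outcome) to the detector's statistic (adjusted
    p-value with ``direction="less"``, PRR with ``direction="greater"``);
    comparisons are strict.  A gold pair with no score is a non-signal.
    """
    if direction not in ("less", "greater"):
        raise ValidationError(f"direction must be 'less' or 'greater', got {direction!r}")
    tp = fp = tn = fn = 0
    for case in gold:
        value = scores.get((case.subject, case.outcome))
        if value is None:
            passing = False
        elif direction == "less":
            passing = value < threshold
        else:
            passing = value > threshold
        if passing:
            tp += case.positive
            fp += not case.positive
        else:
            fn += case.positive
            tn += not case.positive
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(cm: ConfusionMatrix) -> tuple[float | None, float | None, float | None]:
    """Precision, recall and F1 (harmonic mean); a value whose denominator
    is zero is reported as None."""
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp > 0 else None
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, the convention used for printed metrics."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def roc_auc(
    scores: Mapping[str, float],
    labels: Mapping[str, bool],
) -> float:
    """Rank-based (concordance) AUC with ties counted 1/2.

    `labels` enumerates the evaluated subjects; subjects absent from
    `scores` rank below every scored subject (tied among themselves),
    reflecting that no supporting literature means no signal.
    """
    subjects = sorted(labels)
    y = np.array([labels[s] for s in subjects], dtype=bool)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs at least one positive and one negative")
    x = np.array([scores.get(s, -np.inf) for s in subjects], dtype=float)
    ranks = rankdata(x)  # average ranks handle ties, including the -inf block
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
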