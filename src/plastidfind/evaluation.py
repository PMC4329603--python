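"""Classifier evaluation: confusion counts, sensitivity/specificity/MCC,
ROC points, and transit-score histograms.

Predictions are compared against a labeled reference set at one of two
positive-class definitions: "high_only" (only the high-confidence plastid
class counts as a positive prediction) or "high_or_low" (either plastid
class counts).  Both "not plastid" classes count as predicted-negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .predictor import PredictionClass, PredictionRecord

POSITIVE_DEFINITIONS = ("high_only", "high_or_low")


@dataclass(frozen=True)
class LabeledReference:
    """A protein with experimentally known localization."""

    id: str
    true_plastid: bool
    source_note: str = ""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    positive_definition: str = "high_only"

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def swapped(self) -> "ConfusionCounts":
        """Counts after inverting every predicted label."""
        return ConfusionCounts(
            tp=self.fn, fp=self.tn, tn=self.fp, fn=self.tp,
            positive_definition=self.positive_definition,
        )


def _predicted_positive(cls: PredictionClass, positive_definition: str) -> bool:
    if positive_definition == "high_only":
        return cls is PredictionClass.PLASTID_HIGH
    if positive_definition == "high_or_low":
        return cls in (PredictionClass.PLASTID_HIGH, PredictionClass.PLASTID_LOW)
    raise ValueError(f"unknown positive definition '{positive_definition}'")


def confusion(
    predictions: Sequence[PredictionRecord],
    references: Sequence[LabeledReference],
    positive_definition: str = "high_only",
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN of predictions against the reference labels.

    Every reference id must have a prediction; missing ids are an error.
    Predictions without a reference label are ignored.
    """
    ids = [r.id for r in references]
    if len(set(ids)) != len(ids):
        raise ValueError("reference ids are not unique")
    by_id = {p.id: p for p in predictions}
    missing = [r.id for r in references if r.id not in by_id]
    if missing:
        raise KeyError("no prediction for reference id(s): " + ", ".join(missing))
    tp = fp = tn = fn = 0
    for ref in references:
        pred_pos = _predicted_positive(by_id[ref.id].prediction, positive_definition)
        if ref.true_plastid:
            tp += pred_pos
            fn += not pred_pos
        else:
            fp += pred_pos
            tn += not pred_pos
    return ConfusionCounts(tp, fp, tn, fn, positive_definition)


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); undefined (error) without actual positives."""
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no actual positives")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); undefined (error) without actual negatives."""
    if c.tn + c.fp == 0:
        raise ZeroDivisionError("specificity undefined: no actual negatives")
    return c.tn / (c.tn + c.fp)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def roc_point(c: ConfusionCounts) -> tuple[float, float]:
    """(false-positive rate, true-positive rate) of the hard classifier.

    A perfect predictor maps to (0, 1), its inverse to (1, 0); the diagonal
    corresponds to random guessing.
    """
    return 1.0 - specificity(c), sensitivity(c)


def transit_score_histogram(
    predictions: Sequence[PredictionRecord], bin_width: float = 1.0
) -> list[tuple[tuple[float, float], int]]:
    """Histogram of transit-peptide scores over SignalP-positive records.

    Bins are half-open [k*w, (k+1)*w) and returned in ascending order; the
    total count equals the number of records carrying a transit score.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    counts: dict[int, int] = {}
    for p in predictions:
        if p.transit_score is None:
            continue
        k = math.floor(p.transit_score / bin_width)
        counts[k] = counts.get(k, 0) + 1
    return [
        ((k * bin_width, (k + 1) * bin_width), counts[k]) for k in sorted(counts)
    ]


def ranked_transit_scores(
    predictions: Sequence[PredictionRecord],
) -> list[tuple[str, float, str | None]]:
    """(id, transit score, +1 residue) sorted by descending score.

    The rank curve visualizes the characteristic sudden drop in transit
    score where the +1 phenylalanine is lost.
    """
    rows = [
        (p.id, p.transit_score, p.plus1_residue)
        for p in predictions
        if p.transit_score is not None
    ]
    rows.sort(key=lambda r: -r[1])
    return rows


def read_reference_tsv(path: str | Path) -> list[LabeledReference]:
    """Read reference labels: TSV with columns id, plastid (Y/N), note."""
    refs: list[LabeledReference] = []
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if lines and lines[0].split("\t")[0] == "id":
        lines = lines[1:]
    for ln in lines:
        f = ln.split("\t")
        if len(f) < 2 or f[1] not in ("Y", "N"):
            raise ValueError(f"bad reference row (need id, Y/N[, note]): {ln!r}")
        refs.append(LabeledReference(f[0], f[1] == "Y", f[2] if len(f) > 2 else ""))
    return refs


def write_reference_tsv(refs: Sequence[LabeledReference], path: str | Path) -> None:
    lines = ["id\tplastid\tnote"]
    for r in refs:
        lines.append(f"{r.id}\t{'Y' if r.true_plastid else 'N'}\t{r.source_note}")
    Path(path).write_text("\n".join(lines) + "\n")


def statistics_table(
    predictions: Sequence[PredictionRecord],
    references: Sequence[LabeledReference],
) -> "list[dict[str, object]]":
    """Sensitivity/specificity/MCC/ROC under both positive definitions."""
    rows = []
    for definition in POSITIVE_DEFINITIONS:
        c = confusion(predictions, references, definition)
        fpr, tpr = roc_point(c)
        rows.append(
            {
                "positive_definition": definition,
                "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
                "sensitivity": sensitivity(c),
                "specificity": specificity(c),
                "mcc": mcc(c),
                "fpr": fpr, "tpr": tpr,
            }
        )
    return rows
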