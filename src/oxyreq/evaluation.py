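"""Confusion tables, one-vs-rest Matthews correlation, misclassification rate."""

from __future__ import annotations

from dataclasses import dataclass
from math import floor, sqrt
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from oxyreq.bayes_net import PredictionRun


@dataclass
class ConfusionTable:
    """K x K truth-by-prediction counts; ``counts[i, j]`` = genomes of true
    class ``classes[i]`` predicted as ``classes[j]``."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def count(self, true_class: str, predicted_class: str) -> int:
        return int(
            self.counts[self.classes.index(true_class), self.classes.index(predicted_class)]
        )

    def column_percentages(self) -> np.ndarray:
        """Per-true-class prediction percentages, rounded half-up to integers.

        Each true class's row is divided by its row total (the layout used by
        the reference count tables, transposed); entries are integer percents.
        """
        out = np.zeros_like(self.counts)
        for i in range(len(self.classes)):
            row_total = self.counts[i].sum()
            if row_total:
                out[i] = [_round_half_up(100.0 * v / row_total) for v in self.counts[i]]
        return out


def _round_half_up(x: float) -> int:
    return int(floor(x + 0.5))


@dataclass
class BinaryCounts:
    """One-vs-rest collapse of a confusion table."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_table(
    truth: Mapping[str, str],
    predicted: "PredictionRun | Mapping[str, str]",
    classes: Sequence[str],
) -> ConfusionTable:
    """Tally truth-by-prediction counts over the evaluated genomes."""
    preds = predicted.predictions if isinstance(predicted, PredictionRun) else predicted
    missing = [g for g in truth if g not in preds]
    if missing:
        raise ValueError(f"genomes without predictions: {sorted(missing)[:10]}")
    classes = tuple(classes)
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for g, t in truth.items():
        counts[idx[t], idx[preds[g]]] += 1
    return ConfusionTable(classes, counts)


def collapse_one_vs_rest(ct: ConfusionTable, positive_class: str) -> BinaryCounts:
    """Force the K classes into positive vs. everything else."""
    i = ct.classes.index(positive_class)
    tp = int(ct.counts[i, i])
    fn = int(ct.counts[i].sum()) - tp
    fp = int(ct.counts[:, i].sum()) - tp
    tn = ct.total - tp - fn - fp
    return BinaryCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def mcc(bc: BinaryCounts) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    tp, fp, fn, tn = bc.tp, bc.fp, bc.fn, bc.tn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / sqrt(denom)


def misclassification_rate(ct: ConfusionTable) -> float:
    """Fraction of genomes predicted into the wrong class."""
    if ct.total == 0:
        raise ValueError("empty confusion table")
    return 1.0 - int(np.trace(ct.counts)) / ct.total


def per_class_mcc(ct: ConfusionTable) -> dict[str, float]:
    """One-vs-rest MCC for every class of the table."""
    return {c: mcc(collapse_one_vs_rest(ct, c)) for c in ct.classes}


def write_report(ct: ConfusionTable, path: str | Path) -> None:
    """Evaluation report TSV: per-class MCC block, then the confusion table."""
    path = Path(path)
    mccs = per_class_mcc(ct)
    pct = ct.column_percentages()
    with path.open("w") as fh:
        fh.write("class\tmcc\n")
        for c in ct.classes:
            fh.write(f"{c}\t{mccs[c]:.4f}\n")
        fh.write(f"misclassification_rate\t{misclassification_rate(ct):.4f}\n")
        fh.write("\n")
        fh.write("true\\predicted\t" + "\t".join(ct.classes) + "\tpercent_correct\n")
        for i, c in enumerate(ct.classes):
            row = "\t".join(str(int(v)) for v in ct.counts[i])
            fh.write(f"{c}\t{row}\t{int(pct[i, i])}%\n")
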