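"""Alignment evaluation: precision, recall and the F-beta family.

Predicted and reference alignments are sets of (A-id, B-id) pairs.  With
TP/FP/FN the usual confusion counts,

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F_beta    = (1 + beta^2) TP / ((1 + beta^2) TP + beta^2 FN + FP)

F_1 is the harmonic mean of precision and recall; beta < 1 weights
precision, beta > 1 weights recall.  Degenerate 0/0 ratios are reported as
0 (OAEI convention) with a log message.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion(predicted: set[Pair], reference: set[Pair]) -> ConfusionCounts:
    predicted, reference = set(predicted), set(reference)
    tp = len(predicted & reference)
    return ConfusionCounts(TP=tp, FP=len(predicted) - tp,
                           FN=len(reference) - tp)


def precision(c: ConfusionCounts) -> float:
    if c.TP + c.FP == 0:
        logger.debug("precision 0/0 reported as 0")
        return 0.0
    return c.TP / (c.TP + c.FP)


def recall(c: ConfusionCounts) -> float:
    if c.TP + c.FN == 0:
        logger.debug("recall 0/0 reported as 0")
        return 0.0
    return c.TP / (c.TP + c.FN)


def f_beta(c: ConfusionCounts, beta: float) -> float:
    """F-beta from the counts; agrees with the precision/recall form."""
    if not beta > 0:
        raise ValueError(f"beta must be positive, got {beta!r}")
    b2 = beta * beta
    denom = (1 + b2) * c.TP + b2 * c.FN + c.FP
    if denom == 0:
        logger.debug("F_beta 0/0 reported as 0")
        return 0.0
    return (1 + b2) * c.TP / denom


@dataclass
class ScoreReport:
    precision: float
    recall: float
    f1: float
    f05: float
    f2: float
    beta_used: list[float] = field(default_factory=lambda: [0.5, 1.0, 2.0])
    counts: ConfusionCounts | None = None

    def to_dict(self) -> dict:
        out = {"precision": self.precision, "recall": self.recall,
               "f1": self.f1, "f05": self.f05, "f2": self.f2,
               "beta_used": list(self.beta_used)}
        if self.counts is not None:
            out.update(TP=self.counts.TP, FP=self.counts.FP,
                       FN=self.counts.FN)
        return out

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def score_report(predicted: set[Pair], reference: set[Pair]) -> ScoreReport:
    c = confusion(predicted, reference)
    return ScoreReport(precision=precision(c), recall=recall(c),
                       f1=f_beta(c, 1.0), f05=f_beta(c, 0.5),
                       f2=f_beta(c, 2.0), counts=c)


def read_reference(path: str) -> set[Pair]:
    """Read a two-column reference alignment TSV ('#' comments allowed)."""
    pairs: set[Pair] = set()
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two tab-separated columns")
            n_rows += 1
            pairs.add((parts[0].strip(), parts[1].strip()))
    if n_rows > len(pairs):
        logger.warning("%d duplicate reference pairs collapsed in %r",
                       n_rows - len(pairs), path)
    return pairs


def write_reference(pairs: set[Pair], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# reference alignment: A-id<TAB>B-id\n")
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")
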