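"""Hierarchical evaluation: prediction rate, accuracy and micro-F1 per rank.

Per taxonomic rank:

    prediction rate = predicted contigs / total contigs
    accuracy        = correctly predicted contigs / predicted contigs
    F1              = 2 TP / (2 TP + FP + FN)   on class-summed counts

Counting per class: a correct prediction is a TP for the true class; a wrong
prediction is an FP for the predicted class and an FN for the true class; a
contig with no prediction at the rank (early stop or tool abstention) is an
FN for its true class — and remains an FN at every deeper rank, since
predictions only truncate downward.  A consequence worth noting is the
rectangle identity: prediction rate x accuracy equals the fraction of all
contigs predicted correctly at the rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import RANKS

logger = logging.getLogger(__name__)


@dataclass
class RankEvaluation:
    rank: str
    n_total: int
    n_predicted: int
    n_correct: int
    tp: int
    fp: int
    fn: int
    per_class: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    @property
    def prediction_rate(self) -> float:
        return self.n_predicted / self.n_total if self.n_total else float("nan")

    @property
    def accuracy(self) -> float:
        """Correct / predicted; NA (NaN) when nothing was predicted."""
        return self.n_correct / self.n_predicted if self.n_predicted else float("nan")

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0

    def macro_f1(self) -> float:
        """Per-class-averaged F1 (non-canonical, offered for comparison)."""
        scores = []
        for tp, fp, fn in self.per_class.values():
            d = 2 * tp + fp + fn
            scores.append(2 * tp / d if d else 0.0)
        return float(np.mean(scores)) if scores else 0.0


def evaluate_rank(
    truths: Mapping[str, str],
    predictions: Mapping[str, str | None],
    rank: str,
) -> RankEvaluation:
    """Evaluate one rank.

    ``truths``: contig -> true taxon at the rank (complete).  ``predictions``:
    contig -> predicted taxon, or None / missing key for no prediction at the
    rank.  Contigs present in predictions but absent from truths are excluded
    with a warning.
    """
    extra = set(predictions) - set(truths)
    if extra:
        logger.warning("%d predicted contigs have no truth at rank %s; excluded",
                       len(extra), rank)
    counts: dict[str, list[int]] = {}   # class -> [tp, fp, fn]
    def c(name: str) -> list[int]:
        return counts.setdefault(name, [0, 0, 0])

    n_total = n_predicted = n_correct = 0
    for contig, truth in truths.items():
        n_total += 1
        pred = predictions.get(contig)
        if pred is None:
            c(truth)[2] += 1            # no prediction at this rank -> FN
            continue
        n_predicted += 1
        if pred == truth:
            n_correct += 1
            c(truth)[0] += 1
        else:
            c(pred)[1] += 1
            c(truth)[2] += 1
    tp = sum(v[0] for v in counts.values())
    fp = sum(v[1] for v in counts.values())
    fn = sum(v[2] for v in counts.values())
    return RankEvaluation(rank=rank, n_total=n_total, n_predicted=n_predicted,
                          n_correct=n_correct, tp=tp, fp=fp, fn=fn,
                          per_class={k: tuple(v) for k, v in counts.items()})


def evaluate_all_ranks(
    truths: Mapping[str, tuple[str, ...]],
    predictions: Mapping[str, tuple[str, ...]],
) -> list[RankEvaluation]:
    """Evaluate phylum through species.

    ``truths``: contig -> complete 6-rank lineage.  ``predictions``: contig ->
    possibly truncated lineage (phylum downward); a truncated prediction is
    counted as predicted for the ranks it covers and FN below.
    """
    out = []
    for i, rank in enumerate(RANKS):
        rank_truth = {cid: lin[i] for cid, lin in truths.items() if len(lin) > i}
        rank_pred: dict[str, str | None] = {}
        for cid, lin in predictions.items():
            rank_pred[cid] = lin[i] if len(lin) > i else None
        out.append(evaluate_rank(rank_truth, rank_pred, rank))
    return out


def evaluation_table(evaluations: list[RankEvaluation]) -> pd.DataFrame:
    """Tidy per-rank metrics table."""
    return pd.DataFrame([
        dict(rank=e.rank, n_total=e.n_total, n_predicted=e.n_predicted,
             prediction_rate=e.prediction_rate, accuracy=e.accuracy, f1=e.f1,
             macro_f1=e.macro_f1())
        for e in evaluations
    ])
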